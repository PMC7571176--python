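"""Cumulative AUCs, enhancement ratios, FWHM resolution, film thickness.

The cumulative amount of drug delivered into the skin is the trapezoidal
area under a normalized depth profile from the surface down to
``depth_max`` (units: arbitrary units · µm).  The enhancement ratio of a
formulation with penetration enhancer over the plain formulation at the
same time point is the quotient of those two areas.  The axial resolution
of a depth scan is the FWHM of the depth profile of a band emitted from a
thin plane (silica 521 cm⁻¹); a film's apparent thickness is the FWHM of
its plateau-shaped band profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import ProfileShapeError, ValidationError
from .profiling import DepthProfile, ProfileSet

#: Default integration bound, µm: covers the full stratum corneum
#: (15–20 µm) and the deepest observed penetration.
DEFAULT_DEPTH_MAX = 20.0


@dataclass(frozen=True)
class EnhancementResult:
    """Cumulative AUC pair and their ratio at one time point."""

    time_h: float
    auc_plain: float
    auc_enhancer: float
    ratio: float

    def __post_init__(self) -> None:
        if self.auc_plain <= 0:
            raise ValidationError("auc_plain must be positive")


@dataclass(frozen=True)
class ResolutionResult:
    """Axial resolution (FWHM, µm) and the profile it was read from."""

    fwhm_um: float
    profile: DepthProfile

    def __post_init__(self) -> None:
        if self.fwhm_um <= 0:
            raise ValidationError("fwhm_um must be positive")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cumulative_auc(profile: DepthProfile, depth_max: float = DEFAULT_DEPTH_MAX) -> float:
    """Trapezoidal integral of a profile over [0, depth_max] µm.

    The endpoint at ``depth_max`` is linearly interpolated when it falls
    between samples; a bound beyond the last depth is clipped with a
    warning.
    """
    d = profile.depths
    v = profile.values
    if d.size == 0:
        raise ValidationError("cannot integrate an empty profile")
    if depth_max <= d[0]:
        return 0.0
    if depth_max > d[-1] + 1e-9:
        warnings.warn(
            f"depth_max {depth_max} µm beyond last profile depth {d[-1]} µm; "
            "clipping",
            stacklevel=2,
        )
        depth_max = float(d[-1])
    inside = d < depth_max - 1e-12
    dd = np.concatenate([d[inside], [depth_max]])
    vv = np.concatenate([v[inside], [np.interp(depth_max, d, v)]])
    return float(np.trapezoid(vv, dd))


def enhancement_ratio(auc_enhancer: float, auc_plain: float) -> float:
    """AUC with enhancer divided by AUC without; unrounded.

    Use :func:`round_half_up` (2 decimals) when reporting.
    """
    if auc_plain <= 0:
        raise ValidationError(f"auc_plain must be positive, got {auc_plain}")
    return float(auc_enhancer) / float(auc_plain)


def enhancement_table(
    plain: dict[float, ProfileSet],
    enh: dict[float, ProfileSet],
    depth_max: float = DEFAULT_DEPTH_MAX,
) -> list[EnhancementResult]:
    """Per-time-point cumulative AUCs of the mean profiles and their ratio.

    Ratios are reported rounded half-up to 2 decimals; results are sorted
    by time.
    """
    if set(plain) != set(enh):
        raise ValidationError(
            f"time points differ between arms: {sorted(plain)} vs {sorted(enh)}"
        )
    results = []
    for t in sorted(plain):
        a = cumulative_auc(plain[t].mean, depth_max)
        b = cumulative_auc(enh[t].mean, depth_max)
        results.append(
            EnhancementResult(
                time_h=float(t),
                auc_plain=a,
                auc_enhancer=b,
                ratio=round_half_up(enhancement_ratio(b, a), 2),
            )
        )
    return results


def _cross(d: np.ndarray, v: np.ndarray, i: int, j: int, level: float) -> float:
    """Depth where the segment (i, j) crosses ``level`` (linear)."""
    if v[j] == v[i]:
        return float(d[j])
    frac = (level - v[i]) / (v[j] - v[i])
    return float(d[i] + frac * (d[j] - d[i]))


def fwhm(profile: DepthProfile) -> ResolutionResult:
    """Full width at half maximum of a single-peaked depth profile.

    The half-max level is max/2; the crossings on each side of the maximum
    are located by linear interpolation.  Raises
    :class:`ProfileShapeError` when the profile does not fall below
    half-max on both sides.
    """
    d = profile.depths
    v = profile.values
    imax = int(np.argmax(v))
    vmax = float(v[imax])
    if vmax <= 0:
        raise ProfileShapeError("profile maximum must be positive")
    half = 0.5 * vmax
    left = None
    for i in range(imax, 0, -1):
        if v[i - 1] < half <= v[i]:
            left = _cross(d, v, i - 1, i, half)
            break
    right = None
    for i in range(imax, d.size - 1):
        if v[i] >= half > v[i + 1]:
            right = _cross(d, v, i, i + 1, half)
            break
    if left is None or right is None:
        raise ProfileShapeError(
            "profile does not cross half-maximum on both sides of its peak"
        )
    return ResolutionResult(fwhm_um=right - left, profile=profile)


def film_thickness(profile: DepthProfile, method: str = "fwhm") -> float:
    """Apparent film thickness from a plateau-shaped band profile, µm.

    ``method="fwhm"`` (default): distance between the half-maximum
    crossings — for a symmetric edge response this equals the true boxcar
    width.  ``method="edge_midpoints"``: each edge located as the midpoint
    of its 25% and 75% crossings.
    """
    if method == "fwhm":
        return fwhm(profile).fwhm_um
    if method != "edge_midpoints":
        raise ValidationError(f"unknown film_thickness method {method!r}")
    d = profile.depths
    v = profile.values
    imax = int(np.argmax(v))
    vmax = float(v[imax])
    if vmax <= 0:
        raise ProfileShapeError("profile maximum must be positive")
    edges = []
    for level in (0.25 * vmax, 0.75 * vmax):
        left = right = None
        for i in range(imax, 0, -1):
            if v[i - 1] < level <= v[i]:
                left = _cross(d, v, i - 1, i, level)
                break
        for i in range(imax, d.size - 1):
            if v[i] >= level > v[i + 1]:
                right = _cross(d, v, i, i + 1, level)
                break
        if left is None or right is None:
            raise ProfileShapeError("profile lacks clear rising/falling edges")
        edges.append((left, right))
    (l25, r25), (l75, r75) = edges
    return 0.5 * (r25 + r75) - 0.5 * (l25 + l75)


def thickness_discrepancy(nominal_um: float, measured_um: float) -> float:
    """Nominal minus measured film thickness, µm (depth-scale error report)."""
    return nominal_um - measured_um
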