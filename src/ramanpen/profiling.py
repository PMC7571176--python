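"""From a preprocessed scan to cropped, normalized drug depth profiles.

The chain mirrors the measurement logic: the band area (trapezoid over a
baseline-corrected window) of every spectrum gives a raw band-vs-depth
profile; the 10 lateral positions of a scan are split into 3 contiguous
groups and laterally averaged, yielding 3 replicate profiles per scan; the
skin surface is located where the keratin 1008 cm⁻¹ profile first reaches
half of its maximum; profiles are cropped to that surface (depth 0 = skin
surface) and the drug profile is normalized by the arithmetic mean of the
keratin profile over the cropped grid, which compensates the signal
attenuation in deeper skin regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ProfileShapeError, SurfaceDetectionError, ValidationError
from .scan_io import Band, DepthScan

_STATES = ("raw", "cropped", "normalized")


@dataclass
class DepthProfile:
    """Band signal versus depth.

    ``depths`` are µm — stage depth for ``state="raw"``, skin depth
    (0 at the surface, increasing into the skin) after cropping.  ``sd``
    is a per-depth sample SD, present only on aggregated mean profiles.
    """

    depths: np.ndarray
    values: np.ndarray
    band: str
    state: str = "raw"
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.state not in _STATES:
            raise ValidationError(f"unknown profile state {self.state!r}")
        if self.depths.ndim != 1 or self.depths.size == 0:
            raise ValidationError("profile depths must be a non-empty vector")
        if self.values.shape != self.depths.shape:
            raise ValidationError("profile values/depths length mismatch")
        if self.depths.size > 1 and not np.all(np.diff(self.depths) > 0):
            raise ValidationError("profile depths must be strictly increasing")
        if self.state in ("cropped", "normalized") and abs(self.depths[0]) > 1e-9:
            raise ValidationError(f"{self.state} profile must start at depth 0")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.depths.shape:
                raise ValidationError("profile sd/depths length mismatch")


@dataclass
class ProfileSet:
    """Replicate profiles of one formulation/time plus their mean ± SD."""

    replicates: list[DepthProfile]
    mean: DepthProfile
    label: str = ""


def band_auc(wavenumbers: np.ndarray, spectrum: np.ndarray, band: Band) -> float:
    """Baseline-corrected trapezoidal band area of one spectrum.

    A local linear baseline through the window endpoints (each anchored at
    the mean of the 3 outermost in-window samples) is subtracted, then the
    remainder is integrated over [window_lo, window_hi] by the trapezoidal
    rule.  May be negative for noise-only windows.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(spectrum, dtype=float)
    if band.window_lo < wn[0] or band.window_hi > wn[-1]:
        raise ValidationError(
            f"band {band.name!r} window [{band.window_lo}, {band.window_hi}] "
            f"outside spectral axis [{wn[0]}, {wn[-1]}]"
        )
    mask = (wn >= band.window_lo) & (wn <= band.window_hi)
    if mask.sum() < 2:
        raise ValidationError(
            f"band {band.name!r} window contains fewer than 2 samples"
        )
    w = wn[mask]
    v = y[mask]
    k = min(3, v.size)
    x_l, y_l = float(np.mean(w[:k])), float(np.mean(v[:k]))
    x_r, y_r = float(np.mean(w[-k:])), float(np.mean(v[-k:]))
    if x_r > x_l:
        baseline = y_l + (y_r - y_l) * (w - x_l) / (x_r - x_l)
    else:
        baseline = np.full_like(w, 0.5 * (y_l + y_r))
    return float(np.trapezoid(v - baseline, w))


def split_lateral_groups(scan: DepthScan, n_groups: int = 3) -> list[DepthScan]:
    """Partition lateral positions into contiguous groups and average each.

    Groups are as equal as possible, larger groups last (10 positions with
    3 groups → sizes 3, 3, 4); each group's lateral average becomes a
    1 × depth scan.
    """
    n = scan.n_lateral
    if n_groups < 1:
        raise ValidationError("n_groups must be >= 1")
    if n_groups > n:
        raise ValidationError(
            f"cannot split {n} lateral positions into {n_groups} groups"
        )
    base, rem = divmod(n, n_groups)
    sizes = [base] * (n_groups - rem) + [base + 1] * rem
    out = []
    start = 0
    for size in sizes:
        sl = slice(start, start + size)
        mean_int = scan.intensities[sl].mean(axis=0, keepdims=True)
        out.append(
            DepthScan(
                axis=scan.axis,
                lateral_positions=np.array(
                    [float(np.mean(scan.lateral_positions[sl]))]
                ),
                depth_positions=scan.depth_positions.copy(),
                intensities=mean_int,
                metadata={**scan.metadata, "lateral_group": f"{start}:{start + size}"},
            )
        )
        start += size
    return out


def extract_profile(scan_1d: DepthScan, band: Band) -> DepthProfile:
    """Band AUC at every depth of a lateral-averaged (1 × depth) scan."""
    if scan_1d.n_lateral != 1:
        raise ValidationError(
            "extract_profile expects a lateral-averaged scan with 1 lateral "
            f"position, got {scan_1d.n_lateral}"
        )
    wn = scan_1d.axis.wavenumbers
    values = np.array(
        [
            band_auc(wn, scan_1d.intensities[0, i, :], band)
            for i in range(scan_1d.n_depth)
        ]
    )
    return DepthProfile(
        depths=scan_1d.depth_positions.copy(),
        values=values,
        band=band.name,
        state="raw",
    )


def detect_surface(keratin_profile: DepthProfile) -> float:
    """Depth of the skin surface: first half-maximum crossing of keratin.

    The maximum is taken after a 3-point moving-average smooth; the first
    upward crossing of half that maximum is located on the raw profile by
    linear interpolation between the bracketing samples.
    """
    d = keratin_profile.depths
    v = keratin_profile.values
    smoothed = ndimage.uniform_filter1d(v, size=3, mode="nearest")
    vmax = float(smoothed.max())
    if vmax <= 0:
        raise SurfaceDetectionError("keratin profile maximum is not positive")
    half = 0.5 * vmax
    if v[0] >= half:
        raise SurfaceDetectionError(
            "profile already above half-maximum at the first depth "
            "(scan may have started below the skin surface)"
        )
    above = np.nonzero(v >= half)[0]
    if above.size == 0:
        raise SurfaceDetectionError("profile never crosses half-maximum")
    i = int(above[0])
    frac = (half - v[i - 1]) / (v[i] - v[i - 1])
    return float(d[i - 1] + frac * (d[i] - d[i - 1]))


def crop_to_surface(profile: DepthProfile, surface: float) -> DepthProfile:
    """Drop samples above the skin surface and re-zero depth at it.

    If no existing sample lies within 1e-6 µm of the surface, a linearly
    interpolated sample at exactly depth 0 is inserted.
    """
    d = profile.depths
    v = profile.values
    if surface < d[0] - 1e-9 or surface > d[-1] + 1e-9:
        raise ValidationError(
            f"surface {surface} µm outside profile depth range [{d[0]}, {d[-1]}]"
        )
    keep = d >= surface - 1e-6
    new_d = d[keep] - surface
    new_v = v[keep]
    if new_d.size == 0 or new_d[0] > 1e-6:
        v0 = float(np.interp(surface, d, v))
        new_d = np.concatenate([[0.0], new_d])
        new_v = np.concatenate([[v0], new_v])
    else:
        new_d = new_d.copy()
        new_d[0] = 0.0
    return DepthProfile(
        depths=new_d, values=new_v, band=profile.band, state="cropped"
    )


def normalize_profile(
    drug_profile: DepthProfile, keratin_profile: DepthProfile
) -> DepthProfile:
    """Divide the drug profile by the mean keratin signal on the same grid.

    The arithmetic mean of the keratin (1008 cm⁻¹ ring-breathing) profile
    over the cropped grid is the per-profile normalization constant; the
    result is scale-invariant under any global intensity rescaling of the
    raw scan.
    """
    if drug_profile.state != "cropped" or keratin_profile.state != "cropped":
        raise ValidationError("normalize_profile expects cropped profiles")
    if drug_profile.depths.shape != keratin_profile.depths.shape or not np.allclose(
        drug_profile.depths, keratin_profile.depths, atol=1e-9
    ):
        raise ValidationError("drug and keratin profiles are on different grids")
    k = float(np.mean(keratin_profile.values))
    if k <= 0:
        raise ValidationError(f"keratin mean must be positive, got {k}")
    return DepthProfile(
        depths=drug_profile.depths.copy(),
        values=drug_profile.values / k,
        band=drug_profile.band,
        state="normalized",
    )


def aggregate_profiles(
    replicates: list[DepthProfile], label: str = ""
) -> ProfileSet:
    """Mean ± sample SD of replicate profiles on a common depth grid.

    Replicates are linearly interpolated onto a grid spanning the
    intersection of their depth ranges with step = median replicate step.
    """
    if len(replicates) < 2:
        raise ValidationError("aggregation needs at least 2 replicates (for SD)")
    bands = {p.band for p in replicates}
    states = {p.state for p in replicates}
    if len(bands) > 1 or len(states) > 1:
        raise ValidationError(
            f"replicates must share band and state, got bands={bands}, "
            f"states={states}"
        )
    lo = max(p.depths[0] for p in replicates)
    hi = min(p.depths[-1] for p in replicates)
    if hi <= lo:
        raise ValidationError("replicate depth ranges do not overlap")
    step = float(np.median(np.concatenate([np.diff(p.depths) for p in replicates])))
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    grid = lo + step * np.arange(n)
    stack = np.vstack([np.interp(grid, p.depths, p.values) for p in replicates])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    mean_profile = DepthProfile(
        depths=grid,
        values=mean,
        band=replicates[0].band,
        state=replicates[0].state,
        sd=sd,
    )
    return ProfileSet(replicates=list(replicates), mean=mean_profile, label=label)


def scan_to_profiles(
    scan: DepthScan,
    drug_band: Band,
    keratin_band: Band,
    n_groups: int = 3,
) -> list[DepthProfile]:
    """Preprocessed scan → ``n_groups`` cropped, normalized drug profiles.

    Per lateral group: extract drug and keratin profiles, locate the skin
    surface on the keratin profile, crop both to it, normalize the drug
    profile by the keratin mean.
    """
    profiles = []
    for sub in split_lateral_groups(scan, n_groups):
        drug_raw = extract_profile(sub, drug_band)
        ker_raw = extract_profile(sub, keratin_band)
        surface = detect_surface(ker_raw)
        drug_c = crop_to_surface(drug_raw, surface)
        ker_c = crop_to_surface(ker_raw, surface)
        profiles.append(normalize_profile(drug_c, ker_c))
    return profiles
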