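"""Read and write hyperspectral depth scans, band configs, and result tables.

A depth scan is an intensity cube indexed ``[lateral, depth, wavenumber]``
with strictly increasing axes.  Scans are stored in a self-describing
tab-delimited text dialect ("matrix"): ``# key: value`` header lines carry
the three axes and free-form metadata, then one tab-separated spectrum per
row in lateral-major (outer lateral, inner depth) order.

Band definitions (named wavenumber windows such as the caffeine 556 cm⁻¹
O=C-N deformation band or the keratin 1008 cm⁻¹ ring-breathing band) are
read from a YAML file of ``name/center/window_lo/window_hi/assignment``
records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ScanFormatError, ValidationError

_AXIS_KEYS = ("lateral_um", "depth_um", "wavenumber_cm1")

_BAND_KEYS = {"name", "center", "window_lo", "window_hi", "assignment"}


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing Raman-shift axis in cm⁻¹."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        if wn.ndim != 1 or wn.size < 2:
            raise ValidationError("spectral axis needs at least 2 wavenumbers")
        if not np.all(np.diff(wn) > 0):
            raise ValidationError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)


@dataclass(frozen=True)
class Band:
    """Named integration window on the spectral axis.

    ``window_lo < center < window_hi`` always; whether the window fits
    inside a particular axis is checked when the band is applied.
    """

    name: str
    center: float
    window_lo: float
    window_hi: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if not (self.window_lo < self.center < self.window_hi):
            raise ValidationError(
                f"band {self.name!r}: require window_lo < center < window_hi, "
                f"got [{self.window_lo}, {self.center}, {self.window_hi}]"
            )

    def check_on_axis(self, axis: SpectralAxis) -> None:
        wn = axis.wavenumbers
        if self.window_lo < wn[0] or self.window_hi > wn[-1]:
            raise ValidationError(
                f"band {self.name!r} window [{self.window_lo}, {self.window_hi}] "
                f"outside spectral axis [{wn[0]}, {wn[-1]}]"
            )


#: Default band set used throughout: symmetric ~±17 cm⁻¹ windows clear of
#: neighbouring skin bands.
DEFAULT_BANDS: dict[str, Band] = {
    "caffeine": Band("caffeine", 556.0, 540.0, 575.0, "O=C-N deformation"),
    "keratin": Band("keratin", 1008.0, 990.0, 1025.0, "phenylalanine ring breathing"),
    "silica": Band("silica", 521.0, 505.0, 540.0, "Si lattice"),
    "pet": Band("pet", 1614.0, 1598.0, 1630.0, "PET ring C=C stretch"),
}


@dataclass
class DepthScan:
    """Lateral × depth × wavenumber intensity cube with axes and metadata.

    Depth is the stage coordinate, increasing downward into the sample;
    plane 0 is the first acquired plane, typically a couple of µm above the
    skin surface, so raw depth is not skin depth until profiles are cropped.
    Positions are in µm, wavenumbers in cm⁻¹ — no unit auto-detection.
    """

    axis: SpectralAxis
    lateral_positions: np.ndarray
    depth_positions: np.ndarray
    intensities: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lateral_positions = np.asarray(self.lateral_positions, dtype=float)
        self.depth_positions = np.asarray(self.depth_positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        for name, pos in (
            ("lateral_positions", self.lateral_positions),
            ("depth_positions", self.depth_positions),
        ):
            if pos.ndim != 1 or pos.size < 1:
                raise ValidationError(f"{name} must be a non-empty 1-D vector")
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
        expected = (
            self.lateral_positions.size,
            self.depth_positions.size,
            len(self.axis),
        )
        if self.intensities.shape != expected:
            raise ValidationError(
                f"intensity cube shape {self.intensities.shape} does not match "
                f"axes {expected}"
            )

    @property
    def n_lateral(self) -> int:
        return int(self.lateral_positions.size)

    @property
    def n_depth(self) -> int:
        return int(self.depth_positions.size)

    @property
    def n_spectra(self) -> int:
        return self.n_lateral * self.n_depth

    def spectra_matrix(self) -> np.ndarray:
        """All spectra as a (n_spectra, n_wavenumbers) view, lateral-major."""
        return self.intensities.reshape(self.n_spectra, len(self.axis))

    def with_intensities(self, intensities: np.ndarray) -> "DepthScan":
        """Copy of this scan with a replaced intensity cube (same axes)."""
        return DepthScan(
            axis=self.axis,
            lateral_positions=self.lateral_positions.copy(),
            depth_positions=self.depth_positions.copy(),
            intensities=np.asarray(intensities, dtype=float),
            metadata=dict(self.metadata),
        )


def _format_vector(v: np.ndarray) -> str:
    return ",".join(f"{x:.12g}" for x in np.asarray(v, dtype=float))


def write_scan(scan: DepthScan, path) -> None:
    """Write a scan in the "matrix" dialect (see module docstring)."""
    lines = []
    for key, value in scan.metadata.items():
        if key in _AXIS_KEYS:
            raise ValidationError(f"metadata key {key!r} shadows an axis key")
        lines.append(f"# {key}: {value}")
    lines.append(f"# lateral_um: {_format_vector(scan.lateral_positions)}")
    lines.append(f"# depth_um: {_format_vector(scan.depth_positions)}")
    lines.append(f"# wavenumber_cm1: {_format_vector(scan.axis.wavenumbers)}")
    body = scan.spectra_matrix()
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for row in body:
            fh.write("\t".join(f"{x:.12g}" for x in row) + "\n")


def read_scan(path, dialect: str = "matrix") -> DepthScan:
    """Read a scan file, validating header/body consistency.

    Raises :class:`ScanFormatError` on a malformed header and
    :class:`ValidationError` when the declared grid disagrees with the body.
    """
    if dialect != "matrix":
        raise ValidationError(f"unknown scan dialect {dialect!r}")
    metadata: dict[str, str] = {}
    axes: dict[str, np.ndarray] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if rows:
                    raise ScanFormatError(
                        f"{path}:{lineno}: header line after matrix body"
                    )
                stripped = line[1:].strip()
                if ":" not in stripped:
                    raise ScanFormatError(
                        f"{path}:{lineno}: header line without 'key: value'"
                    )
                key, _, value = stripped.partition(":")
                key, value = key.strip(), value.strip()
                if key in _AXIS_KEYS:
                    try:
                        axes[key] = np.array(
                            [float(x) for x in value.split(",") if x.strip()]
                        )
                    except ValueError as exc:
                        raise ScanFormatError(
                            f"{path}:{lineno}: bad numeric axis {key!r}: {exc}"
                        ) from None
                else:
                    metadata[key] = value
            else:
                try:
                    rows.append(np.array([float(x) for x in line.split("\t")]))
                except ValueError as exc:
                    raise ScanFormatError(
                        f"{path}:{lineno}: non-numeric matrix row: {exc}"
                    ) from None
    missing = [k for k in _AXIS_KEYS if k not in axes]
    if missing:
        raise ScanFormatError(f"{path}: missing axis header(s): {missing}")
    n_lat, n_dep, n_wn = (
        axes["lateral_um"].size,
        axes["depth_um"].size,
        axes["wavenumber_cm1"].size,
    )
    if len(rows) != n_lat * n_dep:
        raise ValidationError(
            f"{path}: declared grid {n_lat}x{n_dep} = {n_lat * n_dep} spectra "
            f"but body has {len(rows)} rows"
        )
    widths = {r.size for r in rows}
    if widths and widths != {n_wn}:
        raise ValidationError(
            f"{path}: spectrum length(s) {sorted(widths)} do not match the "
            f"declared {n_wn}-point wavenumber axis"
        )
    cube = np.vstack(rows).reshape(n_lat, n_dep, n_wn)
    return DepthScan(
        axis=SpectralAxis(axes["wavenumber_cm1"]),
        lateral_positions=axes["lateral_um"],
        depth_positions=axes["depth_um"],
        intensities=cube,
        metadata=metadata,
    )


def read_band_config(path) -> list[Band]:
    """Read band definitions from a YAML list of records.

    Each record must use exactly the keys name/center/window_lo/window_hi
    (assignment optional); unknown keys are rejected.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return []
    if not isinstance(doc, list):
        raise ScanFormatError(f"{path}: band config must be a YAML list of records")
    bands = []
    for i, rec in enumerate(doc):
        if not isinstance(rec, dict):
            raise ScanFormatError(f"{path}: record {i} is not a mapping")
        unknown = set(rec) - _BAND_KEYS
        if unknown:
            raise ScanFormatError(f"{path}: record {i} has unknown keys {sorted(unknown)}")
        required = {"name", "center", "window_lo", "window_hi"} - set(rec)
        if required:
            raise ScanFormatError(f"{path}: record {i} missing keys {sorted(required)}")
        bands.append(
            Band(
                name=str(rec["name"]),
                center=float(rec["center"]),
                window_lo=float(rec["window_lo"]),
                window_hi=float(rec["window_hi"]),
                assignment=str(rec.get("assignment", "")),
            )
        )
    return bands


def write_band_config(bands: list[Band], path) -> None:
    doc = [
        {
            "name": b.name,
            "center": b.center,
            "window_lo": b.window_lo,
            "window_hi": b.window_hi,
            "assignment": b.assignment,
        }
        for b in bands
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_profile_csv(profile, path, header_comment: str | None = None) -> None:
    """Write a depth profile as CSV with columns depth_um, value[, sd]."""
    import pandas as pd

    data = {"depth_um": profile.depths, "value": profile.values}
    if profile.sd is not None:
        data["sd"] = profile.sd
    frame = pd.DataFrame(data)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def write_enhancement_json(results, path, extra: dict | None = None) -> None:
    """Write enhancement results (per-time AUC pair + ratio) as JSON."""
    doc = {
        "results": [
            {
                "time_h": r.time_h,
                "auc_plain": r.auc_plain,
                "auc_enhancer": r.auc_enhancer,
                "ratio": r.ratio,
            }
            for r in results
        ]
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
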