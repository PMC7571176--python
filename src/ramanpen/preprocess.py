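"""Spectral cleanup in the acquisition pipeline's fixed order.

Three steps, applied to a whole image scan:

1. :func:`remove_cosmic_rays` — single-channel CCD spikes are uncorrelated
   between adjacent grid spectra while real Raman bands are not, so each
   intensity is compared against the median of its lateral neighbours at
   the same depth and wavenumber and replaced when it deviates by more than
   ``spike_zscore`` robust standard deviations (1.4826 × MAD).
2. :func:`subtract_background` — fluorescence baseline removal by a "shape"
   filter: morphological opening with a flat structuring element of
   ``shape_size`` spectral samples, lightly smoothed, subtracted per
   spectrum.  Narrow Raman bands survive; broad smooth backgrounds do not.
3. :func:`pca_denoise` — the scan's spectra are reconstructed from the
   first ``n_components`` principal components (default 3), discarding
   uncorrelated noise while keeping the few real sources of spectral
   variation (baseline residual, keratin matrix, drug).

:func:`preprocess_scan` chains all three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .errors import ValidationError
from .scan_io import DepthScan


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the three cleanup steps.

    spike_zscore
        robust z threshold above which a value counts as a cosmic spike.
    spike_window
        neighbourhood half-width, in adjacent spectra, for the spike median.
    shape_size
        structuring-element width of the background filter, in spectral
        samples (default 400).
    n_components
        principal components kept in the denoising reconstruction
        (default 3); must be < number of spectra in the scan.
    """

    spike_zscore: float = 8.0
    spike_window: int = 2
    shape_size: int = 400
    n_components: int = 3

    def __post_init__(self) -> None:
        if self.spike_zscore <= 0:
            raise ValidationError("spike_zscore must be > 0")
        if self.spike_window < 1:
            raise ValidationError("spike_window must be >= 1")
        if self.shape_size < 3:
            raise ValidationError("shape_size must be >= 3")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")


def _shifted(values: np.ndarray, axis: int, pad: int) -> list[np.ndarray]:
    """Neighbour slices at offsets ±1..±pad along ``axis`` (mirror-padded)."""
    n = values.shape[axis]
    pad = min(pad, n - 1)
    widths = [(0, 0)] * values.ndim
    widths[axis] = (pad, pad)
    padded = np.pad(values, widths, mode="reflect")
    out = []
    for d in range(-pad, pad + 1):
        if d == 0:
            continue
        sl = [slice(None)] * values.ndim
        sl[axis] = slice(pad + d, pad + d + n)
        out.append(padded[tuple(sl)])
    return out


def _neighbor_median(cube: np.ndarray, half_width: int) -> np.ndarray:
    """Median of each value's grid neighbours at the same channel.

    Neighbourhood: the ±half_width adjacent lateral positions at the same
    depth plus the two adjacent depth planes, excluding the value itself.
    The extra depth neighbours keep the median robust near the lateral
    edges, where mirror padding would otherwise let one spike occupy half
    the window.
    """
    stack = _shifted(cube, 0, half_width) + _shifted(cube, 1, 1)
    return np.median(np.stack(stack, axis=0), axis=0)


def remove_cosmic_rays(
    scan: DepthScan, cfg: PreprocessConfig | None = None
) -> DepthScan:
    """Replace cosmic-ray spikes by the median of neighbouring spectra.

    For every wavenumber channel, each value is compared to the median of
    its adjacent grid spectra (the ``spike_window`` neighbouring lateral
    positions at the same depth, plus the adjacent depth planes); a
    deviation beyond ``spike_zscore`` robust SDs (per channel) is replaced
    by that median.  Returns a new scan of the same shape; clean data pass
    through bit-identically.
    """
    cfg = cfg or PreprocessConfig()
    if scan.n_spectra < 3:
        raise ValidationError("cosmic-ray removal needs at least 3 spectra")
    out = scan.intensities.copy()
    floor = 1e-12 * max(float(np.max(np.abs(out))), 1.0)
    total = 0
    # A spike leaks into the neighbour medians it sits in, so one pass can
    # leave (and even create) residual outliers at the same channel of
    # adjacent positions; iterating to a fixed point removes them and makes
    # the filter idempotent.
    for _ in range(8):
        med = _neighbor_median(out, cfg.spike_window)
        resid = out - med
        # robust scale per wavenumber channel over the whole grid
        center = np.median(resid, axis=(0, 1), keepdims=True)
        mad = np.median(np.abs(resid - center), axis=(0, 1), keepdims=True)
        scale = np.maximum(1.4826 * mad, floor)
        spikes = np.abs(resid) > cfg.spike_zscore * scale
        n = int(spikes.sum())
        if n == 0:
            break
        out[spikes] = med[spikes]
        total += n
    cleaned = scan.with_intensities(out)
    cleaned.metadata["spikes_replaced"] = str(total)
    return cleaned


def _shape_baseline(spectra: np.ndarray, shape_size: int) -> np.ndarray:
    """Opening (erosion→dilation) + moving-average smooth per spectrum row."""
    opened = ndimage.grey_opening(spectra, size=(1, shape_size), mode="nearest")
    smooth_w = max(3, int(round(shape_size / 4)))
    return ndimage.uniform_filter1d(opened, size=smooth_w, axis=1, mode="nearest")


def subtract_background(
    scan: DepthScan, cfg: PreprocessConfig | None = None
) -> DepthScan:
    """Subtract a smooth "shape" baseline from every spectrum.

    The baseline is the morphological opening with a flat element of
    ``shape_size`` samples followed by a moving-average smooth of width
    ``shape_size/4`` (≥3).  Constant offsets are removed exactly; narrow
    peaks (width ≪ shape_size) are preserved.
    """
    cfg = cfg or PreprocessConfig()
    n_wn = len(scan.axis)
    if cfg.shape_size >= n_wn:
        raise ValidationError(
            f"shape_size {cfg.shape_size} must be smaller than the spectrum "
            f"length {n_wn}"
        )
    spectra = scan.spectra_matrix()
    baseline = _shape_baseline(spectra, cfg.shape_size)
    out = (spectra - baseline).reshape(scan.intensities.shape)
    return scan.with_intensities(out)


def pca_denoise(scan: DepthScan, cfg: PreprocessConfig | None = None) -> DepthScan:
    """Reconstruct every spectrum from the scan's top principal components.

    Spectra are mean-centered over the scan, projected onto the leading
    ``n_components`` eigenvectors of the spectral covariance, and rebuilt
    as mean + projection.  PCA is computed per image scan, not pooled
    across scans.
    """
    cfg = cfg or PreprocessConfig()
    X = scan.spectra_matrix()
    n = X.shape[0]
    if cfg.n_components >= n:
        raise ValidationError(
            f"n_components {cfg.n_components} must be < number of spectra {n}"
        )
    pca = PCA(n_components=cfg.n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    recon = pca.inverse_transform(scores)
    return scan.with_intensities(recon.reshape(scan.intensities.shape))


def preprocess_scan(scan: DepthScan, cfg: PreprocessConfig | None = None) -> DepthScan:
    """Full cleanup chain: cosmic rays → background → PCA denoise."""
    cfg = cfg or PreprocessConfig()
    return pca_denoise(subtract_background(remove_cosmic_rays(scan, cfg), cfg), cfg)
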