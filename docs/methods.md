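# Methods

`ramanpen` analyses in-situ confocal Raman microscopy (CRM) depth scans of
drug penetration into the stratum corneum (SC), and ships a synthetic scan
generator so the whole pipeline is testable without instrument data. This
note records the models, the numerical choices, and their limits.

## Measurement model

A depth scan is an intensity cube I(x, z, ν): lateral position x (µm),
stage depth z (µm, increasing into the sample; the scan starts above the
skin surface), Raman shift ν (cm⁻¹, nominally 501–1635). Band intensity is
assumed proportional to local molecular concentration, blurred along z by
the instrument's axial point-spread function (PSF). The drug is quantified
through the caffeine 556 cm⁻¹ band (O=C–N deformation), the skin matrix
through the keratin/phenylalanine 1008 cm⁻¹ ring-breathing band; both are
integrated over configurable windows (defaults 540–575 and 990–1025 cm⁻¹,
chosen symmetric about the band centers and clear of neighbouring skin
bands).

## Preprocessing

Order is fixed: cosmic-ray removal → background subtraction → PCA
denoising.

**Cosmic-ray removal.** CCD spikes are single-channel, single-spectrum
events, uncorrelated between adjacent grid positions, whereas Raman signal
is strongly correlated. Each value is compared with the median of its
neighbours at the same wavenumber channel — the ±`spike_window` (default 2)
adjacent lateral positions at the same depth plus the two adjacent depth
planes. Lateral neighbours share the same expected signal (composition
varies with depth, not laterally at this scale), so real depth structure
such as the skin surface cannot be mistaken for a spike; the two depth
neighbours keep the median robust at the lateral edges of the grid, where
mirror padding would otherwise let a single spike occupy half the window.
Values deviating from the neighbour median by more than `spike_zscore`
(default 8) robust standard deviations (1.4826 × MAD, per channel) are
replaced by that median. Because a spike also contaminates the medians of
the windows it sits in, detection-and-replacement is iterated to a fixed
point (≤ 8 passes; 2 suffice in practice), which also makes the filter
idempotent.

**Background ("shape") subtraction.** The fluorescence baseline is
estimated per spectrum by morphological opening — erosion then dilation
with a flat structuring element of `shape_size` spectral samples (default
400) — followed by a moving-average smooth of width `shape_size/4` (≥ 3),
and subtracted. Opening with an element much wider than any Raman band
removes the bands from the baseline estimate while following smooth
fluorescence; constants are removed exactly and the output is invariant
under adding a constant to every spectrum. The size parameter is
interpreted in spectral samples (not cm⁻¹). Known residual: on strongly
curved or steeply sloped baselines the opening can misestimate the floor
near a peak by a fraction of a percent of the peak height; the band
integrator's local linear baseline (below) absorbs this downstream.

**PCA denoising.** All spectra of one image scan are mean-centered and
reconstructed from their first `n_components` (default 3) principal
components. Three components match the scan's physical rank (fluorescence
residual, keratin matrix, drug), so uncorrelated detector noise is
discarded. PCA is computed per scan, not pooled across a time series —
pooling would let one scan's variance structure leak into another's
reconstruction; a per-series scope could be added but is not default.
With n−1 components (the rank bound after centering) the reconstruction is
the identity to 1e-8 relative, a property the tests pin.

## Depth profiles

**Band area.** Per spectrum, a local linear baseline through the window
endpoints (each anchored at the mean of the 3 outermost in-window samples)
is subtracted and the remainder integrated by the trapezoidal rule over
the window (in cm⁻¹). The local baseline makes the area robust to any
residual broad background; noise-only windows may integrate to small
negative values, which is intended and preserved.

**Lateral grouping.** The 10 lateral positions of a scan are split into 3
contiguous groups (sizes 3, 3, 4 — as equal as possible, larger groups
last) and each group is averaged laterally, yielding 3 replicate profiles
per scan and 9 per formulation with 3 scans. Contiguous grouping uses all
data and preserves spatial locality.

**Surface localization and cropping.** The scan starts ~2 µm above the
skin, so stage depth is not skin depth. The surface is the depth at which
the keratin profile first crosses half of its maximum (maximum taken after
a 3-point moving average; crossing located on the raw profile by linear
interpolation, earliest crossing wins). Profiles are then cropped to the
surface: shallower samples dropped, depths re-zeroed, and a sample
interpolated at exactly 0 if none lies within 1e-6 µm of the surface. A
profile that starts above half-maximum (scan began inside the skin) is a
detection error, not a guess. No refractive-index depth correction is
applied.

**Normalization.** The caffeine profile is divided by the arithmetic mean
of the keratin profile over the same cropped grid, compensating signal
attenuation in deeper skin. The mean is taken per replicate profile (not
per scan or per series): it ties the correction to exactly the profile it
corrects. The result is invariant to global intensity rescaling of the raw
scan to 1e-9 relative.

**Aggregation.** Replicates are linearly interpolated onto the
intersection of their depth ranges (step = median replicate step); the
mean profile carries the per-depth sample SD (ddof = 1).

## Metrics

Cumulative drug amount is the trapezoidal integral of the normalized
profile over [0, `depth_max`] µm, with a linearly interpolated endpoint;
`depth_max` defaults to 20 µm, covering the full SC (15–20 µm thick).
The enhancement ratio at a time point is the cumulative AUC with enhancer
divided by the AUC without; reported values are rounded half-up to 2
decimals. Axial resolution is the FWHM of the depth profile of a band
emitted by a thin plane (silica 521 cm⁻¹), with half-max crossings found
by linear interpolation on each side of the peak. Film thickness is the
FWHM of the plateau-shaped film-band profile — for a symmetric edge
response this equals the true width; an edge-midpoint estimator (mean of
the 25% and 75% crossings per edge) is available as an option.

## Synthetic scans

The generator emulates the three measurement situations on the study
geometry (10 × 50 spectra over 5 × 25 µm, 501–1635 cm⁻¹):

* **Skin.** Spectrum(x, z) = fluorescence baseline (broad exponential in
  ν, scaled 0.2–1.0 with the blurred skin occupancy) + keratin band ×
  A_ker(z) + nuisance skin bands (~850, 935, 1296, 1450 cm⁻¹, fractions
  of the keratin amplitude) + caffeine band × A_caf(z) + noise + spikes.
  A_ker is a step at the surface decaying as exp(−(z−z₀)/ℓ)
  (ℓ = 30 µm default); A_caf follows the erfc solution of 1-D Fickian
  diffusion from a constant-concentration (infinite-dose) boundary,
  A·erfc((z−z₀)/(2√(Dt))) — the simplest physically grounded monotone
  law for this geometry. Both are convolved with a Gaussian axial PSF
  (FWHM 1.86 µm default) on a 10×-refined grid. Bands are unit-area
  Gaussians of 8 cm⁻¹ FWHM.
* **Silica plate.** Modelled as a thin emitting plane: the 521 cm⁻¹
  profile *is* the PSF, so its FWHM is the depth resolution.
* **PET film.** The 1614 cm⁻¹ profile is a boxcar of the film thickness,
  centered in the span, convolved with the PSF.

Default magnitudes: caffeine amplitude 60, keratin 100, baseline 40,
Gaussian noise SD 0.15 (≈ 2% of the caffeine band's spectral peak height;
a Poisson option exists), spike probability 0.01 per spectrum with
amplitude 30× the spectrum maximum. The diffusion coefficient default,
4 µm²/h, is illustrative rather than a fitted literature value: it grows
the penetration front from ~5 µm after 1 h to ~20 µm after 6 h, the
qualitative course the in-situ measurements show. The enhancer is modelled
as a multiplicative factor on the caffeine amplitude and/or diffusivity.
Everything is deterministic given the seed.

**What the generator does not emulate:** Mie scattering and radiative
transfer in tissue, refraction-induced depth compression (the reason a
real 21.6 µm film reads ~0.8 µm thinner), follicular transport, lateral
heterogeneity of real skin, detector nonlinearity, wavenumber-calibration
drift. Passing recovery tests therefore demonstrates correctness of the
analysis chain under the stated forward model, not instrument-grade
validation on real tissue.

## Problem sizes and tolerances

Tests run on reduced grids (e.g. 6 × 40 spectra, 2 cm⁻¹ steps) with the
background element scaled to the spectrum length; end-to-end checks use
the full 10 × 50 × 1135 geometry with 3 scans (9 profiles) per arm — the
study's replication level. Exact contracts are asserted at 1e-8/1e-9
relative; stochastic recoveries at the widths the forward model supports:
resolution FWHM ±0.15 µm, film thickness ±0.3 µm, surface ±0.25 µm,
end-to-end enhancement ratio ±10%. `crop_to_surface` treats depths within
1e-6 µm as coincident; degenerate inputs (all-low/all-high surface
profiles, non-positive keratin means, single replicates, windows off the
axis) raise typed errors rather than returning guesses.
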