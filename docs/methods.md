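# Methods

## Photon-budget normalization and half-times

Photostability comparisons across fluorophores of different brightness use a
standardized emission-rate scale. For a fluorophore with extinction
coefficient ε (M⁻¹ cm⁻¹) at the excitation wavelength λ, quantum yield Φ and
irradiance I (W cm⁻²), the initial per-molecule emission rate is

    R₀ = Φ · σ · I·λ/(hc),   σ = 10³·ln(10)·ε/N_A  [cm²/molecule]

with CODATA-2018 exact constants in double precision. A measured trace is
normalized so its first sample is exactly 1,000 photons/s/molecule and its
time axis is multiplied by R₀/1,000; on that scale, equal times correspond to
equal numbers of photons emitted per molecule, so a bright fluorophore's raw
decay maps to a proportionally longer standardized time.

The half-time t½ is the first downward crossing of 500 photons/s/molecule,
located by linear interpolation between the bracketing samples. Curves that
never reach 500 are reported censored, not errored. Curves with an initial
photoactivation rise are still referenced to the t = 0 rate; the first
crossing below 500 is reported and a flag is set whenever the normalized rate
exceeds 1,050 at any point. Traces need not be uniformly sampled — every
operation uses explicit time stamps — and dark-recovery (shutter-closed)
experiments are represented simply as larger time gaps; no kinetic model is
fitted to them.

First-crossing detection is biased early on noisy traces: any downward noise
excursion shortly before the true crossing triggers detection. `smooth_curve`
applies a centered moving average (odd window, the t = 0 anchor preserved)
before crossing detection; with 5% multiplicative noise and an 11-sample
window the Monte-Carlo mean of recovered half-times is unbiased to within
0.2%. The window should stay a small fraction (≲2%) of the expected
half-time.

The irradiance dependence of t½ is fit by ordinary least squares of
log₁₀(t½) on log₁₀(I); the slope magnitude α, intercept c, r² and standard
errors are returned. α ≈ 1 indicates reciprocity (a fixed photon budget);
α < 1 indicates sub-linear dependence.

Molecular brightness is ε(λab)/10³ × Φ rounded to the nearest integer
(halves away from zero), matching the convention of published tables.
Extinction coefficients from alkali denaturation use the denatured
GFP-chromophore reference ε₄₄₇ = 44,000 M⁻¹ cm⁻¹ at equal concentration.

## Cellular brightness and maturation

The bicistronic assay co-expresses the test FP and mCherry at an equimolar
ratio per cell; the per-cell green/red ratio cancels expression level. The
population summary is the **median** ratio (cell-to-cell variation is heavy
tailed; the mean is provided only through the secondary field-level variant,
total green over total red). Background defaults to the mode of non-cell
pixels per channel. Cell masks are inputs (integer label images); automated
segmentation is out of scope.

Maturation time courses divide total background-subtracted fluorescence by
the transfected-cell area per frame and normalize to the series maximum.
Frames with empty masks are reported missing (NaN), never zero, so a late
start of expression does not masquerade as a measurement.

## ER-network rearrangement

Each frame is thresholded independently by Otsu's method computed on ROI
pixels only; per-frame adaptation keeps the segmented foreground area stable
(within ~5% of its mean in tests) while the movie dims two-fold by
photobleaching. The Otsu maximization is carried out in exact integer
arithmetic whenever the histogram counts are integral, so the tie rule —
lower level wins — is deterministic; pixels at or above the returned level
are foreground. A single-valued frame is flagged degenerate and carried as
all-background with a warning. An optional Gaussian pre-filter
(`smooth_sigma`, default off; 0.7 px is a good choice at SNR ≈ 10)
suppresses shot-noise pixel flips at the foreground boundary.

Movement is quantified per 16×16-pixel sub-block (blocks are small relative
to the network but larger than a tubule width) as the fraction of pixels that
flip state between consecutive frames. The denominator is the full block area
(block²), which is stable when tubules are sparse; partial edge blocks are
dropped. Blocks use 0-based row-major coordinates, block (i, j) covering
pixel rows [16i, 16i+16) and columns [16j, 16j+16). Heat maps quantize the
fractions to 0–255 integers normalized by the **global** maximum over the
whole movie, so successive heat maps are directly comparable; per-frame-pair
normalization is available behind a flag. Per-cell profiles average the
fractions over blocks covered ≥ 50% by the cell mask. The discrete
pseudo-color rendering of heat maps is presentation-only; computation always
uses the full-precision fractions.

## Kymographs and oscillation spectra

Preprocessing masks fluorescent structures (per-frame Otsu), removes
8-connected components below 20 px (connectivity configurable), and crops the
16-bit raw intensities to the mask so profile shapes are preserved. The
kymograph samples each preprocessed frame by bilinear interpolation along the
perpendicular bisector of a user-drawn axis, every 0.5 px by default, from
−L to +L around the axis midpoint. Out-of-bounds samples are clipped with a
warning.

The peak track takes the position of each row's maximum; ties are broken
toward position 0, and a tie set symmetric about 0 reports 0. A row is
"single peak" when exactly one local maximum exceeds half the row maximum,
with a 10% prominence floor so shot-noise wiggles riding one ridge are not
counted as separate peaks. All-zero rows yield missing values.

Spectra use non-overlapping rectangular windows (no taper) of 128 samples,
mean-subtracted, so the frequency axis has spacing exactly frame_rate/window
(1.05 Hz at 134.47 frames/s). Windows containing missing or ambiguous rows
are skipped, never interpolated. The magnitude spectrum is reported per
window; the dominant frequency is the largest non-DC bin of the
window-averaged spectrum. Non-power-of-two windows are accepted with a
warning.

Image FFT spectra average log₁₀|F| over radial annuli of width
0.5/min(H, W) cycles/pixel; the first few bins contain DC residue and should
be ignored when comparing resolution content.

## Synthetic data

The generators emulate the study's three kinds of raw data, each returning a
ground-truth record for recovery tests:

- **Bleaching traces**: mono-/bi-exponential or photoactivating
  (I₀(1+a(1−e^(−k_r t)))e^(−kt)) decays with multiplicative Gaussian noise;
  defaults of 5.6 W cm⁻² at 488 nm match the wide-field photobleaching
  conditions. The t = 0 sample is noise-free so the 1,000 anchor is exact.
- **Tubule movies**: Gaussian cross-section tubules (FWHM 4 px, about a
  super-resolved ER tubule width) spanning the field with static sinusoidal
  waviness, transverse oscillation A·sin(2πft+φ) guarded against aliasing at
  the Nyquist frequency, optional per-block jitter amplitudes, optional
  exponential photobleaching and a motion pause interval during which a
  frozen motion clock stops all displacement. Noise is Poisson photon noise
  plus Gaussian read noise (background 10 counts, read noise 2 counts);
  SNR is defined as tubule peak over background noise s.d. Geometry and
  noise use separate random streams, so one seed gives the same structures
  at every noise level. `pick_kymograph_axis` mirrors the experimental
  selection of an isolated tubule with stable endpoints.
- **Expression fields**: lognormal per-cell expression (log-s.d. 0.5, a
  realistic transient-transfection spread) with independent 10%
  multiplicative measurement noise per channel.

What the generators do **not** emulate: real ER topology dynamics (fusion or
fission of tubules), structured-illumination reconstruction artifacts,
spatially correlated noise, or detector nonlinearity. Passing recovery tests
therefore demonstrate correctness of the statistics under a faithful but
kinematic image model, not robustness to every property of real microscopy
data.

## Problem sizes and numerical choices

The oscillation-recovery checks run three 736-frame movies of 64×160 px at
134.47 frames/s (the full-length fast-imaging record); movement-map checks
use 120 frames at 2.6 frames/s. Binarization agreement with the known mask
at SNR 10 plateaus near 98–99%: the residual is shot-noise pixel flips in the
boundary band where the tubule profile crosses the threshold, plus the small
systematic difference between the Otsu level and the half-peak contour
(~0.4% even on noise-free frames). Heat-map quantization rounds half up;
brightness rounding is half away from zero. All numeric outputs are written
at full precision; images written for display (heat maps, kymographs) are
never read back for computation.
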