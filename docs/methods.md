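# Methods

This note documents the models, parameter choices and numerical decisions
behind `savehsi`, and states what the synthetic experiments do and do not
demonstrate.

## Colorimetry

All spectra live on a uniform wavelength grid, by default 380–780 nm at
1 nm (401 samples). Tristimulus integration uses plain rectangle sums with
Δλ equal to the grid step, consistently everywhere; at 1 nm resolution the
difference from trapezoid integration is far below every tolerance in use.

The CIE 1931 2° color-matching functions are evaluated from the
multi-lobe piecewise-Gaussian analytic fit of the standard observer
(Wyman, Sloan & Shirley, 2013) and shipped as a plain-text table
(`data/cie1931_2deg_1nm.csv`). The fit is accurate to a few parts in 10³
of the peak values; its small negative excursion of the x̄ lobe near
500 nm is clipped to zero so the functions are non-negative. Since every
quantity in the package is computed against these same functions, the
pipeline is self-consistent; absolute colorimetric accuracy against a
measured observer table is not claimed and is not needed for any result
here.

sRGB encoding/decoding follows IEC 61966-2-1 with the 7-digit matrix; the
XYZ→RGB matrix is the numerical inverse of the forward one, which makes
all 256 8-bit round trips bit-exact. Tristimulus values are scaled so the
reference white has Y = 100: `spectrum_to_xyz` applies the luminance ratio
k = 100 / Σ ȳ·S·Δλ, so the illuminant's absolute power never matters.

The Lab reference white is always computed from the active illuminant via
unit reflectance, not hard-coded: different endoscope lights imply
different whites, and this convention makes neutral patches achromatic
under any light (complete adaptation). The one exception is
`region_color_difference`, which receives already-rendered sRGB images and
therefore uses the D65 white those images are encoded against.

Out-of-gamut colors produced by rendering are clipped per channel and the
clipped fraction is reported alongside the image.

## Calibration model

The variable matrix always contains the seven core terms
[XYZ, XY, XZ, YZ, X, Y, Z]; `order=2` adds the squares, `order=3` (the
default) the remaining total-degree-3 monomials, giving the full cubic
polynomial basis in (X, Y, Z) — 19 terms — plus a trailing constant that
models the camera dark offset (20 columns). Capping the expansion at
degree 3 avoids the wild extrapolation higher orders produce from only 24
training colors. XYZ enters the expansion on the Y/100 ∈ [0, 1] scale so
the monomials are well conditioned.

All three regressions (correction matrix C, conversion matrix M) are
minimum-norm least squares via pseudoinverse with a relative
singular-value cutoff of 1e-10 — reproducible across platforms and stable
under rank deficiency. PCA uses SVD of the mean-centred spectra with a
deterministic sign convention (each component's largest-magnitude loading
is positive), so calibration is bit-reproducible. The default of 6
principal components reflects what a 24-sample fit can support and
suffices for smooth natural reflectances; it is configurable from 2 to 12.
The corrected XYZ (not the raw camera XYZ) feeds the score regression,
since it is the calibrated quantity.

Reconstructed reflectance is clipped to [0, 1] and the clipped fraction
reported.

### Exact-recovery construction

With a 3-channel camera, a generic 6-dimensional spectral family cannot be
recovered exactly — metameric spectra collapse to the same XYZ. The
exact-recovery fixture (`make_polynomial_checker`, a synthetic
construction) therefore places its 24 spectra on a 3-parameter manifold
inside a 6-dimensional smooth basis: spectra are
m + B_lin·w + B_quad·(w₁w₂, w₁w₃, w₂w₃), where the three quadratic basis
vectors are metameric blacks under the calibration light (zero
tristimulus). Patch XYZ is then linear in w, so every PCA score is a
polynomial of total degree ≤ 2 in XYZ — inside the cubic family the
regressions fit — and a noiseless colorimetric camera yields spectral RMSE
at the level of accumulated rounding (~1e-11).

## Image-scale conversion

Frames are converted per *unique* RGB triple rather than per pixel:
endoscopy-sized frames (640×480) contain far fewer unique colors than
pixels, the cache guarantees identical pixels receive identical spectra,
and exactness is preserved (unlike a precomputed quantised LUT). Cubes are
stored as float32; on disk they are written as an ENVI-style float32 BSQ
pair with wavelengths in the text header, or a compressed `.npz` with an
embedded wavelength vector.

## Narrow-band enhancement

The synthesized light is a sum of Cauchy–Lorentz bands. Five bands are
used by default, centred near 415 and 540 nm (the hemoglobin absorption
peaks that create vascular contrast) and 600, 700 and 780 nm (the
long-wavelength regions a commercial narrow-band processor passes as
browns). Band centres may move ±20 nm in optimization, widths γ span
2–60 nm, amplitudes 0–1. The Lorentzian's heavy tails keep the summed
spectrum strictly positive, so relit colors are always well defined; the
spectrum is peak-normalized to 1 because the luminance ratio k makes
absolute scale irrelevant and a canonical scale keeps profiles comparable.

The objective is the mean CIEDE2000 difference of the 24 checker patches,
rendered under the candidate light, from a target palette. In a hardware
deployment the palette would be measured from reference narrow-band
photographs of the checker; here it is produced by the fixture module from
a stated reference light (`reference_nbi_light`), through the same code
path a user-supplied reference would take. Optimization uses dual
annealing — generalized simulated annealing blending the classical and
fast (Cauchy-visiting) schedules with a local search phase — which is also
the origin of the Cauchy-Lorentz form: it serves both as the band shape
and inside the annealer's visiting distribution. Invalid parameter vectors
return a finite penalty (1e6) instead of raising, runs are reproducible
for a fixed seed, the recorded trace is the running best (hence monotone
non-increasing), and the result is never worse than the mid-bounds initial
guess.

## Metrics

* **SSIM** defaults to the single-window (global-statistics) form of the
  formula, with C₁ = (0.01·255)², C₂ = (0.03·255)², computed on Rec. 709
  luminance; a sliding Gaussian-window mode (σ = 1.5, ~11×11 support) is
  available for comparability with common practice and the mode is
  recorded in the report.
* **Entropy** is Shannon entropy (bits) of the 256-bin luminance
  histogram; the percentage difference is referenced to the first
  (white-light) image, and is therefore not symmetric.
* **PSNR** is 10·log₁₀(MAX²/MSE) with MAX = 255 for 8-bit images;
  identical images return an infinity sentinel.
* **Region color difference** converts pixels to Lab (D65), averages Lab
  within each region, and applies ΔE76 and ΔE00 to the means.
* **Paired comparison** is the classical paired t; zero-variance
  differences are flagged degenerate rather than producing a spurious
  statistic.

## Synthetic data: what it emulates, and what it does not

The checker generator produces 18 smooth chromatic reflectances (clipped
positive Gaussian mixtures) and a 6-step flat neutral ramp. Two of the
chromatic patches are skin-tone spectra — a reflective baseline attenuated
by hemoglobin-like absorption at two depths — mirroring the light/dark
skin patches of the physical 24-patch target. This matters: the PCA basis
is fitted to the checker, and without blood-tinged patches tissue spectra
fall outside its span, the reconstruction smooths away the 415/540 nm
structure, and narrow-band relighting cannot amplify what is no longer
there. With them, the basis covers the scene family and the contrast gain
appears, which is exactly the role the "majority of natural colors" plays
for the physical target.

Scenes follow a Beer–Lambert model: reflectance = reddish baseline ×
smooth multiplicative texture × exp(−depth · A(λ)), with A a two-peak
(415/540 nm, violet stronger) normalized absorbance and depth stepping
from 0.8 (mucosa) to 1.8 (lesion) inside a circular lesion; a 3-pixel
guard ring between the lesion and normal masks is left unlabelled.
Default scenes are 64×64 — large enough for stable region statistics,
small enough that the 20-scene experiment runs in seconds. The default
texture amplitude (6 %) keeps the lesion subtle, as mild esophagitis is.

Two cameras are provided: an ideal colorimetric camera (CMFs through the
sRGB matrix; small negative lobes; decodes exactly to scene XYZ) used for
exact-recovery and round-trip bounds, and a physical-style camera with
positive Gaussian sensitivities, per-channel white balance, dark offset
and code noise, used as the realistic study condition. The realistic
camera is deliberately *not* colorimetric, so re-rendering its frames
through the sRGB pipeline reproduces them only approximately (a few codes
mean error) — matching the fact that a real endoscope's color rendering is
not sRGB-exact either.

What the fixtures do **not** emulate: radiative transfer in tissue,
specular highlights, vignetting and field-of-view shading, optical blur,
compression artefacts, and inter-frame registration error. Passing the
synthetic experiments therefore shows the pipeline is correct and that the
enhancement mechanism works on spectra with hemoglobin-like structure; it
does not certify clinical image quality on real endoscopes.

## Problem sizes and tolerances

The recovery experiment uses ≤ 200 annealing iterations (the objective is
vectorized over all 24 patches and evaluates in ~0.2 ms) and reaches mean
ΔE00 well below 1; the contrast experiment uses 20 scenes with distinct
seeds. Exactness tolerances are 1e-6 to 1e-9 where algebra predicts
exact results; cross-implementation color-math agreement is asserted at
1e-4; the noisy-calibration RMSE bound (0.05) and the identity-relight
bounds (sub-code for checker mosaics under the colorimetric camera, a few
codes for tissue scenes under the realistic one) were frozen from pilot
runs of the fixture pipeline at its default settings.

## Known limitations

* The CMF table is an analytic approximation of the 2° observer (see
  above); swap in a measured table via `load_cmf` if absolute colorimetry
  matters.
* The calibration inverts only colors near the checker's manifold;
  saturated colors far outside it extrapolate poorly (clipping is
  reported, not hidden).
* Enhancement is purely spectral relighting; it does not replicate the
  edge/texture post-processing of commercial narrow-band processors.
* SSIM/PSNR comparisons require aligned, identically framed image pairs;
  no registration is performed.
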