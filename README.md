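# savehsi

Narrow-band imaging (NBI) enhances the visibility of mucosal vasculature in
endoscopy by illuminating tissue only at the hemoglobin absorption peaks
(415 nm violet, 540 nm green). Capsule endoscopes cannot carry the optical
filters that produce NBI, so `savehsi` synthesizes the effect in software:
it converts an ordinary white-light RGB frame into a per-pixel hyperspectral
reflectance cube via a color-checker calibration, then *relights* that cube
under an optimized narrow-band illuminant to produce an NBI-like image, and
quantifies the enhancement with SSIM, entropy, PSNR and CIELAB
color-difference metrics. It is aimed at researchers in endoscopic image
enhancement and spectral imaging who need a reproducible, fully synthetic
test bed for this class of pipeline.

## Method

**Calibration (RGB → spectrum).** From a 24-patch color checker with known
reflectance spectra R(λ) and camera RGB values, three least-squares stages
are fitted:

1. camera sRGB is decoded to CIE 1931 XYZ and expanded into a polynomial
   variable matrix V (the core terms [XYZ, XY, XZ, YZ, X, Y, Z], higher-order
   monomials up to total degree 3, and a constant dark term); a correction
   matrix is fitted as C = [XYZ_ref] · pinv(V);
2. mean-centred PCA of the reference spectra yields orthonormal principal
   components EV and per-patch scores;
3. a conversion matrix M = [Score] · pinv(V_color) maps the polynomial
   expansion of corrected XYZ to the PCA scores, so any color reconstructs
   as S(λ) = mean(λ) + EVᵀ · M · v(XYZ_corrected).

**Enhancement (spectral relighting).** The synthetic narrow-band light is a
sum of Cauchy–Lorentz bands f(x; x₀, γ) = (1/π)·γ/((x−x₀)² + γ²) centred
near 415, 540, 600, 700 and 780 nm. Band centres, widths and weights are
tuned by dual annealing (generalized simulated annealing with local search)
to minimize the mean CIEDE2000 difference between the 24 checker patches
rendered under the candidate light and a target palette. Enhancing a frame
is then: convert to a cube, re-render the cube under the optimized light.

**Evaluation.** SSIM, Shannon entropy (and % entropy difference), PSNR, and
the lesion-vs-normal region color difference (ΔE76 / ΔE00 between mean
region Lab colors), with a paired t summary across an image set.

Because no public endoscopy/spectrometer dataset exists for this task, the
`synthetic` module generates every input with known ground truth: checker
reflectances (including two skin-tone patches and a 6-step neutral ramp),
parametric cameras, daylight-like and narrow-band lights, and
endoscopy-like scenes whose pixel spectra follow Beer–Lambert attenuation
with hemoglobin-style 415/540 nm absorption and a deeper-absorbing lesion.

## Worked example

```python
import numpy as np
from savehsi import calibrate, enhance_image, optimize_illuminant, make_target_palette
from savehsi.colorspace import WavelengthGrid, cie_1931_cmf
from savehsi.metrics import region_color_difference
from savehsi.synthetic import (daylight_illuminant, gaussian_rgb_camera,
                               make_checker_measurements, make_endoscopy_scene,
                               reference_nbi_light, stack_spectra, SceneSpec)

grid = WavelengthGrid()                      # 380-780 nm, 1 nm, 401 samples
cmf = cie_1931_cmf(grid)
wli = daylight_illuminant(grid)
camera = gaussian_rgb_camera(grid, wli, seed=0)

ms = make_checker_measurements(0, camera, wli, cmf)
model = calibrate(ms, wli, cmf)
print(round(model.fit_report["mean_spectral_rmse"], 4))   # 0.0095

spectra = stack_spectra([m.reference_spectrum for m in ms])
target = make_target_palette(spectra, reference_nbi_light(grid), cmf)
profile = optimize_illuminant(spectra, target, grid, cmf, seed=0, max_iter=150)
print(round(profile.objective_value, 4))                  # 0.0194 mean dE00

frame, masks, _ = make_endoscopy_scene(SceneSpec(seed=100), camera, wli, cmf)
enhanced = enhance_image(frame, model, profile)
print(round(region_color_difference(frame, masks)[1], 2))     # 7.61 (WLI dE00)
print(round(region_color_difference(enhanced, masks)[1], 2))  # 9.98 (enhanced dE00)
```

The calibration reconstructs checker spectra to ~0.01 RMS reflectance, the
optimizer matches the narrow-band target palette to ~0.02 ΔE00, and the
relit frame separates the lesion from normal mucosa noticeably more
(ΔE00 9.98 vs 7.61) than the white-light frame — the contrast gain the
method exists to deliver.

The same pipeline is available as a CLI:

```bash
savehsi simulate data/ --seed 0          # checker CSV + scenes
savehsi calibrate data/checker.csv model.json
savehsi optimize data/checker.csv profile.json --seed 0
savehsi enhance data/scene_00_wli.png model.json profile.json save.png
savehsi evaluate pairs.csv report.csv
```

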