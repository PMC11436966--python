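"""Synthetic fixtures with known ground truth for the full pipeline.

Clinical endoscopy frames and spectrometer-measured checker patches are not
publicly available, so every input the pipeline needs is generated here
with its latent spectra exposed:

* smooth 24-patch checker reflectances (18 chromatic + a 6-step neutral
  ramp), plus a special checker lying exactly in the calibration model's
  polynomial family for exact-recovery experiments;
* a parametric 3-channel camera (spectral sensitivities, sRGB gamma, dark
  offset, additive code noise, optional 8-bit quantisation);
* broadband daylight-like and narrow-band reference illuminants;
* endoscopy-like scenes whose pixel spectra follow a Beer-Lambert
  attenuation with hemoglobin-style absorption peaks at 415 and 540 nm and
  a lesion region of different absorption depth.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import ColorCheckerMeasurement
from .colorspace import (
    ColorMatchingFunctions,
    DomainError,
    SRGB_TO_XYZ_MATRIX,
    Spectrum,
    WavelengthGrid,
    linear_to_srgb,
    spectrum_to_xyz,
)
from .cube import HyperspectralCube
from .enhance import CauchyBand, build_illuminant
from .metrics import RegionMaskPair

__all__ = [
    "SyntheticCamera",
    "SceneSpec",
    "daylight_illuminant",
    "reference_nbi_light",
    "make_color_checker",
    "make_polynomial_checker",
    "hemoglobin_like_absorbance",
    "render_patch",
    "render_reflectance_image",
    "make_checker_measurements",
    "make_endoscopy_scene",
    "ideal_srgb_camera",
    "gaussian_rgb_camera",
    "stack_spectra",
]


def stack_spectra(spectra: Sequence[Spectrum]) -> np.ndarray:
    """Stack a list of spectra into an (n, n_wavelengths) array."""
    return np.stack([s.values for s in spectra])


# --------------------------------------------------------------------------
# Illuminants
# --------------------------------------------------------------------------

def daylight_illuminant(grid: WavelengthGrid, temperature_k: float = 6500.0) -> Spectrum:
    """Smooth broadband daylight-like source (Planckian radiator, peak 1).

    Stands in for a white-light endoscope lamp; its white point sits close
    to D65, so rendering through an sRGB-matched camera stays in gamut.
    """
    wl = grid.wavelengths
    c2_nm_k = 1.4387768775e7  # second radiation constant, nm*K
    x = c2_nm_k / (wl * temperature_k)
    power = wl**-5.0 / np.expm1(x)
    return Spectrum(grid, power / power.max(), kind="illuminant")


#: Bands of the stated narrow-band reference light: hemoglobin peaks at
#: 415/540 nm plus weak 600/700/780 nm bands for the brown tones.
REFERENCE_NBI_BANDS = (
    CauchyBand(415.0, 12.0, 1.0),
    CauchyBand(540.0, 16.0, 0.75),
    CauchyBand(600.0, 10.0, 0.20),
    CauchyBand(700.0, 12.0, 0.12),
    CauchyBand(780.0, 12.0, 0.10),
)


def reference_nbi_light(grid: WavelengthGrid) -> Spectrum:
    """The reference narrow-band illuminant used to define target palettes."""
    return build_illuminant(list(REFERENCE_NBI_BANDS), grid)


# --------------------------------------------------------------------------
# Checker reflectances
# --------------------------------------------------------------------------

def _gaussian(wl: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


def make_color_checker(
    seed: int = 0, n_basis: int = 8, grid: WavelengthGrid | None = None
) -> list[Spectrum]:
    """24 smooth checker reflectances: 18 chromatic + 6-step neutral ramp.

    Chromatic patches are clipped positive combinations of broad wavelength
    Gaussians (smooth, natural-object-like); the first two are skin-tone
    patches — mirroring the light/dark skin patches of the physical target —
    built as Beer-Lambert hemoglobin-attenuated baselines, so the checker
    spans blood-tinged natural reflectances; the last six patches are
    spectrally flat grays at strictly increasing reflectance levels.
    """
    if n_basis < 3:
        raise DomainError("n_basis must be at least 3")
    grid = grid or WavelengthGrid()
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    centers = np.linspace(wl[0] + 20, wl[-1] - 20, n_basis)
    sigmas = rng.uniform(35.0, 80.0, size=n_basis)
    basis = np.stack([_gaussian(wl, c, s) for c, s in zip(centers, sigmas)])

    spectra: list[Spectrum] = []
    absorb = hemoglobin_like_absorbance(grid)
    skin_base = 0.25 + 0.45 / (1.0 + np.exp(-(wl - 580.0) / 40.0))
    for depth in (0.6, 1.4):  # light and dark skin-tone patches
        spectra.append(Spectrum(grid, np.clip(skin_base * np.exp(-depth * absorb), 0.0, 0.95)))
    for _ in range(16):
        weights = rng.uniform(0.0, 1.0, size=n_basis) ** 2
        values = 0.04 + weights @ basis / max(weights.sum(), 1e-9)
        spectra.append(Spectrum(grid, np.clip(values, 0.0, 0.95)))
    for level in np.linspace(0.05, 0.90, 6):
        spectra.append(Spectrum(grid, np.full(grid.n_samples, level)))
    return spectra


def make_polynomial_checker(
    seed: int = 0,
    grid: WavelengthGrid | None = None,
    illuminant: Spectrum | None = None,
    cmf: ColorMatchingFunctions | None = None,
) -> list[Spectrum]:
    """Synthetic checker whose spectra are exactly learnable by calibration.

    Construction (synthetic stand-in for a measured checker): spectra live
    in a 6-dimensional smooth basis, but on a 3-parameter manifold
    ``m + B_lin w + B_quad q(w)`` with quadratic coordinates
    ``q(w) = (w1 w2, w1 w3, w2 w3)``.  The three quadratic basis vectors are
    metameric blacks under ``illuminant`` (zero tristimulus), so patch XYZ
    is *linear* in ``w`` and every PCA score is a polynomial of total degree
    <= 2 in XYZ — inside the cubic family the calibration regressions fit.
    A noiseless colorimetric camera therefore permits exact recovery.
    """
    from .colorspace import cie_1931_cmf  # local import to avoid cycle at import time

    grid = grid or WavelengthGrid()
    cmf = cmf or cie_1931_cmf(grid)
    illuminant = illuminant or daylight_illuminant(grid)
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths

    raw = np.stack(
        [_gaussian(wl, mu, 55.0) for mu in (420, 480, 540, 600, 660, 720)]
    )
    # XYZ integration functionals under the calibration light
    T = (cmf.stacked * illuminant.values[:, None]).T  # (3, B)
    q_basis = raw[3:] - (T.T @ np.linalg.solve(T @ T.T, T @ raw[3:].T)).T  # metameric blacks
    lin_basis = raw[:3]
    lin_basis = lin_basis / np.linalg.norm(lin_basis, axis=1, keepdims=True)
    q_basis = q_basis / np.linalg.norm(q_basis, axis=1, keepdims=True)

    mean = 0.45 + 0.05 * np.cos((wl - wl[0]) / (wl[-1] - wl[0]) * np.pi)
    w = rng.uniform(-1.0, 1.0, size=(24, 3))
    q = np.stack([w[:, 0] * w[:, 1], w[:, 0] * w[:, 2], w[:, 1] * w[:, 2]], axis=1)
    values = mean + 0.9 * w @ lin_basis + 0.5 * q @ q_basis
    if values.min() < 0 or values.max() > 1:
        raise DomainError("polynomial checker amplitudes left [0, 1]")
    return [Spectrum(grid, v) for v in values]


def hemoglobin_like_absorbance(grid: WavelengthGrid) -> np.ndarray:
    """Peak-normalised absorbance shape with maxima at 415 and 540 nm.

    Two positive Gaussian peaks, the violet (Soret-like) one stronger than
    the green one — the spectral signature narrow-band lighting amplifies.
    """
    wl = grid.wavelengths
    if not (wl[0] <= 415.0 <= wl[-1]) or not (wl[0] <= 540.0 <= wl[-1]):
        raise DomainError("grid must cover the 415 and 540 nm absorption peaks")
    shape = _gaussian(wl, 415.0, 18.0) + 0.55 * _gaussian(wl, 540.0, 28.0)
    return shape / shape.max()


# --------------------------------------------------------------------------
# Cameras
# --------------------------------------------------------------------------

@dataclass
class SyntheticCamera:
    """Parametric 3-channel camera used to render fixture scenes.

    ``linear_c = integral(sens_c * S * R) / white_norm_c``; the channel is
    then sRGB gamma-encoded (if ``gamma_encode``), scaled to codes, offset
    by ``dark_offset``, perturbed by Gaussian noise of ``noise_sigma`` codes
    and finally quantised to uint8 (if ``quantize``).  Physical sensors have
    non-negative sensitivities; the ideal colorimetric camera built from the
    color-matching functions has small negative lobes and is allowed.
    """

    grid: WavelengthGrid
    sensitivities: np.ndarray  # (3, n_wavelengths)
    white_norm: np.ndarray  # (3,) linear-signal normaliser
    gamma_encode: bool = True
    dark_offset: float = 0.0
    noise_sigma: float = 0.0
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.white_norm = np.asarray(self.white_norm, dtype=float)
        if self.sensitivities.shape != (3, self.grid.n_samples):
            raise DomainError("sensitivities must be (3, n_wavelengths)")
        if np.any(self.white_norm <= 0):
            raise DomainError("white_norm must be positive")

    def linear_response(self, reflectance: np.ndarray, illuminant: Spectrum) -> np.ndarray:
        """(..., B) reflectance -> (..., 3) linear channel signal."""
        if illuminant.grid != self.grid:
            raise DomainError("camera and illuminant grids differ")
        weights = (self.sensitivities * illuminant.values).T * self.grid.step_nm
        return np.asarray(reflectance, dtype=float) @ weights / self.white_norm


def ideal_srgb_camera(
    grid: WavelengthGrid,
    cmf: ColorMatchingFunctions,
    illuminant: Spectrum,
    quantize: bool = False,
    dark_offset: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SyntheticCamera:
    """Colorimetric camera whose codes decode exactly to scene XYZ.

    Sensitivities are the color-matching functions pushed through the
    XYZ -> linear-sRGB matrix and the normaliser is the luminance integral,
    so decoding the (unquantised, noiseless) codes reproduces
    ``spectrum_to_xyz`` bit for bit.
    """
    m_inv = np.linalg.inv(SRGB_TO_XYZ_MATRIX)
    sens = m_inv @ cmf.stacked.T
    y_integral = float(np.sum(cmf.ybar * illuminant.values) * grid.step_nm)
    return SyntheticCamera(
        grid=grid,
        sensitivities=sens,
        white_norm=np.full(3, y_integral),
        gamma_encode=True,
        dark_offset=dark_offset,
        noise_sigma=noise_sigma,
        quantize=quantize,
        seed=seed,
    )


def gaussian_rgb_camera(
    grid: WavelengthGrid,
    illuminant: Spectrum,
    seed: int = 0,
    dark_offset: float = 0.0,
    noise_sigma: float = 0.0,
    quantize: bool = True,
) -> SyntheticCamera:
    """Physically-shaped camera: three positive Gaussian channel bands.

    Channel peaks near 460/540/610 nm with mild seed-dependent jitter;
    white-balanced per channel against ``illuminant`` (a gray-world camera).
    """
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    centers = np.array([460.0, 545.0, 610.0]) + rng.uniform(-8, 8, 3)
    widths = np.array([28.0, 33.0, 30.0]) * rng.uniform(0.9, 1.1, 3)
    sens = np.stack([_gaussian(wl, c, s) for c, s in zip(centers[::-1], widths[::-1])])
    # rows ordered R, G, B
    norm = (sens * illuminant.values).sum(axis=1) * grid.step_nm
    return SyntheticCamera(
        grid=grid,
        sensitivities=sens,
        white_norm=norm,
        dark_offset=dark_offset,
        noise_sigma=noise_sigma,
        quantize=quantize,
        seed=seed,
    )


def _encode(camera: SyntheticCamera, linear: np.ndarray,
            rng: np.random.Generator | None) -> np.ndarray:
    if camera.gamma_encode:
        clipped = np.clip(linear, 0.0, 1.0)
        enc = np.where(
            clipped <= 0.0031308,
            clipped * 12.92,
            1.055 * clipped ** (1.0 / 2.4) - 0.055,
        )
        codes = enc * 255.0
    else:
        codes = np.clip(linear, 0.0, 1.0) * 255.0
    codes = codes + camera.dark_offset
    if camera.noise_sigma > 0:
        rng = rng or np.random.default_rng(camera.seed)
        codes = codes + rng.normal(0.0, camera.noise_sigma, size=codes.shape)
    if camera.quantize:
        return np.clip(np.round(codes), 0, 255).astype(np.uint8)
    return np.clip(codes, 0.0, 255.0)


def render_patch(
    spectrum: Spectrum,
    illuminant: Spectrum,
    camera: SyntheticCamera,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one reflectance spectrum to a camera RGB triple."""
    linear = camera.linear_response(spectrum.values, illuminant)
    return _encode(camera, linear, rng)


def render_reflectance_image(
    reflectance: np.ndarray,
    grid: WavelengthGrid,
    illuminant: Spectrum,
    camera: SyntheticCamera,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render an (H, W, B) reflectance array to an (H, W, 3) camera image."""
    linear = camera.linear_response(reflectance, illuminant)
    return _encode(camera, linear, rng)


# --------------------------------------------------------------------------
# Measurement sets and scenes
# --------------------------------------------------------------------------

def make_checker_measurements(
    seed: int,
    camera: SyntheticCamera,
    illuminant: Spectrum,
    cmf: ColorMatchingFunctions,
    checker: Sequence[Spectrum] | None = None,
) -> list[ColorCheckerMeasurement]:
    """Complete calibration input: per-patch camera RGB + spectral reference."""
    checker = list(checker) if checker is not None else make_color_checker(seed, grid=camera.grid)
    rng = np.random.default_rng(seed)
    out = []
    for i, spec in enumerate(checker, start=1):
        rgb = render_patch(spec, illuminant, camera, rng=rng)
        out.append(
            ColorCheckerMeasurement(
                patch_id=i,
                camera_rgb=np.asarray(rgb, dtype=float),
                reference_spectrum=spec,
                reference_xyz=spectrum_to_xyz(spec, illuminant, cmf),
            )
        )
    return out


@dataclass
class SceneSpec:
    """Parameters of a two-region endoscopy-like scene.

    Absorption depths are unitless optical depths multiplying the
    hemoglobin-like absorbance shape; the lesion uses the deeper one.
    Defaults give a mild, realistically subtle lesion contrast.
    """

    height: int = 64
    width: int = 64
    mucosa_depth: float = 0.8
    lesion_depth: float = 1.8
    baseline: float = 0.65
    texture_amplitude: float = 0.06
    lesion_center: tuple[float, float] | None = None  # (row, col); default middle
    lesion_radius: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mucosa_depth < 0 or self.lesion_depth < 0:
            raise DomainError("absorption depths must be non-negative")
        center = self.lesion_center or (self.height / 2.0, self.width / 2.0)
        r, c = center
        if (
            r - self.lesion_radius < 0
            or c - self.lesion_radius < 0
            or r + self.lesion_radius > self.height
            or c + self.lesion_radius > self.width
        ):
            raise DomainError("lesion must lie fully inside the image")
        self.lesion_center = center


def make_endoscopy_scene(
    spec: SceneSpec,
    camera: SyntheticCamera,
    illuminant: Spectrum,
    cmf: ColorMatchingFunctions,
) -> tuple[np.ndarray, RegionMaskPair, HyperspectralCube]:
    """Generate a white-light frame with lesion/normal masks and true cube.

    Pixel reflectance follows a Beer-Lambert form
    ``R(x, lambda) = base(lambda) * texture(x) * exp(-depth(x) * A(lambda))``
    with ``A`` the hemoglobin-like absorbance and ``depth`` stepping up
    inside a circular lesion.  Returns the rendered camera image, disjoint
    lesion/normal masks (a guard ring between them is left unlabelled) and
    the ground-truth reflectance cube.
    """
    grid = camera.grid
    rng = np.random.default_rng(spec.seed)
    wl = grid.wavelengths

    # reddish mucosa baseline: higher reflectance at long wavelengths
    base = spec.baseline * (0.45 + 0.55 / (1.0 + np.exp(-(wl - 585.0) / 35.0)))

    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
    rc, cc = spec.lesion_center
    dist = np.hypot(rows - rc, cols - cc)
    lesion = dist <= spec.lesion_radius
    normal = dist >= spec.lesion_radius + 3.0
    depth = np.where(lesion, spec.lesion_depth, spec.mucosa_depth).astype(float)

    texture = ndimage.gaussian_filter(rng.standard_normal((spec.height, spec.width)), 4.0)
    texture = 1.0 + spec.texture_amplitude * texture / max(texture.std(), 1e-12)

    absorb = hemoglobin_like_absorbance(grid)
    refl = base[None, None, :] * texture[:, :, None] * np.exp(
        -depth[:, :, None] * absorb[None, None, :]
    )
    refl = np.clip(refl, 0.0, 1.0)

    image = render_reflectance_image(refl, grid, illuminant, camera, rng=rng)
    cube = HyperspectralCube(grid=grid, values=refl, provenance={"seed": spec.seed})
    return image, RegionMaskPair(lesion=lesion, normal=normal), cube
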