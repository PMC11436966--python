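"""Deterministic color-science primitives.

Everything downstream (calibration, relighting, metrics) is built on the
conversions in this module: sRGB transfer function, CIE 1931 XYZ tristimulus
integration, CIELAB, and the CIE76 / CIEDE2000 color-difference formulas.

Conventions
-----------
* Wavelengths are in nanometres on a uniform grid (default 380-780 nm, 1 nm).
* Tristimulus values are scaled so the reference white has ``Y = 100``.
* Reflectances are unitless in ``[0, 1]``; illuminants are relative spectral
  power, unitless and non-negative (absolute scale never matters because the
  luminance ratio ``k`` normalises it away).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "ColorMatchingFunctions",
    "DEFAULT_GRID",
    "GridMismatchError",
    "DomainError",
    "SRGB_TO_XYZ_MATRIX",
    "D65_WHITE",
    "srgb_to_linear",
    "linear_to_srgb",
    "srgb_to_xyz",
    "xyz_to_srgb",
    "spectrum_to_xyz",
    "xyz_to_lab",
    "delta_e_76",
    "delta_e_2000",
    "cie_1931_cmf",
    "load_cmf",
    "save_cmf",
    "load_spectrum_txt",
    "save_spectrum_txt",
]


class GridMismatchError(ValueError):
    """Spectra that must share a wavelength grid do not."""


class DomainError(ValueError):
    """Input outside the domain of a color transform."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid ``start_nm : step_nm : end_nm`` (inclusive)."""

    start_nm: float = 380.0
    end_nm: float = 780.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.end_nm):
            raise DomainError("grid start must be below end")
        if self.step_nm <= 0:
            raise DomainError("grid step must be positive")
        span = self.end_nm - self.start_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise DomainError("grid span must be divisible by step")

    @property
    def n_samples(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_samples)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid point nearest to ``wavelength_nm``."""
        return int(round((wavelength_nm - self.start_nm) / self.step_nm))


DEFAULT_GRID = WavelengthGrid(380.0, 780.0, 1.0)


@dataclass
class Spectrum:
    """A sampled spectrum: reflectance (in [0,1]) or relative power (>= 0)."""

    grid: WavelengthGrid
    values: np.ndarray
    kind: Literal["reflectance", "illuminant"] = "reflectance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_samples,):
            raise GridMismatchError(
                f"expected {self.grid.n_samples} samples, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DomainError("spectrum contains non-finite values")
        if self.kind == "reflectance":
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise DomainError("reflectance must lie in [0, 1]")
        elif self.values.min() < -1e-12:
            raise DomainError("illuminant power must be non-negative")


@dataclass
class ColorMatchingFunctions:
    """CIE color-matching functions sampled on a wavelength grid."""

    grid: WavelengthGrid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (self.grid.n_samples,):
                raise GridMismatchError(f"{name} does not match the grid")
            if v.min() < 0:
                raise DomainError(f"{name} must be non-negative")
            setattr(self, name, v)

    @property
    def stacked(self) -> np.ndarray:
        """(n_samples, 3) array of [xbar, ybar, zbar] columns."""
        return np.stack([self.xbar, self.ybar, self.zbar], axis=1)


# IEC 61966-2-1 sRGB primaries / D65, linear-RGB -> XYZ (Y of white = 1).
SRGB_TO_XYZ_MATRIX = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# Inverse computed numerically so encode/decode round-trips are exact.
_XYZ_TO_SRGB_MATRIX = np.linalg.inv(SRGB_TO_XYZ_MATRIX)

#: D65 white point on the Y=100 scale (row sums of the sRGB matrix).
D65_WHITE = 100.0 * SRGB_TO_XYZ_MATRIX.sum(axis=1)


def _check_rgb8(rgb8: np.ndarray) -> np.ndarray:
    arr = np.asarray(rgb8, dtype=float)
    if arr.min() < 0 or arr.max() > 255:
        raise DomainError("8-bit RGB channels must lie in [0, 255]")
    return arr


def srgb_to_linear(rgb8) -> np.ndarray:
    """Decode 8-bit sRGB codes to linear RGB in [0, 1].

    Accepts scalars, triples or image arrays with channels in the last axis.
    Float codes are allowed (a synthetic camera may skip quantisation).
    """
    arr = _check_rgb8(rgb8) / 255.0
    return np.where(arr <= 0.04045, arr / 12.92, ((arr + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(linear) -> np.ndarray:
    """Encode linear RGB to 8-bit codes; out-of-range values are clipped."""
    arr = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    enc = np.where(arr <= 0.0031308, arr * 12.92, 1.055 * arr ** (1.0 / 2.4) - 0.055)
    return np.round(enc * 255.0).astype(np.uint8)


def srgb_to_xyz(rgb8) -> np.ndarray:
    """sRGB codes -> CIE 1931 XYZ (D65), scaled so white has Y = 100."""
    linear = srgb_to_linear(rgb8)
    return 100.0 * linear @ SRGB_TO_XYZ_MATRIX.T


def xyz_to_srgb(xyz, return_clip_fraction: bool = False):
    """XYZ (Y=100 scale) -> 8-bit sRGB codes, clipping out-of-gamut values.

    With ``return_clip_fraction=True`` also returns the fraction of samples
    whose linear RGB fell outside [0, 1] before clipping.
    """
    arr = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("XYZ must be finite")
    linear = (arr / 100.0) @ _XYZ_TO_SRGB_MATRIX.T
    out_of_gamut = np.any((linear < -1e-12) | (linear > 1 + 1e-12), axis=-1)
    rgb8 = linear_to_srgb(linear)
    if return_clip_fraction:
        return rgb8, float(np.mean(out_of_gamut))
    return rgb8


def _same_grid(*grids: WavelengthGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridMismatchError(f"wavelength grids differ: {g} vs {first}")


def spectrum_to_xyz(
    reflectance, illuminant: Spectrum, cmf: ColorMatchingFunctions
) -> np.ndarray:
    """Integrate reflectance under an illuminant to XYZ tristimulus values.

    ``X = k * sum(xbar * S * R * dl)`` (similarly Y, Z) with the luminance
    ratio ``k = 100 / sum(ybar * S * dl)``, so unit reflectance always yields
    ``Y = 100`` regardless of the illuminant's absolute scale.

    ``reflectance`` may be a :class:`Spectrum` or an ``(..., n_samples)``
    array of reflectance values on the same grid.
    """
    if isinstance(reflectance, Spectrum):
        _same_grid(reflectance.grid, illuminant.grid, cmf.grid)
        refl = reflectance.values
    else:
        _same_grid(illuminant.grid, cmf.grid)
        refl = np.asarray(reflectance, dtype=float)
        if refl.shape[-1] != illuminant.grid.n_samples:
            raise GridMismatchError("reflectance array does not match the grid")
    power = illuminant.values
    dl = illuminant.grid.step_nm
    denom = float(np.sum(cmf.ybar * power) * dl)
    if denom <= 0:
        raise DomainError("illuminant carries no luminous power")
    k = 100.0 / denom
    weights = cmf.stacked * power[:, None] * dl  # (n_samples, 3)
    return k * refl @ weights


_LAB_DELTA = 6.0 / 29.0


def xyz_to_lab(xyz, white=None) -> np.ndarray:
    """XYZ -> CIELAB relative to ``white`` (default D65, Y=100 scale)."""
    arr = np.asarray(xyz, dtype=float)
    w = D65_WHITE if white is None else np.asarray(white, dtype=float)
    if np.any(w <= 0):
        raise DomainError("white point must have strictly positive components")
    t = arr / w
    f = np.where(
        t > _LAB_DELTA**3,
        np.cbrt(t),
        t / (3 * _LAB_DELTA**2) + 4.0 / 29.0,
    )
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def delta_e_76(lab1, lab2) -> np.ndarray | float:
    """CIE76 color difference: Euclidean distance in CIELAB."""
    a = np.asarray(lab1, dtype=float)
    b = np.asarray(lab2, dtype=float)
    out = np.sqrt(np.sum((a - b) ** 2, axis=-1))
    return float(out) if out.ndim == 0 else out


def delta_e_2000(lab1, lab2, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0):
    """CIEDE2000 color difference.

    Full formula with lightness, chroma and hue weighting functions and the
    blue-region rotation term; symmetric in its arguments and zero exactly
    for identical Lab coordinates.
    """
    a = np.asarray(lab1, dtype=float)
    b = np.asarray(lab2, dtype=float)
    L1, a1, b1 = a[..., 0], a[..., 1], a[..., 2]
    L2, a2, b2 = b[..., 0], b[..., 1], b[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar**7
    G = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0, 0.0, h1p)
    h2p = np.where(C2p == 0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        habs <= 180.0,
        0.5 * hsum,
        np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
    )
    hbp = np.where(C1p * C2p == 0, hsum, hbp)

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cb7 = Cbp**7
    RC = 2.0 * np.sqrt(cb7 / (cb7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -RC * np.sin(2.0 * np.radians(dtheta))

    out = np.sqrt(
        (dLp / (kL * SL)) ** 2
        + (dCp / (kC * SC)) ** 2
        + (dHp / (kH * SH)) ** 2
        + RT * (dCp / (kC * SC)) * (dHp / (kH * SH))
    )
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Color-matching function tables
# --------------------------------------------------------------------------

def _piecewise_gaussian(x: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def cie_1931_cmf(grid: WavelengthGrid = DEFAULT_GRID) -> ColorMatchingFunctions:
    """CIE 1931 2-degree standard observer on ``grid``.

    Evaluated from a multi-lobe piecewise-Gaussian analytic fit of the
    tabulated observer (accurate to a few parts in 10^3 of the peaks, ample
    for relighting and for self-consistent calibration); the tiny negative
    excursion of the fitted x-bar lobe near 500 nm is clipped to zero.
    """
    x = grid.wavelengths
    xbar = (
        1.056 * _piecewise_gaussian(x, 599.8, 37.9, 31.0)
        + 0.362 * _piecewise_gaussian(x, 442.0, 16.0, 26.7)
        - 0.065 * _piecewise_gaussian(x, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _piecewise_gaussian(x, 568.8, 46.9, 40.5) + 0.286 * _piecewise_gaussian(
        x, 530.9, 16.3, 31.1
    )
    zbar = 1.217 * _piecewise_gaussian(x, 437.0, 11.8, 36.0) + 0.681 * _piecewise_gaussian(
        x, 459.0, 26.0, 13.8
    )
    return ColorMatchingFunctions(
        grid=grid,
        xbar=np.clip(xbar, 0.0, None),
        ybar=np.clip(ybar, 0.0, None),
        zbar=np.clip(zbar, 0.0, None),
    )


def save_cmf(cmf: ColorMatchingFunctions, path) -> None:
    """Write a CMF table as plain text: wavelength, xbar, ybar, zbar."""
    data = np.column_stack([cmf.grid.wavelengths, cmf.xbar, cmf.ybar, cmf.zbar])
    np.savetxt(path, data, fmt="%.10g", header="wavelength_nm xbar ybar zbar")


def load_cmf(path) -> ColorMatchingFunctions:
    """Read a CMF table written by :func:`save_cmf`."""
    data = np.loadtxt(path)
    wl = data[:, 0]
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(wl[1] - wl[0]))
    return ColorMatchingFunctions(grid, data[:, 1], data[:, 2], data[:, 3])


def default_cmf() -> ColorMatchingFunctions:
    """The packaged CIE 1931 2-degree observer table on the default grid."""
    ref = importlib.resources.files("savehsi") / "data" / "cie1931_2deg_1nm.csv"
    with importlib.resources.as_file(ref) as path:
        return load_cmf(path)


def save_spectrum_txt(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text: wavelength, value."""
    data = np.column_stack([spectrum.grid.wavelengths, spectrum.values])
    np.savetxt(path, data, fmt="%.10g", header=f"wavelength_nm value ({spectrum.kind})")


def load_spectrum_txt(path, kind: str = "illuminant") -> Spectrum:
    """Read a two-column wavelength/value text file."""
    data = np.loadtxt(Path(path))
    wl = data[:, 0]
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(wl[1] - wl[0]))
    return Spectrum(grid, data[:, 1], kind=kind)
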