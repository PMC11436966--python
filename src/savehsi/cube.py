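"""Image-scale hyperspectral conversion: RGB raster -> reflectance cube.

A :class:`HyperspectralCube` holds per-pixel reflectance on the calibration
wavelength grid.  Conversion runs the scalar calibration path once per
*unique* RGB triple (endoscopy frames contain far fewer unique colors than
pixels), which both caches work and guarantees that identical input pixels
receive identical spectra.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import (
    CalibrationModel,
    apply_correction,
    build_variable_matrix,
    reconstruct_spectrum,
)
from .colorspace import (
    DomainError,
    GridMismatchError,
    Spectrum,
    WavelengthGrid,
    spectrum_to_xyz,
    srgb_to_xyz,
    xyz_to_srgb,
)

__all__ = ["HyperspectralCube", "convert_image", "cube_to_rgb",
           "write_envi", "read_envi", "save_cube_npz", "load_cube_npz"]


@dataclass
class HyperspectralCube:
    """H x W x B per-pixel reflectance with wavelength metadata."""

    grid: WavelengthGrid
    values: np.ndarray  # (H, W, B) float32 in [0, 1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[2] != self.grid.n_samples:
            raise GridMismatchError("cube shape does not match the wavelength grid")
        self.values = v.astype(np.float32, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _check_rgb_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DomainError(
            "expected an H x W x 3 RGB image; convert grayscale to RGB and "
            "drop alpha channels before conversion"
        )
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise DomainError("expected an 8-bit image (uint8 codes 0-255)")
    return arr


def convert_image(image, model: CalibrationModel) -> HyperspectralCube:
    """Convert an 8-bit RGB image to a hyperspectral reflectance cube.

    Per unique color: sRGB -> XYZ -> polynomial correction -> predicted PCA
    scores -> reflectance spectrum, clipped to [0, 1].
    """
    arr = _check_rgb_image(image)
    h, w, _ = arr.shape
    flat = arr.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)

    xyz = srgb_to_xyz(uniq) / 100.0
    V = build_variable_matrix(xyz, order=model.config.order)
    xyz_corr = apply_correction(model.correction, V) * 100.0
    spectra, clip_fraction = reconstruct_spectrum(
        model, xyz_corr, return_clip_fraction=True
    )

    cube = spectra[inverse].reshape(h, w, model.grid.n_samples)
    prov = {
        "source_sha1": hashlib.sha1(arr.tobytes()).hexdigest(),
        "n_unique_colors": int(uniq.shape[0]),
        "clip_fraction": clip_fraction,
    }
    return HyperspectralCube(grid=model.grid, values=cube, provenance=prov)


def cube_to_rgb(
    cube: HyperspectralCube,
    illuminant: Spectrum,
    cmf,
    return_clip_fraction: bool = False,
):
    """Render a reflectance cube under an illuminant to an 8-bit sRGB image.

    Rendering under the calibration illuminant approximates the source
    white-light image; rendering under a narrow-band illuminant produces the
    enhanced image.  Out-of-gamut pixels are clipped per channel.
    """
    if cube.grid != illuminant.grid:
        raise GridMismatchError("cube and illuminant grids differ")
    h, w, b = cube.shape
    flat = cube.values.reshape(-1, b).astype(float)
    xyz = spectrum_to_xyz(flat, illuminant, cmf)
    rgb8, clip_fraction = xyz_to_srgb(xyz, return_clip_fraction=True)
    image = rgb8.reshape(h, w, 3)
    if return_clip_fraction:
        return image, clip_fraction
    return image


# --------------------------------------------------------------------------
# On-disk containers
# --------------------------------------------------------------------------

def write_envi(cube: HyperspectralCube, stem) -> tuple[Path, Path]:
    """Write an ENVI-style pair: ``<stem>.raw`` (float32 BSQ) + ``<stem>.hdr``."""
    stem = Path(stem)
    raw = stem.with_suffix(".raw")
    hdr = stem.with_suffix(".hdr")
    h, w, b = cube.shape
    # band-sequential layout, little-endian float32
    np.ascontiguousarray(np.moveaxis(cube.values, 2, 0).astype("<f4")).tofile(raw)
    wavelengths = ", ".join(f"{v:g}" for v in cube.grid.wavelengths)
    hdr.write_text(
        "ENVI\n"
        "description = {reflectance cube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wavelengths}}}\n"
    )
    return raw, hdr


def read_envi(stem) -> HyperspectralCube:
    """Read a cube written by :func:`write_envi`."""
    stem = Path(stem)
    hdr_text = stem.with_suffix(".hdr").read_text()
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in hdr_text.splitlines():
        if "=" in line and not buf:
            key, _, val = line.partition("=")
            key = key.strip().lower()
            val = val.strip()
            if val.startswith("{") and not val.endswith("}"):
                buf = val
                continue
            fields[key] = val.strip("{}").strip()
        elif buf:
            buf += " " + line.strip()
            if line.strip().endswith("}"):
                fields[key] = buf.strip("{}").strip()
                buf = ""
    h = int(fields["lines"])
    w = int(fields["samples"])
    b = int(fields["bands"])
    if fields.get("interleave", "bsq") != "bsq" or fields.get("data type") != "4":
        raise DomainError("only float32 BSQ cubes are supported")
    wl = np.array([float(v) for v in fields["wavelength"].split(",")])
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(wl[1] - wl[0]))
    data = np.fromfile(stem.with_suffix(".raw"), dtype="<f4").reshape(b, h, w)
    return HyperspectralCube(grid=grid, values=np.moveaxis(data, 0, 2))


def save_cube_npz(cube: HyperspectralCube, path) -> None:
    """Compressed single-file container with embedded wavelength vector."""
    np.savez_compressed(
        path,
        values=cube.values,
        wavelengths=cube.grid.wavelengths,
    )


def load_cube_npz(path) -> HyperspectralCube:
    with np.load(path) as data:
        wl = data["wavelengths"]
        grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(wl[1] - wl[0]))
        return HyperspectralCube(grid=grid, values=data["values"])
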