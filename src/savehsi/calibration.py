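"""Camera-to-spectrum calibration from a 24-patch color checker.

The trained model is a three-stage stack fitted by least squares:

1. **XYZ correction** — camera sRGB is converted to XYZ, expanded into a
   polynomial variable matrix ``V`` (cross terms, higher orders, and a
   constant dark term), and regressed onto the spectrometer-referenced XYZ:
   ``C = XYZ_ref @ pinv(V)``.
2. **Spectral basis** — mean-centred PCA of the reference reflectance
   spectra yields orthonormal principal components and per-patch scores.
3. **Conversion matrix** — the scores are regressed onto the polynomial
   expansion of the corrected XYZ: ``M = Score @ pinv(V_color)``.

Reconstruction of an unseen color then runs corrected-XYZ -> expansion ->
``M`` -> scores -> mean + components^T scores, clipped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .colorspace import (
    ColorMatchingFunctions,
    DomainError,
    GridMismatchError,
    Spectrum,
    WavelengthGrid,
    spectrum_to_xyz,
    srgb_to_xyz,
)

__all__ = [
    "ColorCheckerMeasurement",
    "VariableMatrix",
    "SpectralBasis",
    "CalibrationConfig",
    "CalibrationModel",
    "build_variable_matrix",
    "fit_correction",
    "apply_correction",
    "fit_pca",
    "fit_conversion_matrix",
    "reconstruct_spectrum",
    "calibrate",
    "save_model",
    "load_model",
    "write_checker_csv",
    "read_checker_csv",
]

#: Relative singular-value cutoff used for every pseudoinverse solve.
PINV_RCOND = 1e-10

N_PATCHES = 24


@dataclass
class ColorCheckerMeasurement:
    """One checker patch: camera RGB plus spectrometer-derived references."""

    patch_id: int
    camera_rgb: np.ndarray  # (3,) codes in [0, 255]; float allowed
    reference_spectrum: Spectrum
    reference_xyz: np.ndarray  # (3,), Y=100 scale

    def __post_init__(self) -> None:
        self.camera_rgb = np.asarray(self.camera_rgb, dtype=float)
        self.reference_xyz = np.asarray(self.reference_xyz, dtype=float)


@dataclass
class VariableMatrix:
    """Polynomial expansion of per-patch XYZ values (rows = patches)."""

    values: np.ndarray  # (n_patches, n_terms)
    term_names: list[str]
    order: int


# Expansion term recipes: name -> exponent triple (i, j, k) for X^i Y^j Z^k.
_CORE_TERMS = [
    ("XYZ", (1, 1, 1)),
    ("XY", (1, 1, 0)),
    ("XZ", (1, 0, 1)),
    ("YZ", (0, 1, 1)),
    ("X", (1, 0, 0)),
    ("Y", (0, 1, 0)),
    ("Z", (0, 0, 1)),
]
_ORDER2_EXTRA = [("X2", (2, 0, 0)), ("Y2", (0, 2, 0)), ("Z2", (0, 0, 2))]
_ORDER3_EXTRA = [
    ("X2Y", (2, 1, 0)),
    ("X2Z", (2, 0, 1)),
    ("XY2", (1, 2, 0)),
    ("Y2Z", (0, 2, 1)),
    ("XZ2", (1, 0, 2)),
    ("YZ2", (0, 1, 2)),
    ("X3", (3, 0, 0)),
    ("Y3", (0, 3, 0)),
    ("Z3", (0, 0, 3)),
]


def _expansion_terms(order: int) -> list[tuple[str, tuple[int, int, int]]]:
    if order not in (1, 2, 3):
        raise DomainError("expansion order must be 1, 2 or 3")
    terms = list(_CORE_TERMS)
    if order >= 2:
        terms += _ORDER2_EXTRA
    if order >= 3:
        terms += _ORDER3_EXTRA
    terms.append(("1", (0, 0, 0)))  # constant dark term, always last
    return terms


def build_variable_matrix(xyz, order: int = 3) -> VariableMatrix:
    """Expand XYZ values (on the [0, 1] scale, i.e. Y/100) into ``V``.

    The seven core terms ``[XYZ, XY, XZ, YZ, X, Y, Z]`` are always present;
    ``order`` >= 2 adds the squares, ``order`` 3 the remaining total-degree-3
    monomials; a trailing constant models the dark offset.  With ``order=3``
    this is the full cubic polynomial basis in (X, Y, Z): 20 columns.
    """
    arr = np.atleast_2d(np.asarray(xyz, dtype=float))
    terms = _expansion_terms(order)
    X, Y, Z = arr[:, 0], arr[:, 1], arr[:, 2]
    cols = [X**i * Y**j * Z**k for _, (i, j, k) in terms]
    return VariableMatrix(
        values=np.stack(cols, axis=1),
        term_names=[name for name, _ in terms],
        order=order,
    )


def _min_norm_lstsq(targets: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares solution of ``coef @ design.T = targets``."""
    coef = targets.T @ np.linalg.pinv(design.T, rcond=PINV_RCOND)
    return coef


def fit_correction(reference_xyz, V: VariableMatrix) -> np.ndarray:
    """Fit the 3 x n_terms correction matrix ``C`` by pseudoinverse regression.

    ``reference_xyz`` is (n_patches, 3) on the [0, 1] scale.  Rank-deficient
    designs still yield the minimum-Frobenius-norm solution.
    """
    ref = np.atleast_2d(np.asarray(reference_xyz, dtype=float))
    if ref.shape[0] != V.values.shape[0]:
        raise GridMismatchError("patch counts of references and V differ")
    return _min_norm_lstsq(ref, V.values)


def apply_correction(C: np.ndarray, V: VariableMatrix | np.ndarray) -> np.ndarray:
    """Corrected XYZ = ``C @ v`` for each expansion row."""
    rows = V.values if isinstance(V, VariableMatrix) else np.atleast_2d(np.asarray(V))
    if rows.shape[-1] != C.shape[1]:
        raise GridMismatchError(
            f"expansion has {rows.shape[-1]} terms, C expects {C.shape[1]}"
        )
    return rows @ C.T


@dataclass
class SpectralBasis:
    """Mean spectrum plus orthonormal principal components of reflectance."""

    mean_spectrum: Spectrum
    components: np.ndarray  # (n_components, n_wavelengths)
    explained_variance: np.ndarray  # fraction per component, non-increasing

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def scores(self, spectra: np.ndarray) -> np.ndarray:
        """Project (..., n_wavelengths) reflectances onto the basis."""
        return (np.asarray(spectra) - self.mean_spectrum.values) @ self.components.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Inverse projection: mean + components^T scores (no clipping)."""
        return self.mean_spectrum.values + np.asarray(scores) @ self.components


def fit_pca(spectra: Sequence[Spectrum] | np.ndarray, n_components: int = 6,
            grid: WavelengthGrid | None = None) -> SpectralBasis:
    """Mean-centred PCA of reflectance spectra via SVD.

    Components are orthonormal with a deterministic sign convention (largest
    absolute loading positive).  ``explained_variance`` is the fraction of
    total centred variance per component.
    """
    if isinstance(spectra, np.ndarray):
        if grid is None:
            raise DomainError("grid required when passing a raw array")
        data = np.asarray(spectra, dtype=float)
    else:
        grid = spectra[0].grid
        for s in spectra:
            if s.grid != grid:
                raise GridMismatchError("spectra are on different grids")
        data = np.stack([s.values for s in spectra])
    n, p = data.shape
    if not (1 <= n_components <= min(n, p)):
        raise DomainError(f"n_components must be in [1, {min(n, p)}]")
    mean = data.mean(axis=0)
    centred = data - mean
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    comps = vt[:n_components]
    # deterministic sign: make each component's largest-|.| loading positive
    signs = np.sign(comps[np.arange(n_components), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    comps = comps * signs[:, None]
    total = float(np.sum(svals**2))
    if total > 0:
        explained = (svals[:n_components] ** 2) / total
    else:  # all spectra identical
        explained = np.zeros(n_components)
    return SpectralBasis(
        mean_spectrum=Spectrum(grid, np.clip(mean, 0.0, 1.0), kind="reflectance"),
        components=comps,
        explained_variance=explained,
    )


def fit_conversion_matrix(scores, V_color: VariableMatrix) -> np.ndarray:
    """Least-squares map ``M`` from color-expansion terms to PCA scores."""
    sc = np.atleast_2d(np.asarray(scores, dtype=float))
    if sc.shape[0] != V_color.values.shape[0]:
        raise GridMismatchError("patch counts of scores and V_color differ")
    return _min_norm_lstsq(sc, V_color.values)


@dataclass
class CalibrationConfig:
    order: int = 3
    n_components: int = 6

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise DomainError("order must be 1, 2 or 3")
        if not (2 <= self.n_components <= 12):
            raise DomainError("n_components must be in [2, 12]")


@dataclass
class CalibrationModel:
    """Fitted RGB-to-spectrum conversion stack."""

    correction: np.ndarray          # C, (3, n_terms)
    basis: SpectralBasis
    conversion: np.ndarray          # M, (n_components, n_terms)
    illuminant: Spectrum
    cmf: ColorMatchingFunctions
    config: CalibrationConfig
    fit_report: dict = field(default_factory=dict)

    @property
    def grid(self) -> WavelengthGrid:
        return self.basis.mean_spectrum.grid


def reconstruct_spectrum(
    model: CalibrationModel, xyz_correct, return_clip_fraction: bool = False
):
    """Predict reflectance from corrected XYZ (Y=100 scale).

    Returns an array of shape ``(..., n_wavelengths)`` clipped to [0, 1];
    optionally also the fraction of samples that required clipping.
    """
    xyz = np.asarray(xyz_correct, dtype=float) / 100.0
    single = xyz.ndim == 1
    V = build_variable_matrix(np.atleast_2d(xyz), order=model.config.order)
    scores = V.values @ model.conversion.T
    raw = model.basis.reconstruct(scores)
    clipped = float(np.mean((raw < 0) | (raw > 1)))
    out = np.clip(raw, 0.0, 1.0)
    if single:
        out = out[0]
    if return_clip_fraction:
        return out, clipped
    return out


def predict_spectrum_from_rgb(model: CalibrationModel, rgb8) -> np.ndarray:
    """Full per-color path: sRGB -> XYZ -> correction -> spectrum."""
    xyz = srgb_to_xyz(rgb8) / 100.0
    V = build_variable_matrix(np.atleast_2d(xyz), order=model.config.order)
    xyz_corr = apply_correction(model.correction, V) * 100.0
    out = reconstruct_spectrum(model, xyz_corr)
    return out[0] if np.asarray(rgb8).ndim == 1 else out


def calibrate(
    measurements: Sequence[ColorCheckerMeasurement],
    illuminant: Spectrum,
    cmf: ColorMatchingFunctions,
    config: CalibrationConfig | None = None,
) -> CalibrationModel:
    """Fit the full conversion stack from a complete 24-patch checker set.

    The fit report records per-patch XYZ RMSE before and after correction
    (on the Y=100 scale) and per-patch RMSE of the reconstructed reflectance
    spectra against their spectrometer references.
    """
    config = config or CalibrationConfig()
    if len(measurements) != N_PATCHES:
        raise DomainError(f"expected {N_PATCHES} patches, got {len(measurements)}")
    ids = sorted(m.patch_id for m in measurements)
    if ids != list(range(1, N_PATCHES + 1)):
        raise DomainError("patch_ids must be exactly 1..24")

    ms = sorted(measurements, key=lambda m: m.patch_id)
    camera_xyz = np.stack([srgb_to_xyz(m.camera_rgb) for m in ms]) / 100.0
    ref_xyz = np.stack([m.reference_xyz for m in ms]) / 100.0
    ref_spectra = np.stack([m.reference_spectrum.values for m in ms])
    grid = ms[0].reference_spectrum.grid

    V = build_variable_matrix(camera_xyz, order=config.order)
    C = fit_correction(ref_xyz, V)
    xyz_corr = apply_correction(C, V)

    basis = fit_pca(ref_spectra, n_components=config.n_components, grid=grid)
    scores = basis.scores(ref_spectra)
    V_color = build_variable_matrix(xyz_corr, order=config.order)
    M = fit_conversion_matrix(scores, V_color)

    model = CalibrationModel(
        correction=C, basis=basis, conversion=M,
        illuminant=illuminant, cmf=cmf, config=config,
    )
    recon = reconstruct_spectrum(model, xyz_corr * 100.0)
    pre_rmse = 100.0 * np.sqrt(np.mean((camera_xyz - ref_xyz) ** 2, axis=1))
    post_rmse = 100.0 * np.sqrt(np.mean((xyz_corr - ref_xyz) ** 2, axis=1))
    spec_rmse = np.sqrt(np.mean((recon - ref_spectra) ** 2, axis=1))
    model.fit_report = {
        "patch_ids": list(range(1, N_PATCHES + 1)),
        "xyz_rmse_pre_correction": pre_rmse.tolist(),
        "xyz_rmse_post_correction": post_rmse.tolist(),
        "spectral_rmse": spec_rmse.tolist(),
        "mean_xyz_rmse_pre": float(pre_rmse.mean()),
        "mean_xyz_rmse_post": float(post_rmse.mean()),
        "mean_spectral_rmse": float(spec_rmse.mean()),
    }
    return model


# --------------------------------------------------------------------------
# Serialisation
# --------------------------------------------------------------------------

def _grid_to_dict(grid: WavelengthGrid) -> dict:
    return {"start_nm": grid.start_nm, "end_nm": grid.end_nm, "step_nm": grid.step_nm}


def _grid_from_dict(d: dict) -> WavelengthGrid:
    return WavelengthGrid(d["start_nm"], d["end_nm"], d["step_nm"])


def save_model(model: CalibrationModel, path) -> None:
    """Serialise a model to a single portable JSON document."""
    doc = {
        "format": "savehsi-calibration-v1",
        "grid": _grid_to_dict(model.grid),
        "config": {"order": model.config.order,
                   "n_components": model.config.n_components},
        "correction": model.correction.tolist(),
        "mean_spectrum": model.basis.mean_spectrum.values.tolist(),
        "components": model.basis.components.tolist(),
        "explained_variance": model.basis.explained_variance.tolist(),
        "conversion": model.conversion.tolist(),
        "illuminant": model.illuminant.values.tolist(),
        "cmf": {
            "xbar": model.cmf.xbar.tolist(),
            "ybar": model.cmf.ybar.tolist(),
            "zbar": model.cmf.zbar.tolist(),
        },
        "fit_report": model.fit_report,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "savehsi-calibration-v1":
        raise DomainError(f"{path} is not a calibration model file")
    grid = _grid_from_dict(doc["grid"])
    basis = SpectralBasis(
        mean_spectrum=Spectrum(grid, np.array(doc["mean_spectrum"])),
        components=np.array(doc["components"]),
        explained_variance=np.array(doc["explained_variance"]),
    )
    return CalibrationModel(
        correction=np.array(doc["correction"]),
        basis=basis,
        conversion=np.array(doc["conversion"]),
        illuminant=Spectrum(grid, np.array(doc["illuminant"]), kind="illuminant"),
        cmf=ColorMatchingFunctions(
            grid,
            np.array(doc["cmf"]["xbar"]),
            np.array(doc["cmf"]["ybar"]),
            np.array(doc["cmf"]["zbar"]),
        ),
        config=CalibrationConfig(**doc["config"]),
        fit_report=doc["fit_report"],
    )


# --------------------------------------------------------------------------
# Checker measurement files
# --------------------------------------------------------------------------

def write_checker_csv(measurements: Sequence[ColorCheckerMeasurement], path) -> None:
    """Tabular text: patch_id, R, G, B, then one column per wavelength."""
    grid = measurements[0].reference_spectrum.grid
    wl_cols = [f"r{w:g}" for w in grid.wavelengths]
    rows = []
    for m in sorted(measurements, key=lambda m: m.patch_id):
        rows.append(
            [m.patch_id, *m.camera_rgb.tolist(), *m.reference_spectrum.values.tolist()]
        )
    df = pd.DataFrame(rows, columns=["patch_id", "R", "G", "B", *wl_cols])
    df.to_csv(path, index=False, float_format="%.10g")


def read_checker_csv(
    path, illuminant: Spectrum, cmf: ColorMatchingFunctions
) -> list[ColorCheckerMeasurement]:
    """Read a checker CSV; reference XYZ is recomputed from the spectra."""
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c.startswith("r") and c[1:2].isdigit()]
    wl = np.array([float(c[1:]) for c in wl_cols])
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(wl[1] - wl[0]))
    out = []
    for _, row in df.iterrows():
        spec = Spectrum(grid, row[wl_cols].to_numpy(dtype=float))
        out.append(
            ColorCheckerMeasurement(
                patch_id=int(row["patch_id"]),
                camera_rgb=row[["R", "G", "B"]].to_numpy(dtype=float),
                reference_spectrum=spec,
                reference_xyz=spectrum_to_xyz(spec, illuminant, cmf),
            )
        )
    return out
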