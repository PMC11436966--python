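"""Image-quality and region-contrast metrics.

Covers the evaluation battery used to judge relit endoscopy frames against
their white-light originals: SSIM, Shannon entropy (and the percentage
entropy difference), PSNR, lesion-vs-normal region color difference in
CIELAB, and a paired t summary across an image set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .colorspace import DomainError, delta_e_2000, delta_e_76, srgb_to_xyz, xyz_to_lab

__all__ = [
    "RegionMaskPair",
    "MetricsReport",
    "PairedComparison",
    "to_luminance",
    "ssim",
    "entropy",
    "entropy_difference_pct",
    "psnr",
    "region_color_difference",
    "paired_comparison",
    "compute_report",
]

#: Sentinel PSNR for identical images (MSE = 0).
PSNR_INF = math.inf

# Standard SSIM stabilising constants for 8-bit dynamic range.
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03


@dataclass
class RegionMaskPair:
    """Disjoint boolean masks marking the lesion and a normal reference region."""

    lesion: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.lesion = np.asarray(self.lesion, dtype=bool)
        self.normal = np.asarray(self.normal, dtype=bool)
        if self.lesion.shape != self.normal.shape:
            raise DomainError("masks must have the same shape")
        if not self.lesion.any() or not self.normal.any():
            raise DomainError("each region mask must be non-empty")
        if np.any(self.lesion & self.normal):
            raise DomainError("lesion and normal masks must be disjoint")


def to_luminance(image) -> np.ndarray:
    """RGB image -> float luma (Rec. 709 weights on the encoded channels)."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ np.array([0.2126, 0.7152, 0.0722])
    raise DomainError("expected a grayscale or RGB image")


def _check_same_shape(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise DomainError(f"image shapes differ: {x.shape} vs {y.shape}")


def ssim(
    img_x,
    img_y,
    data_range: float = 255.0,
    mode: str = "global",
    window_sigma: float = 1.5,
) -> float:
    """Structural similarity between two aligned images.

    Both images are reduced to luminance first.  ``mode='global'`` evaluates
    the SSIM formula

        [(2 mu_x mu_y + C1)(2 sigma_xy + C2)] /
        [(mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)]

    once over the whole frame (a single window); ``mode='gaussian'``
    averages it over sliding 11x11 Gaussian-weighted windows, the common
    practice variant.  ``C1 = (0.01 L)^2`` and ``C2 = (0.03 L)^2`` with
    ``L = data_range`` guard the near-zero denominators.
    """
    x = to_luminance(img_x)
    y = to_luminance(img_y)
    _check_same_shape(x, y)
    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2

    if mode == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x, var_y = x.var(), y.var()
        cov = ((x - mu_x) * (y - mu_y)).mean()
        num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
        den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
        return float(num / den)
    if mode == "gaussian":
        def blur(a):
            return ndimage.gaussian_filter(a, window_sigma, truncate=3.5)

        mu_x, mu_y = blur(x), blur(y)
        var_x = blur(x * x) - mu_x**2
        var_y = blur(y * y) - mu_y**2
        cov = blur(x * y) - mu_x * mu_y
        num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
        den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
        return float(np.mean(num / den))
    raise DomainError(f"unknown SSIM mode {mode!r}")


def entropy(image, levels: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram.

    Computed on the luminance channel with ``levels`` integer bins;
    ``0 * log2(0)`` contributes zero.
    """
    lum = to_luminance(image)
    if lum.size == 0:
        raise DomainError("image is empty")
    codes = np.clip(np.round(lum), 0, levels - 1).astype(int)
    counts = np.bincount(codes.ravel(), minlength=levels)
    p = counts[counts > 0] / codes.size
    return float(-np.sum(p * np.log2(p)))


def entropy_difference_pct(img_a, img_b, levels: int = 256) -> float:
    """Percentage entropy difference, referenced to the first image.

    ``100 * |H(a) - H(b)| / H(a)``; when ``H(a) = 0`` the absolute
    difference times 100 is returned.  Not symmetric in general — the first
    argument is the reference (the white-light frame, by convention).
    """
    ha = entropy(img_a, levels)
    hb = entropy(img_b, levels)
    if ha == 0.0:
        return 100.0 * abs(ha - hb)
    return 100.0 * abs(ha - hb) / ha


def psnr(img_x, img_y, max_code: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(MAX^2 / MSE)`` in dB.

    Identical images give the ``inf`` sentinel.
    """
    x = np.asarray(img_x, dtype=float)
    y = np.asarray(img_y, dtype=float)
    _check_same_shape(x, y)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return PSNR_INF
    return float(10.0 * math.log10(max_code**2 / mse))


def region_color_difference(image, masks: RegionMaskPair) -> tuple[float, float]:
    """(ΔE76, ΔE00) between the mean Lab colors of the two regions.

    Pixels are mapped sRGB -> XYZ -> Lab (D65 white), averaged per region in
    Lab, and the two color-difference formulas are applied to the means.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DomainError("expected an RGB image")
    if masks.lesion.shape != arr.shape[:2]:
        raise DomainError("masks do not match the image")
    lab = xyz_to_lab(srgb_to_xyz(arr.astype(float)))
    lesion_mean = lab[masks.lesion].mean(axis=0)
    normal_mean = lab[masks.normal].mean(axis=0)
    return (
        float(delta_e_76(lesion_mean, normal_mean)),
        float(delta_e_2000(lesion_mean, normal_mean)),
    )


@dataclass
class PairedComparison:
    """Classical paired t-test summary over aligned metric lists."""

    t: float
    p: float
    mean_difference: float
    n: int
    degenerate: bool = False


def paired_comparison(values_a: Sequence[float], values_b: Sequence[float]) -> PairedComparison:
    """Paired t on ``values_b - values_a`` (two-sided).

    Zero-variance differences cannot support a t statistic and are flagged
    ``degenerate``: identical lists report ``t=0, p=1``; a constant nonzero
    shift reports an infinite t with ``p=0``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("paired lists must have equal length")
    if a.size < 3:
        raise DomainError("at least 3 pairs are required")
    diff = b - a
    mean_d = float(diff.mean())
    if float(diff.std(ddof=1)) == 0.0:
        if mean_d == 0.0:
            return PairedComparison(0.0, 1.0, 0.0, a.size, degenerate=True)
        return PairedComparison(
            math.copysign(math.inf, mean_d), 0.0, mean_d, a.size, degenerate=True
        )
    res = stats.ttest_rel(b, a)
    return PairedComparison(float(res.statistic), float(res.pvalue), mean_d, a.size)


@dataclass
class MetricsReport:
    """Per-image-pair evaluation row (percentages on the 0-100 scale)."""

    ssim_pct: float
    entropy_a: float
    entropy_b: float
    entropy_diff_pct: float
    psnr_db: float
    de76: float | None = None
    de00: float | None = None
    ssim_mode: str = "global"

    def as_dict(self) -> dict:
        return {
            "ssim_pct": self.ssim_pct,
            "entropy_a": self.entropy_a,
            "entropy_b": self.entropy_b,
            "entropy_diff_pct": self.entropy_diff_pct,
            "psnr_db": self.psnr_db,
            "de76": self.de76,
            "de00": self.de00,
            "ssim_mode": self.ssim_mode,
        }


def compute_report(
    img_a,
    img_b,
    masks: RegionMaskPair | None = None,
    ssim_mode: str = "global",
    levels: int = 256,
) -> MetricsReport:
    """Full metric battery for one aligned image pair.

    ``img_a`` is the reference (white-light) frame, ``img_b`` the enhanced
    one.  When region masks are given, the ΔE columns report the
    lesion-vs-normal color separation measured on ``img_b``.
    """
    de76 = de00 = None
    if masks is not None:
        de76, de00 = region_color_difference(img_b, masks)
    return MetricsReport(
        ssim_pct=100.0 * ssim(img_a, img_b, mode=ssim_mode),
        entropy_a=entropy(img_a, levels),
        entropy_b=entropy(img_b, levels),
        entropy_diff_pct=entropy_difference_pct(img_a, img_b, levels),
        psnr_db=psnr(img_a, img_b),
        de76=de76,
        de00=de00,
        ssim_mode=ssim_mode,
    )
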