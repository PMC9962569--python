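"""Image-quality metrics (MSE, PSNR, SSIM) and one-vs-rest classification metrics.

Image metrics follow the super-resolution convention: intensities on the
8-bit scale (0..255) unless another bit depth is given, RGB inputs reduced
to the luminance channel.  SSIM is computed from global image statistics by
default — a single luminance/contrast/structure term over the whole image —
with an optional Gaussian-windowed variant (the form common practice uses)
for comparison.

Classification metrics operate on a K-class confusion matrix with rows as
true classes and columns as predictions, reduced one-vs-rest per class.
Undefined ratios (zero denominators) are reported as NaN, never silently
as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

logger = logging.getLogger(__name__)

__all__ = [
    "ImageQualityReport",
    "ClassMetrics",
    "to_luminance",
    "mse_image",
    "psnr",
    "ssim",
    "ssim_windowed",
    "quality_report",
    "classification_metrics",
    "macro_average",
]

#: SSIM stabilizing constants on the 8-bit scale
SSIM_C1 = (0.01 * 255.0) ** 2
SSIM_C2 = (0.03 * 255.0) ** 2

#: ITU-R BT.601 luma weights, the SR-literature convention
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ImageQualityReport:
    mse: float
    psnr_db: float  # +inf when mse == 0
    ssim: float


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class (NaN where undefined)."""
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    specificity: float


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Reduce an (H, W) or (H, W, 3) image to a 2-D luminance array."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image @ _LUMA
    return image


def _check_pair(x, y):
    x = to_luminance(x)
    y = to_luminance(y)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    return x, y


def mse_image(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared pixel difference over the H×W grid."""
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, bit_depth: int = 8) -> float:
    """Peak signal-to-noise ratio, 10·log10((2^n − 1)² / MSE), in dB."""
    m = mse_image(x, y)
    if m == 0.0:
        return float("inf")
    peak = (2 ** bit_depth - 1) ** 2
    return float(10.0 * np.log10(peak / m))


def ssim(x: np.ndarray, y: np.ndarray,
         c1: float = SSIM_C1, c2: float = SSIM_C2) -> float:
    """Structural similarity from global image statistics.

    ``(2 μx μy + C1)(2 σxy + C2) / ((μx² + μy² + C1)(σx² + σy² + C2))``;
    symmetric in its arguments and equal to 1 for identical images.
    """
    x, y = _check_pair(x, y)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = float(np.mean((x - mx) * (y - my)))
    return float((2 * mx * my + c1) * (2 * cov + c2)
                 / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


def ssim_windowed(x: np.ndarray, y: np.ndarray,
                  data_range: float = 255.0) -> float:
    """11×11 Gaussian-window SSIM (the common local-statistics variant)."""
    x, y = _check_pair(x, y)
    return float(_skimage_ssim(x, y, data_range=data_range,
                               gaussian_weights=True, sigma=1.5,
                               use_sample_covariance=False))


def quality_report(x: np.ndarray, y: np.ndarray,
                   bit_depth: int = 8) -> ImageQualityReport:
    return ImageQualityReport(mse=mse_image(x, y),
                              psnr_db=psnr(x, y, bit_depth),
                              ssim=ssim(x, y))


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting NaN", name)
        return float("nan")
    return num / den


def classification_metrics(counts: np.ndarray, class_index: int) -> ClassMetrics:
    """One-vs-rest accuracy/precision/sensitivity/F1/specificity for a class.

    ``counts[i, j]`` is the number of samples of true class ``i`` predicted
    as class ``j``.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(counts < 0):
        raise ValueError("confusion matrix counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    k = class_index
    tp = counts[k, k]
    fn = counts[k, :].sum() - tp
    fp = counts[:, k].sum() - tp
    tn = total - tp - fn - fp
    precision = _ratio(tp, tp + fp, "precision")
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    f1 = _ratio(2 * precision * sensitivity, precision + sensitivity, "f1") \
        if precision + sensitivity > 0 else float("nan")
    return ClassMetrics(
        accuracy=_ratio(tp + tn, total, "accuracy"),
        precision=precision, sensitivity=sensitivity, f1=f1,
        specificity=_ratio(tn, tn + fp, "specificity"))


def macro_average(counts: np.ndarray) -> ClassMetrics:
    """Unweighted mean of the per-class one-vs-rest metrics."""
    counts = np.asarray(counts)
    per = [classification_metrics(counts, k) for k in range(counts.shape[0])]
    mean = lambda attr: float(np.mean([getattr(m, attr) for m in per]))
    return ClassMetrics(**{a: mean(a) for a in
                           ("accuracy", "precision", "sensitivity", "f1",
                            "specificity")})
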