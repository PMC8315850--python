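"""Baseline enhancers and histogram/information quality metrics.

Histogram equalization and linear contrast stretching are the two comparison
methods; entropy, dynamic range and histogram uniformity quantify how much
gray-level information each enhancer produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .pcnn import PCNNParams, pcnn_enhance
from .util import round_half_up, validate_image


def histogram(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Exact per-level pixel counts, length ``levels``."""
    validate_image(image, levels)
    return np.bincount(image.ravel(), minlength=levels).astype(np.int64)


def entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy of a normalised histogram, in bits.

    Zero-count levels contribute nothing; an empty histogram is invalid.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise InvalidParameterError("histogram has no counts; entropy undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def hist_equalize(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Classic global histogram equalization via the CDF remap.

    Level v maps to ``round(cdf(v) * (levels - 1))`` (half up); the map is
    monotone non-decreasing, so relative ordering of levels is preserved.
    """
    counts = histogram(image, levels)
    cdf = counts.cumsum() / counts.sum()
    lut = round_half_up(cdf * (levels - 1)).astype(np.uint8)
    return lut[image]


def linear_transform(
    image: np.ndarray,
    low: int | None = None,
    high: int | None = None,
    levels: int = 256,
) -> np.ndarray:
    """Affine contrast stretch mapping low -> 0 and high -> levels-1.

    Values outside [low, high] are clipped; defaults are the image min/max.
    """
    validate_image(image, levels)
    if low is None:
        low = int(image.min())
    if high is None:
        high = int(image.max())
    if low >= high:
        raise InvalidParameterError(f"need low < high, got low={low} high={high}")
    stretched = (image.astype(float) - low) * (levels - 1) / (high - low)
    out = np.clip(round_half_up(stretched), 0, levels - 1)
    return out.astype(np.uint8)


@dataclass(frozen=True)
class EnhancementReport:
    """Quality summary of one enhancement method on one image.

    dynamic_range is (max-min)/(levels-1) in [0, 1]; uniformity is the
    chi-square distance of the histogram to the flat histogram, normalised
    to [0, 1] (0 = perfectly flat, 1 = all mass on one level).
    """

    method: str
    entropy: float
    dynamic_range: float
    uniformity: float


def _report(method: str, image: np.ndarray, levels: int) -> EnhancementReport:
    counts = histogram(image, levels)
    n = counts.sum()
    expected = n / levels
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return EnhancementReport(
        method=method,
        entropy=entropy_bits(counts),
        dynamic_range=float(image.max() - image.min()) / (levels - 1),
        uniformity=chi2 / (n * (levels - 1)),
    )


def compare_methods(
    image: np.ndarray,
    params: PCNNParams | None = None,
    levels: int = 256,
) -> list[EnhancementReport]:
    """Run all three enhancers and report metrics, ordered by method name."""
    if params is None:
        params = PCNNParams()
    validate_image(image, levels)
    enhanced = {
        "hist_eq": hist_equalize(image, levels),
        "linear": linear_transform(image, levels=levels),
        "pcnn": pcnn_enhance(image, params, levels),
    }
    return [_report(name, enhanced[name], levels) for name in sorted(enhanced)]


__all__ = [
    "EnhancementReport",
    "histogram",
    "entropy_bits",
    "hist_equalize",
    "linear_transform",
    "compare_methods",
]
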