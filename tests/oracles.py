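"""Independent reference implementations used to check the package.

Everything here is deliberately brute-force (nested loops, explicit
enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def naive_convolve3(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """3x3 sliding-window convolution with reflect padding, by explicit loops."""
    h, w = image.shape
    out = np.zeros((h, w), dtype=float)

    def reflect(idx: int, n: int) -> int:
        # single-pixel reflect (scipy 'reflect' / half-sample symmetric)
        if idx < 0:
            return -idx - 1
        if idx >= n:
            return 2 * n - idx - 1
        return idx

    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii = reflect(i + di, h)
                    jj = reflect(j + dj, w)
                    acc += kernel[1 + di, 1 + dj] * float(image[ii, jj])
            out[i, j] = acc
    return out


def laplacian_kernel(center: int) -> np.ndarray:
    k = -np.ones((3, 3), dtype=float)
    k[1, 1] = float(center)
    return k


def scalar_firing_time(
    stimulus: float, theta0: float, tau: float, max_iters: int
) -> int:
    """First iteration at which a lone neuron fires: decay then compare."""
    theta = theta0
    for m in range(1, max_iters + 1):
        theta *= math.exp(-tau)
        if stimulus > theta:
            return m
    raise AssertionError("oracle neuron did not fire within the cap")


def uncoupled_firing_times(
    image: np.ndarray,
    center: int,
    tau: float,
    stimulus_floor: float,
    max_iters: int,
) -> np.ndarray:
    """Per-pixel firing times with linking disabled, via the scalar recurrence."""
    cpg = naive_convolve3(image, laplacian_kernel(center))
    bpg = float(image.max())
    h, w = image.shape
    out = np.zeros((h, w), dtype=int)
    for i in range(h):
        for j in range(w):
            theta0 = max(bpg - cpg[i, j], stimulus_floor)
            stim = max(float(image[i, j]), stimulus_floor)
            out[i, j] = scalar_firing_time(stim, theta0, tau, max_iters)
    return out


def pairwise_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by enumerating every positive-negative pair (ties count half)."""
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def cdf_remap(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Histogram equalization by the plain CDF formula, per pixel."""
    counts = np.zeros(levels, dtype=int)
    for v in image.ravel():
        counts[v] += 1
    n = image.size
    out = np.zeros_like(image)
    for idx, v in np.ndenumerate(image):
        v = int(v)
        cdf = counts[: v + 1].sum() / n
        out[idx] = math.floor(cdf * (levels - 1) + 0.5)
    return out


def shannon_bits(values: np.ndarray) -> float:
    """Histogram entropy of integer values, independent of the package."""
    _, counts = np.unique(np.asarray(values).ravel(), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())
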