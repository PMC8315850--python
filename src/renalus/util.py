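"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

from .errors import InvalidImageError


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round with ties away from zero-point-five upward (0.5 -> 1, 1.5 -> 2).

    Used everywhere a real value maps to a gray level, for bit-exact
    cross-implementation agreement (numpy's own ``round`` is banker's).
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def validate_image(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Check a 2-D integer gray image with values in [0, levels-1].

    Returns the array unchanged; raises :class:`InvalidImageError` otherwise.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise InvalidImageError(f"expected a 2-D image, got ndim={arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidImageError(f"image dimensions must be >= 1, got {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise InvalidImageError(f"expected integer pixels, got dtype={arr.dtype}")
    if arr.min() < 0 or arr.max() > levels - 1:
        raise InvalidImageError(
            f"pixel values outside [0, {levels - 1}]: "
            f"min={arr.min()}, max={arr.max()}"
        )
    return arr


def rescale_to_levels(raw: np.ndarray, levels: int = 256) -> np.ndarray:
    """Affine min-max rescale of a real field onto [0, levels-1].

    Round half up.  A constant field maps to mid-gray ``(levels-1)//2``
    by convention (the affine map is undefined there).
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return np.full(raw.shape, (levels - 1) // 2, dtype=np.uint8)
    out = round_half_up((raw - lo) / (hi - lo) * (levels - 1))
    return out.astype(np.uint8)
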