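"""File-format plumbing: 8-bit grayscale images and the three CSV tables.

CSV dialect is fixed (comma separator, mandatory header, dot decimal, UTF-8).
Images are read from PNG/TIFF and always written as 8-bit single-channel
PNG/TIFF chosen by extension.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .clinical import DUScore, RRIRecord, SpectrumMeasurement
from .errors import InvalidImageError, RenalusError
from .util import validate_image

_COLOR_MODES = {"RGB", "RGBA", "P", "CMYK", "YCbCr", "LAB", "HSV"}


def read_gray_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale PNG/TIFF as a uint8 array.

    Color inputs are rejected with a convert-first message rather than
    silently flattened.
    """
    try:
        img = Image.open(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - PIL raises many types
        raise InvalidImageError(f"cannot read image {path}: {exc}") from exc
    if img.mode in _COLOR_MODES or img.mode == "LA":
        raise InvalidImageError(
            f"{path}: color/multi-channel input (mode {img.mode}); "
            "convert to 8-bit grayscale first"
        )
    if img.mode != "L":
        raise InvalidImageError(
            f"{path}: unsupported mode {img.mode}; expected 8-bit grayscale (L)"
        )
    arr = np.asarray(img, dtype=np.uint8)
    return validate_image(arr)


def write_gray_image(image: np.ndarray, path: str | Path) -> None:
    """Write a uint8 gray array as single-channel PNG/TIFF (by extension)."""
    validate_image(image)
    Image.fromarray(image.astype(np.uint8), mode="L").save(path)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RenalusError(f"{path}: missing required column(s) {missing}")


def read_spectra(path: str | Path) -> dict[tuple[str, int], list[SpectrumMeasurement]]:
    """Read patient_id,day,sv,dv rows grouped per patient-day, input order kept."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("patient_id", "day", "sv", "dv"), path)
    out: dict[tuple[str, int], list[SpectrumMeasurement]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.patient_id), int(row.day))
        out.setdefault(key, []).append(
            SpectrumMeasurement(sv=float(row.sv), dv=float(row.dv))
        )
    return out


def write_spectra(
    spectra: dict[tuple[str, int], list[SpectrumMeasurement]],
    path: str | Path,
) -> None:
    rows = [
        {"patient_id": pid, "day": day, "sv": m.sv, "dv": m.dv}
        for (pid, day), measures in spectra.items()
        for m in measures
    ]
    pd.DataFrame(rows, columns=["patient_id", "day", "sv", "dv"]).to_csv(
        path, index=False
    )


def read_cohort(path: str | Path) -> list[RRIRecord]:
    """Read patient_id,day,rri,aki rows as validated records."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("patient_id", "day", "rri", "aki"), path)
    return [
        RRIRecord(
            patient_id=str(row.patient_id),
            day=int(row.day),
            rri=float(row.rri),
            aki=int(row.aki),
        )
        for row in df.itertuples(index=False)
    ]


def write_cohort(records: Iterable[RRIRecord], path: str | Path) -> None:
    rows = [
        {"patient_id": r.patient_id, "day": r.day, "rri": r.rri, "aki": r.aki}
        for r in records
    ]
    pd.DataFrame(rows, columns=["patient_id", "day", "rri", "aki"]).to_csv(
        path, index=False
    )


def read_du_scores(path: str | Path) -> list[DUScore]:
    """Read patient_id,day,rater_id,score rating rows."""
    df = pd.read_csv(path)
    _require_columns(df, ("patient_id", "day", "rater_id", "score"), path)
    return [
        DUScore(
            patient_id=str(row.patient_id),
            day=int(row.day),
            rater_id=str(row.rater_id),
            score=int(row.score),
        )
        for row in df.itertuples(index=False)
    ]


def write_firing_csv(firing: np.ndarray, path: str | Path) -> None:
    """Dump a firing-time matrix as a headerless integer CSV grid."""
    np.savetxt(path, np.asarray(firing, dtype=int), fmt="%d", delimiter=",")


def write_histogram_csv(counts: np.ndarray, path: str | Path) -> None:
    """Two-column level,count export of a histogram."""
    df = pd.DataFrame(
        {"level": np.arange(len(counts)), "count": np.asarray(counts, dtype=int)}
    )
    df.to_csv(path, index=False)


__all__ = [
    "read_gray_image",
    "write_gray_image",
    "read_spectra",
    "write_spectra",
    "read_cohort",
    "write_cohort",
    "read_du_scores",
    "write_firing_csv",
    "write_histogram_csv",
]
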