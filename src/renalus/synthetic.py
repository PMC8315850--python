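"""Seeded synthetic inputs: kidney phantoms, Doppler spectra, patient cohorts.

Everything here is a pure function of its spec (seed included), so reruns are
bit-identical.  The phantom emulates a low-contrast speckled renal scan: an
elliptical kidney with cortex/medulla/sinus compartments on a dark field,
multiplicative Rayleigh speckle, and a final contrast compression into a
narrow gray band.  The cohort generator produces per-patient RRI
trajectories that drift upward over ICU days with patient-level random
intercepts and an additive AKI shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .clinical import RRIRecord, SpectrumMeasurement
from .errors import DegenerateCohortError, InvalidSpecError
from .util import round_half_up

#: Rayleigh scale with unit mean: mean = scale * sqrt(pi / 2).
_RAYLEIGH_UNIT_SCALE = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue intensities and noise of the synthetic kidney scan.

    Region mean intensities are chosen roughly a factor of two apart
    (background 4, medulla 9, cortex 19, sinus 78) so the compartments stay
    separable after speckle and compression; the compression band defaults
    to a dark 80-level range as in a low-gain ultrasound capture.
    """

    height: int = 128
    width: int = 128
    center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    axes: tuple[float, float] = (52.0, 34.0)  # (semi-major, semi-minor)
    rotation_deg: float = 25.0
    medulla_frac: float = 0.62  # medulla ellipse, as fraction of kidney axes
    sinus_frac: float = 0.30  # sinus ellipse, as fraction of kidney axes
    background_mean: float = 4.0
    medulla_mean: float = 9.0
    cortex_mean: float = 19.0
    sinus_mean: float = 78.0
    speckle_scale: float = 0.25
    band: tuple[int, int] = (2, 80)  # compressed output range
    levels: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise InvalidSpecError("frame dimensions must be >= 1")
        if not (0 <= self.band[0] < self.band[1] <= self.levels - 1):
            raise InvalidSpecError(f"invalid compression band {self.band}")
        if self.speckle_scale < 0:
            raise InvalidSpecError("speckle_scale must be >= 0")
        r = max(self.axes)
        cy, cx = self.center
        if (cy - r < 0 or cy + r > self.height - 1
                or cx - r < 0 or cx + r > self.width - 1):
            raise InvalidSpecError(
                f"kidney ellipse (radius {r}) does not fit a "
                f"{self.height}x{self.width} frame at center {self.center}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Longitudinal RRI cohort: random intercepts, daily drift, AKI shift."""

    n_patients: int = 20
    days: int = 7
    baseline_mean: float = 0.70
    between_sd: float = 0.05
    slope: float = 0.0135
    residual_sd: float = 0.02
    aki_fraction: float = 0.35
    aki_effect: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise InvalidSpecError("n_patients must be >= 2")
        if self.days < 1:
            raise InvalidSpecError("days must be >= 1")
        if not (0.0 <= self.aki_fraction <= 1.0):
            raise InvalidSpecError("aki_fraction must be in [0, 1]")
        if self.between_sd < 0 or self.residual_sd < 0:
            raise InvalidSpecError("standard deviations must be >= 0")


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation_deg: float,
) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rows - center[0]
    dx = cols - center[1]
    th = math.radians(rotation_deg)
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec | None = None) -> np.ndarray:
    """Render the speckled low-contrast kidney phantom as a gray image.

    Region means are multiplied by unit-mean Rayleigh speckle attenuated by
    ``speckle_scale`` (scale 0 leaves the piecewise-constant regions), then
    the whole field is affinely compressed into ``band`` and rounded, so the
    output dynamic range never exceeds ``band[1] - band[0]`` gray levels.
    """
    if spec is None:
        spec = PhantomSpec()
    shape = (spec.height, spec.width)
    kidney = _ellipse_mask(shape, spec.center, spec.axes, spec.rotation_deg)
    medulla = _ellipse_mask(
        shape, spec.center,
        (spec.axes[0] * spec.medulla_frac, spec.axes[1] * spec.medulla_frac),
        spec.rotation_deg,
    )
    sinus = _ellipse_mask(
        shape, spec.center,
        (spec.axes[0] * spec.sinus_frac, spec.axes[1] * spec.sinus_frac),
        spec.rotation_deg,
    )

    base = np.full(shape, spec.background_mean, dtype=float)
    base[kidney] = spec.cortex_mean
    base[medulla] = spec.medulla_mean
    base[sinus] = spec.sinus_mean

    rng = np.random.default_rng(spec.seed)
    speckle = rng.rayleigh(scale=_RAYLEIGH_UNIT_SCALE, size=shape)
    field = base * (1.0 + spec.speckle_scale * (speckle - 1.0))
    field = np.maximum(field, 0.0)

    lo, hi = float(field.min()), float(field.max())
    b0, b1 = spec.band
    if hi == lo:
        compressed = np.full(shape, (b0 + b1) / 2.0)
    else:
        compressed = b0 + (field - lo) / (hi - lo) * (b1 - b0)
    out = np.clip(round_half_up(compressed), 0, spec.levels - 1)
    return out.astype(np.uint8)


def make_doppler(
    sv_mean: float = 100.0,
    dv_mean: float = 30.0,
    cycles: int = 5,
    noise_sd: float = 5.0,
    seed: int = 0,
    min_cycles: int = 4,
    max_cycles: int = 6,
) -> list[SpectrumMeasurement]:
    """Simulate consecutive similar Doppler spectra with Gaussian jitter.

    Each cycle draws (sv, dv) around the requested means and rejection-
    resamples until 0 <= dv <= sv and sv > 0 hold.
    """
    if not (0 < dv_mean < sv_mean):
        raise InvalidSpecError(
            f"need 0 < dv_mean < sv_mean, got dv={dv_mean}, sv={sv_mean}"
        )
    if not (min_cycles <= cycles <= max_cycles):
        raise InvalidSpecError(
            f"cycles must be in [{min_cycles}, {max_cycles}], got {cycles}"
        )
    rng = np.random.default_rng(seed)
    out: list[SpectrumMeasurement] = []
    for _ in range(cycles):
        for _attempt in range(1000):
            sv = rng.normal(sv_mean, noise_sd)
            dv = rng.normal(dv_mean, noise_sd)
            if sv > 0 and 0 <= dv <= sv:
                out.append(SpectrumMeasurement(sv=sv, dv=dv))
                break
        else:
            raise InvalidSpecError(
                "could not sample a valid spectrum in 1000 attempts; "
                "noise_sd is too large for the requested means"
            )
    return out


def make_cohort(spec: CohortSpec | None = None) -> list[RRIRecord]:
    """Simulate a longitudinal RRI cohort with AKI labels.

    ``rri(p, d) = clip(b_p + slope * d + aki_p * effect + eps, 0, 1)`` with
    patient intercepts ``b_p ~ N(baseline_mean, between_sd)`` and residuals
    ``eps ~ N(0, residual_sd)``.  ``round(aki_fraction * n)`` patients get
    the positive label, assigned by a seeded permutation; a fraction giving
    zero positives or zero negatives raises :class:`DegenerateCohortError`.
    """
    if spec is None:
        spec = CohortSpec()
    n_pos = int(round(spec.aki_fraction * spec.n_patients))
    if n_pos == 0 or n_pos == spec.n_patients:
        raise DegenerateCohortError(
            f"aki_fraction={spec.aki_fraction} gives {n_pos} positives out "
            f"of {spec.n_patients} patients"
        )

    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.n_patients, dtype=int)
    labels[:n_pos] = 1
    labels = rng.permutation(labels)
    intercepts = rng.normal(spec.baseline_mean, spec.between_sd, spec.n_patients)

    records: list[RRIRecord] = []
    for p in range(spec.n_patients):
        pid = f"P{p + 1:03d}"
        for day in range(1, spec.days + 1):
            eps = rng.normal(0.0, spec.residual_sd)
            value = (
                intercepts[p]
                + spec.slope * day
                + labels[p] * spec.aki_effect
                + eps
            )
            records.append(
                RRIRecord(
                    patient_id=pid,
                    day=day,
                    rri=float(np.clip(value, 0.0, 1.0)),
                    aki=int(labels[p]),
                )
            )
    return records


__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_doppler",
    "make_cohort",
]
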