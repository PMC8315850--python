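"""Fire-once pulse-coupled neural network (PCNN) gray-image enhancement.

The enhancer is a single-layer laterally coupled neuron grid, one neuron per
pixel.  Each neuron carries a dynamic threshold initialised from a Laplacian
convolution of the input (so thresholds encode local contrast, mimicking the
Mach-band effect), decays it exponentially each iteration, and fires exactly
once when its internal activity exceeds it.  The per-pixel firing iteration
``S(i, j)`` is then mapped monotonically back to gray levels: earlier firing
means brighter output.

The whole pipeline is deterministic; there is no randomness and no training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

from .errors import InvalidImageError, InvalidParameterError, IterationCapError
from .util import rescale_to_levels, round_half_up, validate_image

log = logging.getLogger(__name__)

#: Sentinel threshold assigned to a fired neuron; exp-decay keeps it infinite,
#: so a fired neuron can never satisfy U > theta again (no re-ignition).
FIRED_SENTINEL = np.inf


def _default_linking_kernel() -> np.ndarray:
    """Uniform 3x3 neighbour weights with zero self-coupling."""
    k = np.ones((3, 3), dtype=float)
    k[1, 1] = 0.0
    return k


@dataclass(frozen=True)
class PCNNParams:
    """All constants of the pulse network and the firing-time-to-gray map.

    Parameters
    ----------
    alpha:
        Linking strength between neighbouring neurons (0 disables coupling).
    tau:
        Per-iteration exponential threshold decay constant; must be > 0.
    w_l:
        Amplitude of the linking (neighbour feedback) term.
    w_f:
        Re-excitation amplitude added to a neuron's threshold on firing.
        Retained for fidelity with the full recurrence; because fired
        neurons receive the infinite sentinel it never takes effect.
    laplacian_center:
        Centre weight of the 3x3 Laplacian used to initialise thresholds
        (all eight off-centre weights are -1).  8 gives the zero-sum kernel.
    max_iters:
        Iteration cap; exceeding it raises :class:`IterationCapError`.
    stimulus_floor:
        Positive value substituted for zero stimuli and for non-positive
        initial thresholds, guaranteeing every neuron eventually fires.
    enhance_tau:
        Decay constant of the firing-time-to-gray map (independent of the
        iteration ``tau``; both default to 0.7).
    enhance_form:
        ``"exp"`` maps raw = BPG * exp(-enhance_tau * (S - 1));
        ``"log"`` maps raw = ln(BPG) - enhance_tau * (S - 1).  The two are
        order-equivalent; only the monotone ordering survives rescaling.
    linking_kernel:
        3x3 nonnegative neighbour weights for the linking term.
    """

    alpha: float = 0.2
    tau: float = 0.7
    w_l: float = 1.0
    w_f: float = 278.0
    laplacian_center: int = 8
    max_iters: int = 64
    stimulus_floor: float = 1.0
    enhance_tau: float = 0.7
    enhance_form: str = "exp"
    linking_kernel: np.ndarray = field(default_factory=_default_linking_kernel)

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")
        if self.w_f <= 0:
            raise InvalidParameterError(f"w_f must be > 0, got {self.w_f}")
        if self.max_iters < 1:
            raise InvalidParameterError(
                f"max_iters must be >= 1, got {self.max_iters}"
            )
        if self.stimulus_floor <= 0:
            raise InvalidParameterError(
                f"stimulus_floor must be > 0, got {self.stimulus_floor}"
            )
        if self.enhance_tau <= 0:
            raise InvalidParameterError(
                f"enhance_tau must be > 0, got {self.enhance_tau}"
            )
        if self.enhance_form not in ("exp", "log"):
            raise InvalidParameterError(
                f"enhance_form must be 'exp' or 'log', got {self.enhance_form!r}"
            )
        kern = np.asarray(self.linking_kernel, dtype=float)
        if kern.shape != (3, 3) or (kern < 0).any():
            raise InvalidParameterError("linking_kernel must be 3x3 nonnegative")
        object.__setattr__(self, "linking_kernel", kern)


def laplacian_convolve(image: np.ndarray, center: int = 8) -> np.ndarray:
    """Convolve with the 3x3 Laplacian (off-centre weights -1), reflect padding.

    Output is real-valued and deliberately not clamped.
    """
    validate_image(image)
    kernel = -np.ones((3, 3), dtype=float)
    kernel[1, 1] = float(center)
    return convolve(image.astype(float), kernel, mode="reflect")


def init_thresholds(image: np.ndarray, params: PCNNParams) -> np.ndarray:
    """Initial dynamic thresholds: brightest input pixel minus convolved gray.

    Each entry is ``BPG - CPG(i, j)`` with BPG the maximum of the *original*
    input and CPG the Laplacian-convolved value, clamped below at
    ``stimulus_floor`` so every threshold is finite and positive (the raw
    difference can be non-positive wherever the convolution overshoots).
    """
    validate_image(image)
    bpg = float(image.max())
    cpg = laplacian_convolve(image, params.laplacian_center)
    return np.maximum(bpg - cpg, params.stimulus_floor)


def run_pcnn(image: np.ndarray, params: PCNNParams | None = None) -> np.ndarray:
    """Run the synchronous fire-once iteration; return the firing-time matrix.

    Per iteration m = 1, 2, ...:

    1. every unfired threshold decays, ``theta <- exp(-tau) * theta``
       (fired neurons hold the infinite sentinel; the ``w_f * Y`` term of the
       recurrence is applied but is inert against the sentinel);
    2. the linking term is ``R = w_l * sum(V * Y[m-1])`` over the 3x3
       neighbourhood, reflect-padded;
    3. internal activity ``U = F * (1 + alpha * R)`` with feed F the
       floor-clamped pixel intensity, constant across iterations;
    4. a neuron fires when ``U > theta``; its firing time ``S = m`` is
       recorded and its threshold becomes the sentinel.

    The loop ends when all neurons have fired; hitting ``max_iters`` with
    unfired neurons raises :class:`IterationCapError` naming their count.
    """
    if params is None:
        params = PCNNParams()
    validate_image(image)

    feed = np.maximum(image.astype(float), params.stimulus_floor)
    theta = init_thresholds(image, params)
    firing = np.zeros(image.shape, dtype=np.int64)
    y = np.zeros(image.shape, dtype=float)
    fired = np.zeros(image.shape, dtype=bool)
    decay = math.exp(-params.tau)

    for m in range(1, params.max_iters + 1):
        theta = decay * theta + params.w_f * y
        link = params.w_l * convolve(y, params.linking_kernel, mode="reflect")
        activity = feed * (1.0 + params.alpha * link)
        fire = (activity > theta) & ~fired
        firing[fire] = m
        theta[fire] = FIRED_SENTINEL
        fired |= fire
        y = fire.astype(float)
        log.debug("iteration %d: %d neuron(s) fired", m, int(fire.sum()))
        if fired.all():
            return firing

    raise IterationCapError(int((~fired).sum()), params.max_iters)


def enhance(
    image: np.ndarray,
    firing: np.ndarray,
    params: PCNNParams | None = None,
    levels: int = 256,
) -> np.ndarray:
    """Map firing times to an enhanced gray image (earlier = brighter).

    ``raw = BPG * exp(-enhance_tau * (S - 1))`` (or the logarithmic variant),
    strictly decreasing in S, then affinely rescaled to span the full
    [0, levels-1] range with half-up rounding.  A single shared firing time
    degenerates to constant mid-gray.
    """
    if params is None:
        params = PCNNParams()
    validate_image(image, levels)
    firing = np.asarray(firing)
    if firing.shape != image.shape:
        raise InvalidImageError(
            f"firing shape {firing.shape} != image shape {image.shape}"
        )
    if (firing < 1).any():
        raise InvalidImageError("firing times must all be >= 1")
    bpg = float(image.max())
    if bpg <= 0:
        raise InvalidImageError("brightest pixel must be positive to enhance")

    steps = firing.astype(float) - 1.0
    if params.enhance_form == "exp":
        raw = bpg * np.exp(-params.enhance_tau * steps)
    else:  # "log"
        raw = math.log(bpg) - params.enhance_tau * steps
    return rescale_to_levels(raw, levels)


def pcnn_enhance(
    image: np.ndarray,
    params: PCNNParams | None = None,
    levels: int = 256,
) -> np.ndarray:
    """Full pipeline: thresholds -> fire-once iteration -> gray remap."""
    if params is None:
        params = PCNNParams()
    return enhance(image, run_pcnn(image, params), params, levels)


__all__ = [
    "FIRED_SENTINEL",
    "PCNNParams",
    "laplacian_convolve",
    "init_thresholds",
    "run_pcnn",
    "enhance",
    "pcnn_enhance",
    "round_half_up",
]
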