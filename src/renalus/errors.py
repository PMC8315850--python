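"""Exception hierarchy for renalus.

Every anticipated failure raises a subclass of :class:`RenalusError`, so the
CLI can distinguish domain errors (exit 1) from usage errors (exit 2).
"""


class RenalusError(Exception):
    """Base class for all anticipated renalus failures."""


class InvalidImageError(RenalusError):
    """Input is not a valid 8-bit single-channel grayscale image."""


class InvalidParameterError(RenalusError):
    """A parameter violates its documented constraints."""


class IterationCapError(RenalusError):
    """The pulse network hit the iteration cap with neurons still unfired."""

    def __init__(self, unfired: int, max_iters: int):
        self.unfired = unfired
        self.max_iters = max_iters
        super().__init__(
            f"{unfired} neuron(s) unfired after {max_iters} iterations; "
            f"raise max_iters or check the stimulus floor"
        )


class InvalidMeasurementError(RenalusError):
    """A Doppler spectrum measurement violates 0 <= dv <= sv, sv > 0."""


class InsufficientSpectraError(RenalusError):
    """Fewer spectra than the configured minimum for a daily average."""

    def __init__(self, count: int, minimum: int, maximum: int):
        self.count = count
        super().__init__(
            f"got {count} spectra; between {minimum} and {maximum} required"
        )


class DegenerateDesignError(RenalusError):
    """Longitudinal design has no within-patient day variation."""


class UndefinedAUCError(RenalusError):
    """ROC requested on single-class data; AUC is undefined."""


class InvalidSpecError(RenalusError):
    """A synthetic-data specification is internally inconsistent."""


class DegenerateCohortError(RenalusError):
    """Simulated cohort would contain no positives or no negatives."""
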