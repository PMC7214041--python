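"""Exception hierarchy shared across the package.

Domain errors (states a valid pipeline can reach on bad cohorts) are kept
distinct from format/configuration errors so the CLI can map them to
different exit codes.
"""


class PolarLabelError(Exception):
    """Base class for all package errors."""


class FormatError(PolarLabelError):
    """Malformed tabular input (bad header, negative count, unknown label...)."""


class ConfigurationError(PolarLabelError):
    """Invalid parameter combination supplied by the caller."""


class DomainError(PolarLabelError):
    """A valid computation reached a cohort state it cannot proceed from."""


class EmptyPoleError(DomainError):
    """No patient reaches the pole required by the algorithm step.

    Raised when a cohort has no potential silver positives (nobody carries
    the disease code) or when the high-pole cut-off excludes every patient.
    """


class CapacityError(DomainError):
    """Requested train size exceeds the balanced silver set under strict mode."""

    def __init__(self, requested: int, available: int):
        self.requested = requested
        self.available = available
        super().__init__(
            f"requested train size {requested} exceeds the {available} "
            f"patients available in the balanced silver set"
        )


class DegenerateLabelsError(DomainError):
    """Training or scoring labels contain a single class."""


class CohortSizeError(DomainError):
    """Gold cohort too small to admit both classes in both split halves."""
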