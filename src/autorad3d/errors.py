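"""Exception hierarchy for the processing chain.

Every stage raises a subclass of :class:`AutoradError` so that the pipeline
driver can attach subject/section context while re-raising.
"""


class AutoradError(Exception):
    """Base class for all errors raised by this package."""


class InvalidSpecError(AutoradError):
    """A phantom specification violates its invariants."""


class DegenerateHistogramError(AutoradError):
    """All histogram mass sits in a single bin; no threshold exists."""


class EmptyMaskError(AutoradError):
    """Cleaning produced an empty foreground for a section."""

    def __init__(self, index: int, message: str | None = None):
        self.index = index
        super().__init__(message or f"empty mask after cleaning section {index}")


class HeterogeneousSectionsError(AutoradError):
    """Sections to be stacked disagree in shape or in-plane spacing."""


class UndefinedCorrelationError(AutoradError):
    """NCC is undefined: zero variance inside the joint mask."""


class TooFewStandardsError(AutoradError):
    """Fewer than four calibration standards were supplied."""


class InvalidStandardsError(AutoradError):
    """Calibration standards are not strictly monotone or contain duplicates."""


class OutOfRangeError(AutoradError):
    """Pixels fall outside the calibration range under the 'error' policy."""

    def __init__(self, count: int):
        self.count = count
        super().__init__(f"{count} pixel(s) outside the calibration range")


class InvalidGridError(AutoradError):
    """A B-spline control grid is too fine for the volume it must cover."""


class RegistrationError(AutoradError):
    """An optimizer stalled or a registration precondition failed."""


class DependencyError(AutoradError):
    """A pipeline step was requested before its prerequisite step ran."""


class ConfigError(AutoradError):
    """A study configuration file is malformed or references missing paths."""
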