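"""Exception hierarchy for the anonymization pipeline."""


class CurveAnonError(Exception):
    """Base class for all package-specific errors."""


class CurveFormatError(CurveAnonError, ValueError):
    """A curve CSV file violates the expected dialect (header or rows)."""


class CurveValidationError(CurveAnonError, ValueError):
    """A curve violates a structural invariant (monotone time, length)."""


class AlignmentError(CurveAnonError, ValueError):
    """Curves are not on a common time frame where one is required."""


class SplitError(CurveAnonError, ValueError):
    """A segmentation request is invalid or unachievable."""


class InfeasibleAnonymizationError(CurveAnonError, RuntimeError):
    """The dataset cannot be anonymized under the given constraints,
    e.g. fewer than k curves, or no releasable equivalence class."""
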