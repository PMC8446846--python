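"""Exception and warning types shared across the package."""


class FescomError(Exception):
    """Base class for all package errors."""


class FormatError(FescomError):
    """A file does not conform to the expected layout (e.g. missing channel column)."""


class ValidationError(FescomError):
    """Data violates an invariant (non-finite values, out-of-range annotation, ...)."""


class ParameterError(FescomError, ValueError):
    """A parameter is outside its admissible range."""


class SampleSizeError(FescomError):
    """A statistical operation received fewer samples than it requires."""


class StratificationError(FescomError):
    """A class is too small to be represented in every fold / partition."""


class EmptyCandidateSetError(FescomError):
    """The filter stage rejected every feature; raise the threshold."""


class DegenerateSignalWarning(UserWarning):
    """Emitted when a zero-variance signal forces the degenerate feature convention."""


class DegenerateTestWarning(UserWarning):
    """Emitted when a two-sample test is degenerate (both samples constant and equal)."""
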