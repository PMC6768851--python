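"""Exception hierarchy.

Two branches: :class:`InputError` for malformed inputs / parameters /
file formats (CLI exit code 2) and :class:`AnalysisError` for analyses
that cannot proceed on valid input (CLI exit code 3).
"""


class MotilityError(Exception):
    """Base class for all package errors."""


class InputError(MotilityError):
    """Invalid input data or parameters."""


class ParameterError(InputError):
    """A simulation or analysis parameter violates its invariant."""


class FormatError(InputError):
    """A file on disk does not match the expected format."""


class AnalysisError(MotilityError):
    """Analysis failed on structurally valid input."""


class BimodalityNotFound(AnalysisError):
    """The structure histogram does not contain two qualifying peaks."""


class InsufficientDataError(AnalysisError):
    """Too few observations for the requested estimate."""


class NormalizationError(AnalysisError):
    """Normalization reference is degenerate (e.g. zero-mean controls)."""
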