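"""Exception hierarchy for the ceprobe pipeline."""


class CeprobeError(Exception):
    """Base class for all ceprobe errors."""


class FormatError(CeprobeError):
    """A file is empty, truncated or otherwise not parseable."""


class DialectError(FormatError):
    """The input table matches neither supported peak-table dialect."""


class ValidationError(CeprobeError):
    """Input data violate a structural contract (duplicates, mismatched lengths...)."""


class SequenceError(ValidationError):
    """The provided sequence is not RNA or is too short for the probing data."""


class InsufficientDataError(CeprobeError):
    """Too few reliable reactivities to normalize or test."""


class NonPositiveScaleError(CeprobeError):
    """The effective maximum reactivity is not positive; profile cannot be scaled."""


class DependencyError(CeprobeError):
    """A required external executable is not available."""


class ExternalToolError(CeprobeError):
    """An external tool exited with a failure status."""


class PseudoknotError(CeprobeError):
    """A pair set contains crossing pairs and cannot be written as plain dot-bracket."""
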