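"""Exception hierarchy for the metintegrate pipeline."""


class MetIntegrateError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(MetIntegrateError, ValueError):
    """A function argument violates its documented precondition."""


class InvalidInputError(MetIntegrateError, ValueError):
    """Input data violates a structural requirement (group sizes, labels...)."""


class FormatError(MetIntegrateError, ValueError):
    """A file does not parse under the declared dialect."""


class MergeError(MetIntegrateError, ValueError):
    """Cohorts cannot be merged (e.g. empty gene intersection)."""
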