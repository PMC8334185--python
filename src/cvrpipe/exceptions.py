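"""Error taxonomy used across the pipeline.

All exceptions derive from ``ValueError`` so callers that do not care about
the fine distinction can catch a single base class.
"""


class CvrPipeError(ValueError):
    """Base class for all cvrpipe errors."""


class FormatError(CvrPipeError):
    """A file does not have the expected structure (missing column, wrong
    dimensionality, ...)."""


class DataError(CvrPipeError):
    """A file is structurally fine but its content violates a precondition
    (non-monotone time axis, apneic flow trace, too few breaths, ...)."""


class DegenerateInputError(DataError):
    """An input signal carries no usable information (zero variance)."""


class ConfigError(CvrPipeError):
    """Inconsistent configuration or mutually incompatible inputs."""
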