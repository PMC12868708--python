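"""Exception hierarchy used across the package."""


class HfemapError(Exception):
    """Base class for all package-specific errors."""


class InvalidFrequencyError(HfemapError, ValueError):
    """Allele frequencies are out of range or sum to more than one."""


class ValidationError(HfemapError, ValueError):
    """An input table or record violates a structural invariant."""


class FormatError(HfemapError, ValueError):
    """A file does not contain what the format contract requires."""


class DegenerateInputError(HfemapError, ValueError):
    """A statistical test received input on which it is undefined."""


class EmptySelectionError(HfemapError, ValueError):
    """A selection step matched nothing (e.g. all seed samples are noise)."""


class PipelineStageError(HfemapError, RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""
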