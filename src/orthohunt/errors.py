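"""Exception hierarchy shared across the package."""


class OrthohuntError(Exception):
    """Base class for all package-specific errors."""


class InputError(OrthohuntError):
    """A user-supplied path or list file is missing or unusable."""


class FormatError(OrthohuntError):
    """A file exists but violates its declared on-disk format."""


class CalibrationMissingError(OrthohuntError):
    """E-values were requested for a profile without forward-score statistics."""


class ConsistencyError(OrthohuntError):
    """Internal invariant violated between pipeline stages (indicates a bug)."""


class PipelineError(OrthohuntError):
    """A pipeline stage failed; message names the profile, proteome and stage."""
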