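"""Exception hierarchy for mbratools."""


class MbraError(Exception):
    """Base class for all mbratools errors."""


class FormatError(MbraError):
    """A file does not conform to the expected text dialect."""


class MetadataError(MbraError):
    """Sample metadata is missing, duplicated, or inconsistent."""


class InsufficientDataError(MbraError):
    """Too few samples, days, or groups for the requested computation."""
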