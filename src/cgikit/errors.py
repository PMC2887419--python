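"""Exception types shared across the package."""


class CgikitError(ValueError):
    """Base class for all cgikit errors."""


class FormatError(CgikitError):
    """A file does not conform to its declared format (FASTA/BED/TSV)."""


class InsufficientDataError(CgikitError):
    """Too few observations to compute the requested statistic."""


class UndefinedStatisticError(CgikitError):
    """The requested statistic is undefined for this input (e.g. empty set)."""
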