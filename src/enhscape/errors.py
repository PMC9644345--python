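"""Exception hierarchy shared by all pipeline stages."""


class EnhscapeError(Exception):
    """Base class for all errors raised by enhscape."""


class ParseError(EnhscapeError):
    """A malformed record in an input file.

    Carries the offending path and 1-based line number so the user can fix
    the file rather than guess.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class ConfigError(EnhscapeError):
    """Invalid or unknown configuration key/value."""


class NoTSSOnChromosome(EnhscapeError):
    """A region's chromosome has no TSS record to assign it to."""


class EmptyLibrary(EnhscapeError):
    """Tag library size of zero; normalization undefined."""


class BinningError(EnhscapeError):
    """Profile bin count does not evenly divide the window."""


class InfeasibleLayout(EnhscapeError):
    """The toy genome cannot host the requested elements without overlap."""


class UnknownCondition(EnhscapeError):
    """An interaction references a condition with no ATAC track."""


class GeneNotFound(EnhscapeError):
    """Requested gene absent from the TSS table."""
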