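"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`CutRegulonError`, so callers can catch one type at a pipeline
boundary while still distinguishing parameter problems (``ValueError``
subclasses) from I/O and format problems.
"""


class CutRegulonError(Exception):
    """Base class for all errors raised by cutregulon."""


class InvalidParameterError(CutRegulonError, ValueError):
    """A parameter violates its documented contract."""


class PackingError(CutRegulonError):
    """Requested genomic features cannot be placed without violating spacing."""


class ParseError(CutRegulonError):
    """A record in an input file is malformed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class UnsupportedInputError(CutRegulonError):
    """Input is syntactically valid but outside the supported scope."""


class IncompatibleTrackError(CutRegulonError):
    """Two tracks that must share a window grid do not."""


class ConfigError(CutRegulonError, ValueError):
    """A run configuration is invalid or contains unknown keys."""
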