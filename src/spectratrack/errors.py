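"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`SpectraTrackError`; plain :class:`OSError` is allowed to propagate
for filesystem failures (missing/unreadable files, unwritable directories).
"""


class SpectraTrackError(Exception):
    """Base class for all spectratrack errors."""


class ValidationError(SpectraTrackError, ValueError):
    """Malformed or semantically invalid input (bad hash, unknown id, ...)."""


class StateError(SpectraTrackError, RuntimeError):
    """Operation applied in the wrong session state (file not open, store closed)."""


class SchemaError(SpectraTrackError):
    """Store directory holds a corrupt, foreign, or uninitialized database."""


class IntegrityError(SpectraTrackError):
    """A content-addressed file is missing or its bytes no longer match its hash."""

    def __init__(self, message: str, hash: str | None = None):
        super().__init__(message)
        self.hash = hash


class ResolutionError(SpectraTrackError, LookupError):
    """A macro key could not be resolved to a registered plugin."""


class ExecutionError(SpectraTrackError, RuntimeError):
    """A processing plugin or estimator failed while executing."""


class ParseError(SpectraTrackError, ValueError):
    """A text file (FID, basis, options, batch) is malformed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
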