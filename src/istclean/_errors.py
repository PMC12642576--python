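"""Exception types shared across the package."""


class ISTCleanError(Exception):
    """Base class for all package errors."""


class ValidationError(ISTCleanError, ValueError):
    """Raised when user-supplied inputs violate a documented contract."""


class DegenerateInputError(ISTCleanError, ValueError):
    """Raised when an input is too degenerate for the requested computation
    (e.g. all transcripts at one point, or an empty background bin set)."""
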