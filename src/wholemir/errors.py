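"""Exception hierarchy shared across the package."""


class WholemirError(Exception):
    """Base class for package errors."""


class ValidationError(WholemirError):
    """Invalid user input (bad alphabet, out-of-range value, bad config)."""


class ParseError(WholemirError):
    """Malformed input file or structure string."""


class BackendError(WholemirError):
    """A thermodynamic folding backend failed or is unavailable."""
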