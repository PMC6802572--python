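"""Exception types shared across the engine."""


class TreelikeError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(TreelikeError, ValueError):
    """Invalid user-supplied values (frequencies, shapes, counts, ...)."""


class ParseError(TreelikeError, ValueError):
    """Malformed input file (alignment, tree, config)."""


class StateError(TreelikeError, RuntimeError):
    """An operation was issued against an instance in the wrong state,
    e.g. reading a partials buffer that was never written."""
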