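"""Exception hierarchy.

Every fatal condition raised by the package derives from
:class:`LRValidationError`, so callers (and the CLI) can catch one type.
"""


class LRValidationError(Exception):
    """Base class for all errors raised by lrvalidate."""


class ParseError(LRValidationError):
    """A file could not be parsed (message carries the path and line)."""


class ConfigError(LRValidationError):
    """The parameter file or CLI configuration is invalid or incomplete."""


class InvariantError(LRValidationError):
    """An input violates a structural invariant (e.g. PEV exceeding the
    prior variance, or whole/partial files apparently swapped)."""
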