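"""Exception hierarchy.

All package errors derive from :class:`PathReverseError` so callers can
catch one type at the pipeline boundary; the CLI maps subtypes to exit codes.
"""


class PathReverseError(Exception):
    """Base class for all errors raised by pathreverse."""


class FormatError(PathReverseError):
    """A file is structurally invalid (missing column, malformed line...)."""


class ConfigError(PathReverseError):
    """A configuration value is invalid or inconsistent."""


class SizingError(ConfigError):
    """A simulation size request is infeasible (e.g. sets larger than universe)."""


class SignatureLookupError(PathReverseError, KeyError):
    """A signature or compound id is not present where required."""


class EmptyInputError(PathReverseError):
    """An operation received an empty table or list it cannot act on."""
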