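"""Exception hierarchy.

All zygopeak errors derive from :class:`ZygopeakError` so callers can catch
everything the library raises with a single except clause.
"""


class ZygopeakError(Exception):
    """Base class for all zygopeak errors."""


class FormatError(ZygopeakError):
    """A file does not conform to the expected tabular dialect."""


class IntegrityError(ZygopeakError):
    """Input data violates a uniqueness or cross-reference constraint."""


class ValidationError(ZygopeakError):
    """An argument or value is outside its documented domain."""


class DegenerateInputError(ZygopeakError):
    """Input is technically valid but carries no usable signal (e.g. zero variance)."""


class StateError(ZygopeakError):
    """An operation was invoked on an object in an incompatible state."""
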