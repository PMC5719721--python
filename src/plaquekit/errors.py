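"""Exception hierarchy.

All package-specific failures derive from :class:`PlaquekitError` so callers
can catch one type at pipeline level while tests can assert on the precise
subclass.
"""


class PlaquekitError(Exception):
    """Base class for all plaquekit errors."""


class SchemaError(PlaquekitError):
    """An input table does not match the documented column schema."""


class ValidationError(PlaquekitError):
    """A domain object violates one of its invariants."""


class ConfigError(PlaquekitError):
    """An analysis or generator configuration value is invalid."""


class DegenerateFrameError(ValidationError):
    """A frame is geometrically degenerate (e.g. zero EEM area)."""


class RegistrationError(PlaquekitError):
    """Landmark pairs cannot define a monotone baseline/follow-up mapping."""


class InsufficientOverlapError(PlaquekitError):
    """The registered baseline/follow-up overlap is shorter than required.

    Carries a human-readable ``reason`` used in exclusion records.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ConstantInputError(PlaquekitError):
    """A correlation was requested on a constant vector."""
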