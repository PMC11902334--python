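"""Exception hierarchy for impedquant.

All labeled errors raised by the package derive from :class:`ImpedquantError`
so callers can catch pipeline failures without masking programming errors.
"""


class ImpedquantError(Exception):
    """Base class for all impedquant errors."""


class ConfigError(ImpedquantError, ValueError):
    """A configuration object violates one of its invariants."""


class InputError(ImpedquantError, ValueError):
    """An operation received data that violates its preconditions."""


class ParseError(ImpedquantError, ValueError):
    """A file could not be parsed into the expected schema."""


class StageError(ImpedquantError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
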