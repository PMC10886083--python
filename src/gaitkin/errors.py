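"""Exception hierarchy for the gait-analysis pipeline.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; everything else is a bug.
"""


class GaitError(Exception):
    """Base class for all package errors."""


class ConfigError(GaitError):
    """Invalid configuration value (bad window, unknown key, ...)."""


class SchemaError(GaitError):
    """A file does not match the declared landmark/marker schema."""


class DataError(GaitError):
    """Input data violate a precondition (empty trial, all-missing landmark, ...)."""


class InsufficientCyclesError(DataError):
    """Fewer than two heel strikes detected: no gait cycle can be formed."""
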