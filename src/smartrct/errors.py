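"""Exception hierarchy for the trial engine.

Every error class maps to one failure mode of the automated-trial
workflow; the CLI translates them into distinct exit codes.
"""


class SmartRctError(Exception):
    """Base class for all engine errors."""


class FormatError(SmartRctError):
    """A data file does not conform to its declared schema."""


class ScanFormatError(SmartRctError):
    """A scanned code is not a digit string."""


class ConfigError(SmartRctError):
    """A trial configuration value is missing, malformed, or inconsistent."""


class StateError(SmartRctError):
    """An operation was requested in a lifecycle state that does not allow it."""


class ScreeningError(SmartRctError):
    """Screening answers are incomplete or cannot be evaluated."""


class MonotonicClockError(SmartRctError):
    """The participant clock was advanced backwards."""


class LabelingError(SmartRctError):
    """A nutrition label cannot be computed for a product."""


class DuplicateRegistrationError(SmartRctError):
    """The e-mail fingerprint is already registered."""
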