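"""Exception types shared across chforge modules."""


class ChforgeError(Exception):
    """Base class for all chforge errors."""


class ConfigError(ChforgeError, ValueError):
    """A simulation or filter configuration violates its invariants."""


class MalformedRecordError(ChforgeError, ValueError):
    """An input record is structurally invalid (e.g. zero sequencing depth)."""


class InsufficientInstrumentsError(ChforgeError, ValueError):
    """Too few genetic instruments for the requested MR estimator."""


class ValidationError(ChforgeError, ValueError):
    """Fatal schema violation detected during input validation."""
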