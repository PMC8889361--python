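"""Exception hierarchy shared across the pipeline stages."""


class CwsiError(Exception):
    """Base class for all package errors."""


class ValidationError(CwsiError, ValueError):
    """A value violates a physical or structural invariant."""


class SchemaError(CwsiError, ValueError):
    """A tabular input does not match its declared schema."""


class CalibrationError(CwsiError, ValueError):
    """Baseline calibration cannot proceed (empty/degenerate data)."""
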