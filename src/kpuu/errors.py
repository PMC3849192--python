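"""Exception hierarchy for kpuu.

All package-specific failures derive from :class:`KpuuError` so callers can
catch one base class at pipeline boundaries.
"""


class KpuuError(Exception):
    """Base class for all kpuu errors."""


class InvalidParameterError(KpuuError, ValueError):
    """A physical parameter is outside its admissible range."""


class DegenerateMeasurementError(KpuuError, ValueError):
    """A measurement cannot support the requested ratio (e.g. zero donor)."""


class NonIdentifiableError(KpuuError, ValueError):
    """The data carry no information about the requested parameter."""


class EstimationFailureError(KpuuError, RuntimeError):
    """A numerical estimation step failed (e.g. no root in the bracket)."""


class AssayError(KpuuError, ValueError):
    """A binding-assay readout is invalid (zero/negative reference signal)."""


class SchemaError(KpuuError, ValueError):
    """An input table does not match the expected column schema."""
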