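"""Exception hierarchy for fepaudit."""


class FepAuditError(Exception):
    """Base class for all package errors."""


class StabilityError(FepAuditError):
    """Drift matrix is not Hurwitz: no stationary density exists."""


class StructureError(FepAuditError):
    """A claimed sensorimotor structure mask is violated."""


class DimensionError(FepAuditError):
    """Shapes inconsistent with the declared partition."""


class GenerationError(FepAuditError):
    """Random-system generation failed (Hurwitz resampling exhausted)."""


class SchemaError(FepAuditError):
    """Malformed or incomplete serialized system document."""


class DegenerateDensityError(FepAuditError):
    """Stationary covariance is numerically singular; precision unavailable."""


class UnsupportedModeError(FepAuditError):
    """Operation requires homogeneous noise or another unsupported mode."""


class MappingUndefinedError(FepAuditError):
    """A required covariance block is singular or violates a rank condition."""
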