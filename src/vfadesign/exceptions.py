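"""Exception hierarchy for vfadesign."""


class VFADesignError(Exception):
    """Base class for all vfadesign errors."""


class DomainError(VFADesignError, ValueError):
    """A physical parameter or acquisition setting violates its domain."""


class DegenerateNormalizationError(VFADesignError, ValueError):
    """The normalization divisor is zero (first flip angle is 0 degrees)."""


class SingularInformationError(VFADesignError, ValueError):
    """The Fisher information matrix is singular or too ill-conditioned to invert."""


class IdentifiabilityError(VFADesignError, ValueError):
    """The requested model variant is not identifiable under the given scheme."""


class OptimizationFailureError(VFADesignError, RuntimeError):
    """Every multistart initialization of a design optimization failed."""


class SchemeParseError(VFADesignError, ValueError):
    """A scheme/dataset/parameter file is malformed."""
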