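"""Exception hierarchy shared by all neutronrbe modules."""


class NeutronRBEError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(NeutronRBEError):
    """A container or argument violates a structural precondition."""


class InvalidParameterError(NeutronRBEError):
    """A scalar parameter is outside its physical domain."""


class CompositionError(NeutronRBEError):
    """Dose fractions of a mixed field violate their sum rule."""


class RangeError(NeutronRBEError):
    """A query point lies outside the tabulated range."""


class FitError(NeutronRBEError):
    """A damage-curve fit could not be performed or did not converge."""


class ConfigurationError(NeutronRBEError):
    """Required model configuration (curves, reference values) is missing or inconsistent."""


class DataError(NeutronRBEError):
    """Required data (e.g. a species lineal energy) is missing for a requested computation."""


class UnknownReactionError(NeutronRBEError):
    """Reaction identifier not present in the embedded nuclear-data set."""


class PatternValidationError(NeutronRBEError):
    """A genomic break pattern violates its ordering or bounds invariants."""
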