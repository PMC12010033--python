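"""Exception hierarchy shared across the package."""


class BkariskError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BkariskError):
    """A value violates a domain invariant (inclusion criterion, enum, arity)."""


class SchemaError(BkariskError):
    """A cohort file does not conform to the required CSV schema."""


class AnalysisError(BkariskError):
    """An analysis step cannot be carried out on the given cohort."""


class CapabilityError(BkariskError):
    """An exact computation was requested beyond its feasible size limit."""
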