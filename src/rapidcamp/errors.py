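"""Exception hierarchy shared across the package."""


class RapidCampError(ValueError):
    """Base class for all rapidcamp errors."""


class DomainError(RapidCampError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(RapidCampError):
    """A configuration object is internally inconsistent or infeasible
    (e.g. a trajectory line that leaves the physical screen)."""


class MalformedStreamError(RapidCampError):
    """An observer event stream violates the OFF/ON alternation grammar."""


class SchemaError(RapidCampError):
    """A serialized document has an unsupported schema version or shape."""
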