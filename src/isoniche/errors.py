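"""Exception hierarchy shared across the package."""


class IsoNicheError(Exception):
    """Base class for all isoniche errors."""


class SchemaError(IsoNicheError):
    """Input file does not carry the required columns."""


class DatasetValidationError(IsoNicheError):
    """A record or dataset violates a domain invariant."""


class MissingBaselineError(IsoNicheError):
    """A year requesting nitrogen standardization has no baseline records."""


class DegenerateStandardizationError(IsoNicheError):
    """Carbon range is zero; the range-scaling formula is undefined."""


class InsufficientSampleError(IsoNicheError):
    """Too few points for the requested estimate (SEA needs n >= 3)."""


class DegenerateGeometryError(IsoNicheError):
    """Covariance is singular; the ellipse has no area."""


class SamplerError(IsoNicheError):
    """The MCMC sampler failed irrecoverably."""


class ContractError(IsoNicheError):
    """Caller violated an operation's precondition."""
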