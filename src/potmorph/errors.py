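"""Exception hierarchy shared across the pipeline."""


class PotmorphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PotmorphError):
    """Input data violates a documented invariant (bad file, bad ordering)."""


class DomainError(PotmorphError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(PotmorphError):
    """Input is structurally valid but degenerate (zero height, zero duration)."""


class DesignError(PotmorphError):
    """A statistical design precondition is violated (singleton potter, etc.)."""


class InsufficientRankError(PotmorphError):
    """Too few observations to span the requested subspace."""


class ConfigError(PotmorphError):
    """Pipeline configuration is malformed."""
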