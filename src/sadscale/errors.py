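"""Exception hierarchy for sadscale."""


class SadscaleError(Exception):
    """Base class for all sadscale errors."""


class ParseError(SadscaleError, ValueError):
    """Malformed OTU table or abundance file; message names the offending line."""


class DomainError(SadscaleError, ValueError):
    """Input outside the mathematical domain of an operation."""


class DivergingMeanError(DomainError):
    """The requested mean abundance does not exist (e.g. alpha <= 1 with unbounded support)."""


class NotNormalizableError(DomainError):
    """Model parameters do not define a proper probability density."""


class InsufficientTailError(DomainError):
    """Too few points above every candidate cutoff for a tail fit."""


class ComparisonError(SadscaleError, ValueError):
    """Model fits being compared were not computed on identical data."""


class FitError(SadscaleError, RuntimeError):
    """Likelihood optimisation failed irrecoverably."""


class PipelineConfigError(SadscaleError, ValueError):
    """Invalid pipeline configuration."""
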