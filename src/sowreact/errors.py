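"""Exception hierarchy shared across the pipeline."""


class SowreactError(Exception):
    """Base class for all package-specific errors."""


class MalformedSessionError(SowreactError):
    """An ethogram session record violates the session invariants."""


class QCError(SowreactError):
    """Genotype quality control cannot proceed (e.g. empty study)."""


class DesignError(SowreactError):
    """A model design matrix cannot be built (rank deficiency, unknown ids)."""


class DegenerateChainError(SowreactError):
    """An MCMC chain is degenerate (zero variance) and cannot be diagnosed."""


class GrmError(SowreactError):
    """Genomic relationship matrix construction or use failed."""
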