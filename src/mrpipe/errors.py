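"""Exception hierarchy for mrpipe.

All package-specific errors derive from :class:`MrPipeError` so callers
(and the CLI) can catch one base class.
"""


class MrPipeError(Exception):
    """Base class for all mrpipe errors."""


class SummaryTableError(MrPipeError):
    """A summary-statistics table is missing columns or has malformed rows."""


class ValidationError(MrPipeError):
    """A record violates a domain invariant (e.g. non-positive SE)."""


class HarmonisationError(MrPipeError):
    """Allele harmonisation failed."""


class EmptyInstrumentError(HarmonisationError):
    """No SNPs survived harmonisation."""


class EstimationError(MrPipeError):
    """An estimator could not be computed."""


class SingularInstrumentError(EstimationError):
    """The weighted design matrix is singular (e.g. all exposure betas zero)."""


class InsufficientSnpsError(EstimationError):
    """Fewer SNPs than the method's minimum."""


class ParameterError(MrPipeError):
    """An argument is outside its admissible domain."""


class PipelineStageError(MrPipeError):
    """A pipeline stage failed; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
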