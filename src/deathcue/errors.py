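"""Exception hierarchy shared across the package."""


class DeathcueError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DeathcueError, ValueError):
    """A simulation spec or configuration value violates its invariants."""


class UndefinedPreferenceError(DeathcueError):
    """Preference index requested for a trial in which no fly made a choice."""


class InsufficientDataError(DeathcueError):
    """Too few trials, samples, or events for the requested statistic."""


class BlockStructureError(DeathcueError):
    """Block labels are inconsistent between the groups being compared."""


class PipelineOrderError(DeathcueError):
    """A metabolome processing step was called out of the enforced order."""


class EmptyMatrixError(DeathcueError):
    """A filtering step removed every metabolite."""


class DomainError(DeathcueError):
    """An abundance value is outside the domain of the requested transform."""


class DegenerateDataError(DeathcueError):
    """Zero-variance column or zero within-group spread; statistic undefined."""


class DesignError(DeathcueError):
    """The 2x2 factor structure required by an interaction test is incomplete."""


class FitError(DeathcueError):
    """A model fit failed to converge."""


class ValidationError(DeathcueError):
    """A data file failed validation on read."""


class StageError(DeathcueError):
    """A full-pipeline stage aborted; the message names the stage and cause."""
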