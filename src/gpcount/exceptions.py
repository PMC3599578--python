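"""Exception hierarchy.

Every error the library raises derives from :class:`GPCountError`, with
distinct subclasses per failure class so the CLI can map them to distinct
exit codes.
"""


class GPCountError(Exception):
    """Base class for all gpcount errors."""


class DomainError(GPCountError, ValueError):
    """Distribution parameters violate the GP parameter space."""


class DataError(GPCountError, ValueError):
    """Malformed or inconsistent input records."""


class ConfigError(GPCountError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FitError(GPCountError, RuntimeError):
    """Base class for model-fitting failures."""


class RankDeficiencyError(FitError):
    """Design matrix is not of full column rank."""


class ConvergenceError(FitError):
    """Optimizer failed to converge within the iteration cap."""


class SingularInformationError(FitError):
    """Observed information matrix is singular or not positive on the diagonal."""


class PipelineError(GPCountError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
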