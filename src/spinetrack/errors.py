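"""Exception hierarchy for the spinetrack toolkit."""


class SpinetrackError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(SpinetrackError, ValueError):
    """An argument violates a documented precondition."""


class DataError(SpinetrackError, ValueError):
    """Input data are structurally valid but unusable (too few readings, ...)."""


class SingularDesignError(DataError):
    """Least-squares design matrix is singular (e.g. all voltages equal)."""


class NoFringesError(SpinetrackError):
    """No interference fringes above the noise floor in a power spectrum."""


class UndefinedRigidityError(SpinetrackError, ZeroDivisionError):
    """Instant rigidity is undefined (zero displacement or angle)."""


class ConfigError(SpinetrackError, ValueError):
    """Run configuration is missing, malformed or fails validation."""


class StageError(SpinetrackError, RuntimeError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
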