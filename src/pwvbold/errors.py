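"""Exception types shared across the package."""


class PwvBoldError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(PwvBoldError, ValueError):
    """A parameter combination is physically or numerically invalid."""


class FootDetectionError(PwvBoldError, RuntimeError):
    """The systolic foot of a flow waveform could not be located."""


class EstimationError(PwvBoldError, RuntimeError):
    """A velocity/transit-time estimate is inconsistent (e.g. t <= 0)."""


class ModelError(PwvBoldError, RuntimeError):
    """A statistical model cannot be fitted (singular design, constants)."""


class DependencyError(PwvBoldError, RuntimeError):
    """A pipeline stage was requested before its inputs were produced."""

    def __init__(self, stage: str, missing: str):
        self.stage = stage
        self.missing = missing
        super().__init__(
            f"stage '{stage}' requires output of stage '{missing}', "
            f"which is disabled or has not run"
        )
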