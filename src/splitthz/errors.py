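"""Exception hierarchy shared across the pipeline stages."""


class SplitTHzError(Exception):
    """Base class for all package errors."""


class ConfigError(SplitTHzError, ValueError):
    """Invalid configuration value."""


class LayoutError(ConfigError):
    """Phantom region layout is inconsistent (overlaps, out of bounds)."""


class DimensionError(SplitTHzError, ValueError):
    """Array shapes do not line up with the fitted model or expected layout."""


class DegenerateFeatureError(SplitTHzError, ValueError):
    """A feature column is constant, so min-max normalization is undefined."""


class KernelError(SplitTHzError, ValueError):
    """Filter kernel incompatible with the spectra it is applied to."""


class InsufficientDataError(SplitTHzError, ValueError):
    """Not enough rows (overall or per class) to fit a model."""


class LabelError(SplitTHzError, ValueError):
    """A label falls outside the model's class set."""


class ParameterError(SplitTHzError, ValueError):
    """Model parameters violate their constraints (e.g. unordered cutpoints)."""


class DivergenceError(SplitTHzError, RuntimeError):
    """Optimisation diverged; typically the learning rate is too large."""


class UndefinedAUCError(SplitTHzError, ValueError):
    """ROC/AUC requested with only one class present."""


class PrivacyViolationError(SplitTHzError, RuntimeError):
    """A split-learning transcript payload leaked raw feature rows."""

    def __init__(self, message: str, round_index: int | None = None):
        super().__init__(message)
        self.round_index = round_index


class FormatError(SplitTHzError, ValueError):
    """On-disk artifact does not match the expected layout."""


class PipelineStageError(SplitTHzError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
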