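"""Exception hierarchy shared across the pipeline."""


class EmbryomorphError(Exception):
    """Base class for all package errors."""


class GridError(EmbryomorphError):
    """Invalid image grid (non-positive or non-isotropic spacing, bad shape)."""


class ParameterError(EmbryomorphError):
    """Out-of-range analysis parameter."""


class MissingLabelError(EmbryomorphError):
    """A requested label id is absent from a label map."""


class DegenerateDataError(EmbryomorphError):
    """Input with no usable signal (zero variance, empty mask, ...)."""


class GenerationError(EmbryomorphError):
    """Phantom generation failed (e.g. organs collide after effects)."""


class RegistrationError(EmbryomorphError):
    """Registration optimisation failed; carries the metric trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class InversionError(EmbryomorphError):
    """Transform inversion did not reach the requested residual."""

    def __init__(self, message, worst_residual_um=None):
        super().__init__(message)
        self.worst_residual_um = worst_residual_um


class FoldError(InversionError):
    """Transform folds (non-positive Jacobian determinant) in the domain."""


class DesignError(EmbryomorphError):
    """Statistical design is unusable (rank deficiency, too few specimens)."""


class ConfigError(EmbryomorphError):
    """Pipeline configuration is invalid."""
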