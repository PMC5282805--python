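"""Exception hierarchy for the tarsal shape-model pipeline."""


class TarsalSSMError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TarsalSSMError, ValueError):
    """Input violates a documented precondition."""


class NotStarShapedError(TarsalSSMError, ValueError):
    """A point cloud or mesh is not star-shaped about the chosen origin."""


class DegeneratePlaneError(TarsalSSMError, ValueError):
    """Three landmark points are collinear; the landmark plane is undefined."""


class MissingRegionError(TarsalSSMError, KeyError):
    """A requested landmark region label is absent from the mesh."""


class ConditioningError(TarsalSSMError, ValueError):
    """A least-squares design matrix is rank deficient or ill conditioned."""


class InvalidShapeError(TarsalSSMError, ValueError):
    """A reconstructed radius function is non-positive somewhere."""


class GenerationError(TarsalSSMError, RuntimeError):
    """Synthetic sample generation failed (e.g. positivity retries exhausted)."""


class UnbalancedDesignError(TarsalSSMError, ValueError):
    """An ANOVA layout has unequal cell counts."""


class StratificationError(TarsalSSMError, ValueError):
    """A class has too few members for the requested number of CV folds."""


class ConfigError(TarsalSSMError, ValueError):
    """Pipeline configuration is invalid."""
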