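"""Exception hierarchy shared across the package."""


class TwinTowerError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TwinTowerError):
    """Invalid or inconsistent configuration."""


class ModalityFileError(TwinTowerError):
    """A required per-channel input file is missing or unreadable."""


class ShapeMismatchError(TwinTowerError):
    """Array shapes disagree with each other or with a configuration."""


class NoTumorError(TwinTowerError):
    """The segmentation mask contains no tumor voxels."""


class EmptyMatrixError(TwinTowerError):
    """Gene-ID intersection across samples is empty."""


class LabelError(TwinTowerError):
    """A clinical response value cannot be mapped to a binary label."""


class SplitError(TwinTowerError):
    """A stratum is too small to be partitioned."""


class ScalerError(TwinTowerError):
    """A feature scaler was misused (unfitted, or fitted on < 2 rows)."""


class EmptyTrainingSetError(TwinTowerError):
    """A training stage received no samples."""


class ModalityError(TwinTowerError):
    """A sample is missing a modality required by the requested stage."""


class FoldError(TwinTowerError):
    """Cross-validation folds cannot be formed (e.g. a class missing)."""


class RocError(TwinTowerError):
    """ROC analysis is undefined (single-class labels)."""


class EmptyEvalError(TwinTowerError):
    """Metrics requested for an empty evaluation set."""
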