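"""Exception hierarchy shared across the pipeline stages."""


class DermclfError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DermclfError):
    """Invalid user-supplied configuration value."""


class LabelError(DermclfError):
    """A class label outside the configured seven-code vocabulary."""


class DanglingReferenceError(DermclfError):
    """Metadata rows referencing image files that do not exist."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(
            f"{len(self.missing_ids)} image_id(s) have no image file: "
            + ", ".join(self.missing_ids[:10])
            + ("..." if len(self.missing_ids) > 10 else "")
        )


class InsufficiencyError(DermclfError):
    """A class has fewer images than the requested per-class subset size."""


class SchemaError(DermclfError):
    """Inconsistent in-memory data (e.g. ragged feature vectors)."""


class FormatError(DermclfError):
    """A persisted artifact does not match the expected on-disk layout."""


class ValidationError(DermclfError):
    """Invalid numeric input (NaN features, shape mismatches...)."""


class DegenerateTrainingError(DermclfError):
    """Training requested with fewer than two classes present."""


class ConsistencyError(DermclfError):
    """Cross-artifact mismatch (e.g. split ids absent from the feature store)."""


class DivergenceError(DermclfError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


class PrerequisiteError(DermclfError):
    """A pipeline command was run before the command that produces its input."""
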