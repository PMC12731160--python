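"""Exception hierarchy shared across the package."""


class OmicsFuseError(Exception):
    """Base class for all package errors."""


class InputError(OmicsFuseError):
    """A required input file is missing or unreadable."""


class ValidationError(OmicsFuseError):
    """Input data violates a structural invariant (NaN, duplicates, ...)."""


class AlignmentError(OmicsFuseError):
    """Sample sets of the omics layers and labels do not match."""


class ConfigError(OmicsFuseError):
    """A configuration value is out of its admissible range."""


class TrainingDivergenceError(OmicsFuseError):
    """Training produced a non-finite loss."""

    def __init__(self, stage: str, epoch: int):
        self.stage = stage
        self.epoch = epoch
        super().__init__(f"non-finite loss in {stage} at epoch {epoch}")
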