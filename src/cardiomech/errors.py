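"""Exception hierarchy for the cardiomech pipeline."""


class CardiomechError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CardiomechError):
    """Malformed or inconsistent input file."""


class ChannelMissingError(FormatError):
    """A required channel is absent from a recording file."""

    def __init__(self, channel: str):
        self.channel = channel
        super().__init__(f"required channel missing: {channel!r}")


class ValidationError(CardiomechError):
    """A domain object violates one of its invariants."""


class SynthesisError(CardiomechError):
    """Synthetic-cohort specification cannot be realised."""


class FilterError(CardiomechError):
    """Signal too short (or otherwise unsuitable) for a filtering step."""


class InsufficientBeatsError(CardiomechError):
    """Fewer than two usable heartbeats detected on the ECG."""


class SegmentationError(CardiomechError):
    """Cycle segmentation or interpolation failed."""


class InsufficientCyclesError(SegmentationError):
    """Fewer cardiac cycles available than one series requires."""


class ShapeError(CardiomechError):
    """An array does not have the shape the pipeline stage expects."""


class TrainingError(CardiomechError):
    """Classifier training cannot proceed (e.g. single-class data)."""


class ModelStateError(CardiomechError):
    """Operation requires a trained model but got an untrained one."""


class FoldError(CardiomechError):
    """A cross-validation fold is unusable (e.g. a class is missing)."""


class LeakageError(CardiomechError):
    """Subject-level data leakage detected between train and test."""


class MetricsError(CardiomechError):
    """Metrics undefined for the given predictions (e.g. one class)."""


class AggregationError(CardiomechError):
    """Cannot aggregate an empty collection of cycle probabilities."""


class FusionError(CardiomechError):
    """Classifier fusion is missing one of its required inputs."""


class ComparisonError(CardiomechError):
    """Model comparison requested on mismatched subject sets."""
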