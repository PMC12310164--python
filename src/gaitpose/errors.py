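"""Exception hierarchy for the gait-analysis pipeline."""


class GaitPoseError(Exception):
    """Base class for all package errors."""


class ProfileValidationError(GaitPoseError):
    """A gait profile violates one of its invariants."""


class GenerationError(GaitPoseError):
    """A cohort spec could not be satisfied (e.g. repeated resampling failed)."""


class FormatError(GaitPoseError):
    """An input file could not be parsed in the expected dialect."""


class FrameGapError(GaitPoseError):
    """Per-frame files have non-contiguous frame indices."""


class CalibrationError(GaitPoseError):
    """Degenerate pixel-to-meter calibration (coincident marks, bad distance)."""


class UnitError(GaitPoseError):
    """Operation applied to a trajectory in the wrong units."""


class FilterError(GaitPoseError):
    """Trial too short (or otherwise unsuitable) for the low-pass filter."""


class StationaryTrialError(GaitPoseError):
    """Net mid-hip displacement too small to infer a walking direction."""


class InsufficientStridesError(GaitPoseError):
    """Too few gait events to compute the requested quantity."""


class SequenceError(GaitPoseError):
    """A gait event sequence failed validation after repair."""


class MissingLandmarkError(GaitPoseError):
    """A landmark required at an event (e.g. heel at initial contact) is missing."""


class IncompleteParticipantError(GaitPoseError):
    """A participant lacks one or more of the required conditions."""


class DegenerateDataError(GaitPoseError):
    """Statistical input carries no usable variation."""


class ConfigError(GaitPoseError):
    """Invalid or unknown keys in a pipeline configuration."""
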