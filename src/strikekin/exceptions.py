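"""Exception hierarchy for the strike-analysis pipeline.

Every detector failure is a typed error so that trials can be flagged and
logged rather than silently dropped.
"""


class StrikekinError(Exception):
    """Base class for all package errors."""


class DegenerateCalibrationError(StrikekinError):
    """Calibration point set is rank deficient (e.g. coplanar, or <6 points)."""


class BehindCameraError(StrikekinError):
    """3D point lies on the camera's principal plane (projection denominator ~ 0)."""


class TooShortSeriesError(StrikekinError):
    """Series too short for the requested polynomial order."""


class DegenerateGeometryError(StrikekinError):
    """Zero-length segment vector or coincident landmarks in an angle computation."""


class NoPeakError(StrikekinError):
    """Femur/tibia angle never forms a local peak before capture."""


class NoCaptureError(StrikekinError):
    """Prey never enters the foreleg triangle; the attempt is excluded."""


class PhaseDetectionError(StrikekinError):
    """Approach/sweep thresholds never crossed."""


class MissingLandmarkError(StrikekinError):
    """A landmark required by an operation is absent from the trajectory."""


class MissingTipError(StrikekinError):
    """Species labels that cannot be matched to a tip of the phylogeny."""


class ConvergenceError(StrikekinError):
    """Mixed-model optimizer failed to converge."""


class PipelineError(StrikekinError):
    """A pipeline stage failed; carries the stage name and offending trials."""

    def __init__(self, stage: str, message: str, trials: list[str] | None = None):
        self.stage = stage
        self.trials = trials or []
        suffix = f" (trials: {', '.join(self.trials)})" if self.trials else ""
        super().__init__(f"stage {stage!r}: {message}{suffix}")
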