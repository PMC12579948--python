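"""Core containers: landmark scheme, 2D tracked trajectories, 3D trajectories.

The landmark scheme follows the ten-point digitization used throughout the
pipeline: points 1-4 on the left foreleg (thorax/coxa joint, trochanter,
femur-tibia joint, tibia tip), point 5 at the mesocoxal joint, point 6 on the
prey, point 7 at the centre of the left eye, and points 8-10 mirroring 2-4 on
the right foreleg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical landmark labels, index i corresponds to "point i+1".
LANDMARKS: tuple[str, ...] = (
    "procoxal_joint",       # 1
    "trochanter_left",      # 2
    "femorotibial_left",    # 3
    "tibia_tip_left",       # 4
    "mesocoxal_joint",      # 5
    "prey",                 # 6
    "left_eye",             # 7
    "trochanter_right",     # 8
    "femorotibial_right",   # 9
    "tibia_tip_right",      # 10
)

#: 0-based indices, named for readability at call sites.
P1, P2, P3, P4, P5, P6, P7, P8, P9, P10 = range(10)


@dataclass
class TrackedTrajectory2D:
    """Pixel-space trajectories of the ten landmarks from a single camera.

    ``points`` has shape (frames, n_landmarks, 2); untracked entries are NaN.
    ``confidence`` mirrors the tracker's per-point likelihood.
    """

    points: np.ndarray
    labels: tuple[str, ...] = LANDMARKS
    confidence: np.ndarray | None = None
    frame_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must have shape (frames, landmarks, 2)")
        if self.confidence is None:
            self.confidence = np.ones(self.points.shape[:2])

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[1]


@dataclass
class Trajectory3D:
    """World-space (cm) trajectories of the ten landmarks for one trial."""

    coords: np.ndarray  # (frames, landmarks, 3)
    frame_rate: float
    labels: tuple[str, ...] = LANDMARKS
    reconstruction_error_mean: float = 0.0
    reconstruction_error_max: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, landmarks, 3)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def point(self, index: int) -> np.ndarray:
        """(frames, 3) series of one landmark by 0-based index."""
        return self.coords[:, index, :]


@dataclass
class SegmentLengths:
    """Foreleg segment and metazona lengths in cm."""

    coxa: float = 1.0
    femur: float = 1.6
    tibia: float = 0.9
    metazona: float = 1.4

    def __post_init__(self) -> None:
        for name in ("coxa", "femur", "tibia", "metazona"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment length {name!r} must be positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "coxa": self.coxa,
            "femur": self.femur,
            "tibia": self.tibia,
            "metazona": self.metazona,
        }
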