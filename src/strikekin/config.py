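"""Pipeline configuration: every threshold used by the extractors lives here.

Defaults encode the extraction rules: a 10th-order smoothing polynomial, the
99% rule for the peak coxa angle, the 5%-of-peak-coxa-angle approach onset,
the 10%-of-max femur angular velocity approach end, the 50 deg
basigrade/anterograde cut, and the capture-triangle plane tolerance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # smoothing
    poly_order: int = 10
    smoothing_mode: str = "windowed"   # "windowed" (sliding fit) or "global"
    smoothing_window_frames: int = 13  # sliding-window length (odd, > poly_order)
    pad_frames: int = 10           # smoothing window = strike window +/- pad

    # event detection
    coxa_peak_factor: float = 0.99       # peak coxa angle = factor * max standardized
    approach_start_frac: float = 0.05    # coxa at this fraction of peak coxa angle
    approach_end_frac: float = 0.10      # femur AV at this fraction of its max
    baseline_frames: int = 20            # frames used for the onset noise floor
    onset_sd_mult: float = 3.0           # onset threshold = mean + mult * SD
    onset_fallback_frac: float = 0.05    # fallback: fraction of trial max speed
    capture_plane_tol_frac: float = 0.10  # plane tolerance as fraction of femur length

    # variable definitions (documented alternates)
    segment_velocity_point: str = "distal"  # path of the distal joint per segment
    pp_angle_3d: bool = True                # predator-prey angle measured in 3D
    coxa_start_standardized: bool = False   # raw anatomical angle at strike start

    # classification
    hunting_style_cut_deg: float = 50.0

    # tracking input
    confidence_cutoff: float = 0.6

    # run orchestration
    frame_rate: float = 1000.0
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("coxa_peak_factor", "approach_start_frac", "approach_end_frac",
                     "onset_fallback_frac", "capture_plane_tol_frac",
                     "confidence_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")
        if self.smoothing_mode not in ("windowed", "global"):
            raise ValueError("smoothing_mode must be 'windowed' or 'global'")
        if self.smoothing_mode == "windowed" and \
                self.smoothing_window_frames <= self.poly_order:
            raise ValueError("smoothing_window_frames must exceed poly_order")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
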