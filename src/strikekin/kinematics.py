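"""Rule-based extraction of strike kinematics from a 10-landmark 3D trajectory.

A prey-capture attempt is reduced to 16 kinematic variables, the
approach/sweep phase times and four morphological segment lengths:

* the strike window runs from the first detectable foreleg movement to the
  frame at which the prey crosses into the triangle formed by the forelegs;
* joint angles (coxa, trochanter/femur, tibia) are measured on the left leg
  from the tracked landmarks, smoothed, and standardized by subtracting each
  joint's minimum over the window;
* the approach phase begins when the coxa reaches 5% of its peak angle and
  ends when the femur angular velocity first reaches 10% of its maximum; the
  sweep runs from there to capture;
* angular velocities are derivatives of the smoothed angles; the tibia's
  maximum is the absolute value of its most negative (flexion) velocity;
* linear velocities track the distal joint of each segment, body motion
  tracks the midpoint of the pro- and mesocoxal joints, and lateral
  displacements are the maxima of the smoothed left-right joint distances.

Smoothing uses an order-10 least-squares polynomial.  By default it is
applied in a short sliding window (Savitzky-Golay), which tracks the
millisecond-scale femur/tibia events that a single polynomial spanning the
whole window cannot represent; the single global fit is available via
``PipelineConfig.smoothing_mode = "global"`` and as :func:`fit_poly_smooth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .config import PipelineConfig
from .core import P1, P2, P3, P4, P5, P6, P7, P8, P9, P10, Trajectory3D
from .exceptions import (
    DegenerateGeometryError,
    MissingLandmarkError,
    NoCaptureError,
    NoPeakError,
    PhaseDetectionError,
    TooShortSeriesError,
)

__all__ = [
    "AngleSeries",
    "StrikePhases",
    "PeakAngles",
    "KinematicRecord",
    "MorphologyRecord",
    "TABLE1_LABELS",
    "fit_poly_smooth",
    "smooth_series",
    "joint_angle_series",
    "peak_angles",
    "angular_velocities",
    "segment_linear_velocities",
    "body_motion",
    "detect_strike_window",
    "detect_phases",
    "lateral_displacements",
    "predator_prey_geometry",
    "extract_morphology",
    "extract_kinematic_record",
]

JOINTS = ("coxa", "femur", "tibia")

#: Table-style labels of the 16 kinematic variables, in canonical order.
TABLE1_LABELS: dict[str, str] = {
    "coxa_lv": "Coxa LV",
    "femur_lv": "Femur LV",
    "coxa_av": "Coxa AV",
    "femur_av": "Femur AV",
    "tibia_av": "Tibia AV",
    "tibia_lv": "Tibia LV",
    "coxa_start_angle": "Coxa start angle",
    "approach_time": "Approach time",
    "pp_angle": "PP angle",
    "pp_dist": "PP dist.",
    "body_velocity": "Body vel.",
    "body_displacement": "Body disp.",
    "sweep_time": "Sweep time",
    "coxa_femur_ld": "Coxa/femur LD",
    "femur_tibia_ld": "Femur/tibia LD",
    "tibia_ld": "Tibia LD",
}


# ---------------------------------------------------------------------------
# smoothing

def _interpolate_interior_nans(y: np.ndarray) -> np.ndarray:
    """Linearly interpolate interior missing values; edges are extended."""
    y = np.asarray(y, dtype=float)
    bad = ~np.isfinite(y)
    if not bad.any():
        return y
    if bad.all():
        raise TooShortSeriesError("series contains no finite values")
    idx = np.arange(y.size)
    out = y.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
    return out


def fit_poly_smooth(
    series: np.ndarray,
    frame_rate: float = 1.0,
    order: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Global least-squares polynomial smoothing with an analytic derivative.

    Fits a single polynomial of ``order`` over the full series (time axis in
    seconds from ``frame_rate``) and evaluates both the fit and its exact
    derivative from the fitted coefficients.  Interior missing values are
    linearly interpolated before fitting.

    Returns ``(smoothed, derivative)``; the derivative is per second.
    """
    y = _interpolate_interior_nans(series)
    if y.size < order + 2:
        raise TooShortSeriesError(
            f"series of length {y.size} too short for order-{order} polynomial"
        )
    t = np.arange(y.size) / frame_rate
    poly = np.polynomial.Polynomial.fit(t, y, order)
    return poly(t), poly.deriv()(t)


def smooth_series(
    series: np.ndarray,
    frame_rate: float,
    config: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth a per-frame series with the configured order-10 smoother.

    ``smoothing_mode="windowed"`` (default) applies the order-``poly_order``
    least-squares polynomial in a sliding window of
    ``smoothing_window_frames``; ``"global"`` delegates to
    :func:`fit_poly_smooth`.
    """
    if config.smoothing_mode == "global":
        return fit_poly_smooth(series, frame_rate, config.poly_order)
    y = _interpolate_interior_nans(series)
    win = min(config.smoothing_window_frames, y.size)
    if win % 2 == 0:
        win -= 1
    if win <= config.poly_order:
        # window cannot support the polynomial order: fall back to global fit
        order = min(config.poly_order, y.size - 2)
        if order < 1:
            raise TooShortSeriesError("series too short to smooth")
        return fit_poly_smooth(y, frame_rate, order)
    sm = savgol_filter(y, win, config.poly_order)
    dv = savgol_filter(y, win, config.poly_order, deriv=1, delta=1.0 / frame_rate)
    return sm, dv


# ---------------------------------------------------------------------------
# containers

@dataclass
class AngleSeries:
    """Raw, smoothed, standardized joint angles (deg) and angular velocities
    (deg/s) over the analysis window."""

    frames: np.ndarray                    # absolute frame indices
    frame_rate: float
    raw: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray]
    standardized: dict[str, np.ndarray]
    velocity: dict[str, np.ndarray]

    def index_of(self, frame: int) -> int:
        i = int(frame) - int(self.frames[0])
        if not 0 <= i < self.frames.size:
            raise IndexError(f"frame {frame} outside analysis window")
        return i


@dataclass
class StrikePhases:
    """Frame indices and durations of the strike phases."""

    strike_start_frame: int
    approach_start_frame: int
    approach_end_frame: int
    capture_frame: int
    frame_rate: float

    def __post_init__(self) -> None:
        if not (self.strike_start_frame <= self.approach_start_frame
                < self.approach_end_frame < self.capture_frame):
            raise PhaseDetectionError(
                "phase frames must satisfy start <= approach_start < "
                "approach_end < capture"
            )

    @property
    def approach_time(self) -> float:
        return (self.approach_end_frame - self.approach_start_frame) / self.frame_rate

    @property
    def sweep_time(self) -> float:
        return (self.capture_frame - self.approach_end_frame) / self.frame_rate


@dataclass
class PeakAngles:
    """Per-joint maximum standardized angles (deg) and the frames at which
    the femur/tibia angular peaks occur."""

    coxa: float
    femur: float
    tibia: float
    femur_frame: int
    tibia_frame: int


@dataclass
class KinematicRecord:
    """The 16 strike variables plus phases, morphology and trial metadata.

    Linear quantities are cm and cm/s, angles deg, angular velocities deg/s,
    times s.
    """

    coxa_lv: float
    femur_lv: float
    coxa_av: float
    femur_av: float
    tibia_av: float
    tibia_lv: float
    coxa_start_angle: float
    approach_time: float
    pp_angle: float
    pp_dist: float
    body_velocity: float
    body_displacement: float
    sweep_time: float
    coxa_femur_ld: float
    femur_tibia_ld: float
    tibia_ld: float
    phases: StrikePhases | None = None
    morphology: "MorphologyRecord | None" = None
    metadata: dict = field(default_factory=dict)

    def kinematic_values(self) -> dict[str, float]:
        """The 16 variables keyed by their table labels, in canonical order."""
        return {label: float(getattr(self, name)) for name, label in TABLE1_LABELS.items()}

    def __post_init__(self) -> None:
        maxima = ("coxa_lv", "femur_lv", "coxa_av", "femur_av", "tibia_av",
                  "tibia_lv", "body_velocity", "coxa_femur_ld",
                  "femur_tibia_ld", "tibia_ld")
        for name in maxima:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is a maximum and must be >= 0")
        if self.approach_time <= 0 or self.sweep_time <= 0:
            raise ValueError("approach_time and sweep_time must be positive")


@dataclass
class MorphologyRecord:
    """Foreleg segment and metazona lengths (cm), averaged over the strike."""

    coxa_length: float
    femur_length: float
    tibia_length: float
    metazona_length: float

    def __post_init__(self) -> None:
        for name in ("coxa_length", "femur_length", "tibia_length",
                     "metazona_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# geometry helpers

def _vector_angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle (deg) between row vectors of v1 and v2; zero vectors are errors."""
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    finite = np.isfinite(n1) & np.isfinite(n2)
    if np.any((n1[finite] == 0) | (n2[finite] == 0)):
        raise DegenerateGeometryError("zero-length segment vector in angle computation")
    cosang = np.sum(v1 * v2, axis=-1) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _require_landmarks(traj: Trajectory3D, indices: tuple[int, ...],
                       window: tuple[int, int]) -> None:
    a, b = window
    for i in indices:
        if not np.all(np.isfinite(traj.coords[a:b, i, :])):
            raise MissingLandmarkError(
                f"landmark {traj.labels[i]!r} missing within frames {a}..{b - 1}"
            )


# ---------------------------------------------------------------------------
# operations

def joint_angle_series(
    traj: Trajectory3D,
    window: tuple[int, int],
    config: PipelineConfig | None = None,
) -> AngleSeries:
    """Coxa, femur and tibia angle series over ``window`` (half-open frames).

    Coxa: angle at the procoxal joint (point 1) between the metazona axis
    (1->5) and the coxa (1->2).  Femur: angle at the trochanter (point 2)
    between 2->1 and 2->3.  Tibia: angle at the femorotibial joint (point 3)
    between 3->2 and 3->4.  Each raw series is smoothed with the configured
    smoother; the standardized series subtracts each joint's minimum.
    """
    config = config or PipelineConfig()
    a, b = window
    _require_landmarks(traj, (P1, P2, P3, P4, P5), window)
    c = traj.coords[a:b]
    raw = {
        "coxa": _vector_angle_deg(c[:, P5] - c[:, P1], c[:, P2] - c[:, P1]),
        "femur": _vector_angle_deg(c[:, P1] - c[:, P2], c[:, P3] - c[:, P2]),
        "tibia": _vector_angle_deg(c[:, P2] - c[:, P3], c[:, P4] - c[:, P3]),
    }
    smoothed, velocity, standardized = {}, {}, {}
    for j, series in raw.items():
        sm, dv = smooth_series(series, traj.frame_rate, config)
        smoothed[j] = sm
        velocity[j] = dv
        standardized[j] = sm - np.min(sm)
    return AngleSeries(
        frames=np.arange(a, b),
        frame_rate=traj.frame_rate,
        raw=raw,
        smoothed=smoothed,
        standardized=standardized,
        velocity=velocity,
    )


def peak_angles(
    angles: AngleSeries,
    capture_frame: int,
    config: PipelineConfig | None = None,
) -> PeakAngles:
    """Per-joint maximum standardized angles.

    The peak coxa angle is 99% (``coxa_peak_factor``) of the maximum measured
    standardized angle.  Femur and tibia open during the approach and close
    during the sweep, so their maxima are read at the highest local peak of
    the standardized smoothed angle occurring before capture; a series with
    no such peak raises :class:`NoPeakError` so the trial can be flagged.
    """
    config = config or PipelineConfig()
    cap = angles.index_of(capture_frame)
    coxa_max = config.coxa_peak_factor * float(np.max(angles.standardized["coxa"]))

    out: dict[str, tuple[float, int]] = {}
    for joint in ("femur", "tibia"):
        series = angles.standardized[joint][: cap + 1]
        rng = float(np.ptp(series))
        peaks, props = find_peaks(series, prominence=0.02 * rng if rng > 0 else None)
        if peaks.size == 0:
            raise NoPeakError(
                f"{joint} angle has no local peak before capture "
                f"(frame {capture_frame}); trial flagged"
            )
        best = peaks[np.argmax(series[peaks])]
        out[joint] = (float(series[best]), int(angles.frames[0] + best))

    return PeakAngles(
        coxa=coxa_max,
        femur=out["femur"][0],
        tibia=out["tibia"][0],
        femur_frame=out["femur"][1],
        tibia_frame=out["tibia"][1],
    )


def angular_velocities(
    angles: AngleSeries,
    capture_frame: int | None = None,
) -> dict[str, float]:
    """Maximum angular velocities (deg/s) per joint.

    Coxa and femur report the maximum of the smoothed-angle derivative
    (extension/abduction); the tibia, which flexes rapidly to secure the
    prey, reports the absolute value of its most negative derivative.
    """
    stop = angles.index_of(capture_frame) + 1 if capture_frame is not None else None
    return {
        "coxa": float(np.max(angles.velocity["coxa"][:stop])),
        "femur": float(np.max(angles.velocity["femur"][:stop])),
        "tibia": float(abs(np.min(angles.velocity["tibia"][:stop]))),
    }


def _path_speed_max(
    positions: np.ndarray,
    frame_rate: float,
    config: PipelineConfig,
    lo: int,
    hi: int,
) -> tuple[float, float]:
    """Max derivative of the smoothed cumulative path length, and the smoothed
    path displacement between frames lo..hi (indices into ``positions``)."""
    steps = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    path = np.concatenate([[0.0], np.cumsum(steps)])
    sm, dv = smooth_series(path, frame_rate, config)
    vmax = float(np.max(dv[lo:hi + 1]))
    disp = float(sm[hi] - sm[lo])
    return vmax, disp


def segment_linear_velocities(
    traj: Trajectory3D,
    window: tuple[int, int],
    phases_window: tuple[int, int],
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Maximum linear velocity (cm/s) of each foreleg segment.

    Each segment's linear displacement is the cumulative 3D path of its
    distal landmark (coxa -> trochanter, femur -> femorotibial joint,
    tibia -> tibia tip); velocity is the derivative of the smoothed path and
    the maximum is taken over the strike (start..capture).
    """
    config = config or PipelineConfig()
    a, b = window
    lo, hi = phases_window[0] - a, phases_window[1] - a
    out = {}
    for name, idx in (("coxa", P2), ("femur", P3), ("tibia", P4)):
        _require_landmarks(traj, (idx,), window)
        vmax, _ = _path_speed_max(traj.coords[a:b, idx], traj.frame_rate,
                                  config, lo, hi)
        out[name] = max(vmax, 0.0)
    return out


def body_motion(
    traj: Trajectory3D,
    window: tuple[int, int],
    phases_window: tuple[int, int],
    config: PipelineConfig | None = None,
) -> tuple[float, float]:
    """Body displacement (cm) and maximum body velocity (cm/s).

    The body is tracked as the midpoint of the procoxal and mesocoxal joints
    (points 1 and 5); displacement is the smoothed path length from strike
    start to capture, velocity the maximum of the smoothed derivative.
    """
    config = config or PipelineConfig()
    a, b = window
    _require_landmarks(traj, (P1, P5), window)
    mid = 0.5 * (traj.coords[a:b, P1] + traj.coords[a:b, P5])
    lo, hi = phases_window[0] - a, phases_window[1] - a
    vmax, disp = _path_speed_max(mid, traj.frame_rate, config, lo, hi)
    return max(disp, 0.0), max(vmax, 0.0)


# --- capture triangle ------------------------------------------------------

def _triangle_contains(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, q: np.ndarray, tol: float
) -> bool:
    """True if q projects inside triangle (a, b, c) and lies within ``tol``
    of its plane."""
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn == 0:
        return False
    n = n / nn
    d = float(np.dot(q - a, n))
    if abs(d) > tol:
        return False
    p = q - d * n
    # barycentric containment
    v0, v1, v2 = c - a, b - a, p - a
    d00, d01, d02 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v0, v2)
    d11, d12 = np.dot(v1, v1), np.dot(v1, v2)
    denom = d00 * d11 - d01 * d01
    if denom == 0:
        return False
    u = (d11 * d02 - d01 * d12) / denom
    v = (d00 * d12 - d01 * d02) / denom
    return u >= 0.0 and v >= 0.0 and (u + v) <= 1.0


def capture_triangle(coords_frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Capture-triangle vertices at one frame: left tibia tip, right tibia
    tip, and the midpoint of the two trochanters."""
    return (
        coords_frame[P4],
        coords_frame[P10],
        0.5 * (coords_frame[P2] + coords_frame[P8]),
    )


def detect_strike_window(
    traj: Trajectory3D,
    config: PipelineConfig | None = None,
) -> tuple[int, int]:
    """Detect ``(strike_start_frame, capture_frame)``.

    Strike start is the earliest frame at which any foreleg landmark's speed
    exceeds its baseline noise floor (mean + 3 SD over the first
    ``baseline_frames`` frames, falling back to 5% of the trial maximum when
    the baseline is silent).  Capture is the first subsequent frame at which
    the prey lies inside the foreleg triangle within a plane tolerance of
    ``capture_plane_tol_frac`` x mean femur length.  A prey that never enters
    the triangle raises :class:`NoCaptureError`.
    """
    config = config or PipelineConfig()
    fps = traj.frame_rate
    foreleg = (P2, P3, P4, P8, P9, P10)
    F = traj.n_frames
    if F < 3:
        raise NoCaptureError("trajectory too short to contain a strike")

    # raw per-landmark speeds, lightly averaged over 3 frames
    start: int | None = None
    for idx in foreleg:
        pos = traj.coords[:, idx, :]
        v = np.linalg.norm(np.diff(pos, axis=0), axis=1) * fps
        if v.size >= 3:
            v = np.convolve(v, np.ones(3) / 3.0, mode="same")
        nb = min(config.baseline_frames, v.size)
        base = v[:nb]
        vmax = float(np.nanmax(v)) if np.any(np.isfinite(v)) else 0.0
        if vmax <= 0:
            continue
        thr = float(np.nanmean(base) + config.onset_sd_mult * np.nanstd(base))
        if not np.isfinite(thr) or thr <= 1e-9 * vmax:
            thr = config.onset_fallback_frac * vmax
        crossed = np.nonzero(v > thr)[0]
        if crossed.size:
            start = int(crossed[0]) if start is None else min(start, int(crossed[0]))
    if start is None:
        raise NoCaptureError("no foreleg movement detected (motionless trial)")

    femur_len = float(np.nanmean(
        np.linalg.norm(traj.coords[:, P2] - traj.coords[:, P3], axis=1)))
    tol = config.capture_plane_tol_frac * femur_len

    for f in range(start + 1, F):
        c = traj.coords[f]
        needed = c[[P2, P4, P6, P8, P10]]
        if not np.all(np.isfinite(needed)):
            continue
        a, b, m = capture_triangle(c)
        if _triangle_contains(a, b, m, c[P6], tol):
            return start, f
    raise NoCaptureError("prey never entered the foreleg triangle; attempt excluded")


def detect_phases(
    angles: AngleSeries,
    strike_start_frame: int,
    capture_frame: int,
    config: PipelineConfig | None = None,
) -> StrikePhases:
    """Approach/sweep phase detection from the angle series.

    Approach start: first frame the standardized coxa angle reaches
    ``approach_start_frac`` of the peak coxa angle (the 99% rule value).
    Approach end (= sweep start): first subsequent frame the femur angular
    velocity reaches ``approach_end_frac`` of its maximum before capture.
    """
    config = config or PipelineConfig()
    cap = angles.index_of(capture_frame)
    coxa_std = angles.standardized["coxa"]
    peak_coxa = config.coxa_peak_factor * float(np.max(coxa_std))
    # a strike abducts the coxa by tens of degrees; excursions below half a
    # degree are flat profiles where the 5% threshold is meaningless
    if peak_coxa < 0.5:
        raise PhaseDetectionError("coxa angle is flat; no approach detected")

    thr_coxa = config.approach_start_frac * peak_coxa
    hits = np.nonzero(coxa_std[: cap + 1] >= thr_coxa)[0]
    if hits.size == 0:
        raise PhaseDetectionError("coxa never reached the approach-start threshold")
    a_start = int(hits[0])

    fem_av = angles.velocity["femur"][: cap + 1]
    thr_fem = config.approach_end_frac * float(np.max(fem_av))
    hits = np.nonzero(fem_av[a_start + 1:] >= thr_fem)[0]
    if hits.size == 0:
        raise PhaseDetectionError("femur velocity never reached the approach-end threshold")
    a_end = a_start + 1 + int(hits[0])
    if a_end >= cap:
        raise PhaseDetectionError("approach end not before capture")

    w0 = int(angles.frames[0])
    return StrikePhases(
        strike_start_frame=int(strike_start_frame),
        approach_start_frame=w0 + a_start,
        approach_end_frame=w0 + a_end,
        capture_frame=int(capture_frame),
        frame_rate=angles.frame_rate,
    )


def lateral_displacements(
    traj: Trajectory3D,
    window: tuple[int, int],
    phases_window: tuple[int, int],
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Maximum smoothed distances (cm) between homologous left/right joints.

    Pairs: trochanters (coxa/femur LD), femorotibial joints (femur/tibia LD),
    tibia tips (tibia LD); maxima are taken over the strike.
    """
    config = config or PipelineConfig()
    a, b = window
    lo, hi = phases_window[0] - a, phases_window[1] - a
    pairs = {
        "coxa_femur_ld": (P2, P8),
        "femur_tibia_ld": (P3, P9),
        "tibia_ld": (P4, P10),
    }
    out = {}
    for name, (l, r) in pairs.items():
        _require_landmarks(traj, (l, r), window)
        dist = np.linalg.norm(traj.coords[a:b, l] - traj.coords[a:b, r], axis=1)
        sm, _ = smooth_series(dist, traj.frame_rate, config)
        out[name] = float(np.max(sm[lo:hi + 1]))
    return out


def predator_prey_geometry(
    traj: Trajectory3D,
    strike_start_frame: int,
) -> tuple[float, float]:
    """Predator-prey distance (cm) and angle (deg) at the start of the strike.

    Distance: 3D distance from the left eye (point 7) to the prey (point 6).
    Angle: 3D angle between the anterior body axis (mesocoxal -> procoxal,
    5->1) and the eye-to-prey vector.
    """
    c = traj.coords[strike_start_frame]
    for i in (P1, P5, P6, P7):
        if not np.all(np.isfinite(c[i])):
            raise MissingLandmarkError(
                f"landmark {traj.labels[i]!r} missing at strike start")
    axis = c[P1] - c[P5]
    gaze = c[P6] - c[P7]
    if np.linalg.norm(axis) == 0:
        raise DegenerateGeometryError("points 1 and 5 coincide; body axis undefined")
    dist = float(np.linalg.norm(gaze))
    angle = float(_vector_angle_deg(axis[None, :], gaze[None, :])[0])
    return dist, angle


def extract_morphology(
    traj: Trajectory3D,
    window: tuple[int, int],
) -> MorphologyRecord:
    """Segment lengths averaged over the strike frames.

    Coxa: points 1-2; femur: 2-3; tibia: 3-4; metazona: 1-5.
    """
    a, b = window
    _require_landmarks(traj, (P1, P2, P3, P4, P5), window)
    c = traj.coords[a:b]

    def mean_len(i: int, j: int) -> float:
        return float(np.mean(np.linalg.norm(c[:, i] - c[:, j], axis=1)))

    return MorphologyRecord(
        coxa_length=mean_len(P1, P2),
        femur_length=mean_len(P2, P3),
        tibia_length=mean_len(P3, P4),
        metazona_length=mean_len(P1, P5),
    )


def extract_kinematic_record(
    traj: Trajectory3D,
    metadata: Mapping | None = None,
    config: PipelineConfig | None = None,
) -> KinematicRecord:
    """Run the full rule-based extraction on one trial.

    Detects the strike window, smooths over the window padded by
    ``pad_frames``, and assembles the complete 16-variable record plus
    phases and morphology.  Any detector failure propagates as its typed
    error; no partial record is emitted.
    """
    config = config or PipelineConfig()
    start, capture = detect_strike_window(traj, config)
    w0 = max(0, start - config.pad_frames)
    w1 = min(traj.n_frames, capture + config.pad_frames + 1)
    window = (w0, w1)
    strike = (start, capture)

    angles = joint_angle_series(traj, window, config)
    peaks = peak_angles(angles, capture, config)   # validates femur/tibia peaks
    avs = angular_velocities(angles, capture)
    phases = detect_phases(angles, start, capture, config)
    lvs = segment_linear_velocities(traj, window, strike, config)
    body_disp, body_vel = body_motion(traj, window, strike, config)
    lds = lateral_displacements(traj, window, strike, config)
    pp_dist, pp_angle = predator_prey_geometry(traj, start)
    morph = extract_morphology(traj, strike)

    i_start = angles.index_of(start)
    if config.coxa_start_standardized:
        coxa_start = float(angles.standardized["coxa"][i_start])
    else:
        coxa_start = float(angles.smoothed["coxa"][i_start])

    return KinematicRecord(
        coxa_lv=lvs["coxa"],
        femur_lv=lvs["femur"],
        coxa_av=avs["coxa"],
        femur_av=avs["femur"],
        tibia_av=avs["tibia"],
        tibia_lv=lvs["tibia"],
        coxa_start_angle=coxa_start,
        approach_time=phases.approach_time,
        pp_angle=pp_angle,
        pp_dist=pp_dist,
        body_velocity=body_vel,
        body_displacement=body_disp,
        sweep_time=phases.sweep_time,
        coxa_femur_ld=lds["coxa_femur_ld"],
        femur_tibia_ld=lds["femur_tibia_ld"],
        tibia_ld=lds["tibia_ld"],
        phases=phases,
        morphology=morph,
        metadata=dict(metadata or {}),
    )
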