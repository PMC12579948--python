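"""Synthetic strike, camera, phylogeny and trait generators.

Every downstream stage of the pipeline is testable against ground truth
produced here, with no external data:

* :func:`make_strike` builds a rigid 10-point kinematic chain (thorax axis,
  mirror-symmetric coxa/femur/tibia on both sides, eye, prey) driven by
  raised-cosine joint-angle profiles, so the true maxima, velocities and
  phase times are available in closed form;
* :func:`make_cameras_and_calibration` builds two synthetic pinhole cameras
  with roughly orthogonal optical axes (a ventral and a lateral view), their
  exact DLT coefficients, and noiseless observations of a calibration point
  cloud;
* :func:`project_strike` projects a strike through the cameras with optional
  Gaussian pixel noise, emulating tracked two-camera footage at 1000 fps;
* :func:`make_tree` and :func:`simulate_traits` produce ultrametric
  pure-birth phylogenies and species-structured trait tables under
  lambda-scaled Brownian motion with species and residual variance, the
  generative model the phylogenetic mixed model assumes.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import PipelineConfig
from .core import (LANDMARKS, P1, P2, P3, P4, P5, P6, P7, P8, P9, P10,
                   SegmentLengths, TrackedTrajectory2D, Trajectory3D)
from .dlt import CalibrationSet, CameraDLT, reproject
from .exceptions import DegenerateCalibrationError
from .kinematics import (KinematicRecord, MorphologyRecord, StrikePhases,
                         capture_triangle, _triangle_contains)
from .phylo import build_phylo_covariance

__all__ = [
    "StrikeParams",
    "GroundTruthStrike",
    "ComparativeSimSpec",
    "CAMOUFLAGE_LEVELS",
    "make_strike",
    "strike_params_for_velocities",
    "make_cameras_and_calibration",
    "project_strike",
    "make_tree",
    "simulate_traits",
]

CAMOUFLAGE_LEVELS = ("generalist", "flower", "dead leaf", "stick")

# phase-layout fractions of the sweep used by the generator (see methods note)
_FEMUR_OPEN_FRAC = 0.55    # fast femur opening, as a fraction of sweep time
_FEMUR_CLOSE_FRAC = 0.30
_TIBIA_PEAK_FRAC = 0.50    # tibia angular peak, into the sweep
_TIBIA_CLOSE_FRAC = 0.45


def _rc(t: np.ndarray | float, start: float, duration: float) -> np.ndarray:
    """Raised-cosine ramp: 0 before ``start``, 1 after ``start+duration``."""
    s = np.clip((np.asarray(t, dtype=float) - start) / duration, 0.0, 1.0)
    return (1.0 - np.cos(np.pi * s)) / 2.0


@dataclass
class StrikeParams:
    """Parameters of one synthetic prey-capture attempt.

    Angles in degrees, lengths in cm, durations in s.  ``approach_duration``
    and ``sweep_duration`` are the *operational* phase times, i.e. the times
    the rule-based detector defines (coxa at 5% of peak angle to femur
    velocity at 10% of max; then to capture); the generator lays out its
    profiles so those detector definitions hold analytically.
    """

    segment_lengths: SegmentLengths = field(default_factory=SegmentLengths)
    frame_rate: float = 1000.0
    coxa_start_angle: float = 30.0
    coxa_peak_angle: float = 70.0
    femur_start_angle: float = 50.0
    femur_peak_angle: float = 120.0
    femur_end_angle: float = 95.0
    tibia_start_angle: float = 25.0
    tibia_peak_angle: float = 120.0
    tibia_end_angle: float = 30.0
    approach_duration: float = 0.020
    sweep_duration: float = 0.022
    body_lunge: float = 0.6
    lateral_spread_peak: float = 2.5
    prey_start_position: tuple[float, float, float] | None = None
    prey_distance: float = 3.5       # used when prey_start_position is None
    prey_angle_deg: float = 25.0
    spread_start_deg: float = 12.0
    pre_roll_frames: int = 30
    post_roll_frames: int = 10
    noise_sd_pixels: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.approach_duration <= 0 or self.sweep_duration <= 0:
            raise ValueError("durations must be positive")
        if not (0 <= self.coxa_start_angle < self.coxa_peak_angle <= 180):
            raise ValueError("need 0 <= coxa_start_angle < coxa_peak_angle <= 180")
        for lo, hi in ((self.femur_start_angle, self.femur_peak_angle),
                       (self.tibia_start_angle, self.tibia_peak_angle)):
            if not (0 < lo < hi <= 180):
                raise ValueError("joint start angles must lie below peak angles in (0, 180]")
        if not (self.femur_start_angle <= self.femur_end_angle < self.femur_peak_angle):
            raise ValueError("femur_end_angle must lie in [start, peak)")
        if not (self.tibia_start_angle <= self.tibia_end_angle < self.tibia_peak_angle):
            raise ValueError("tibia_end_angle must lie in [start, peak)")
        if self.body_lunge < 0 or self.lateral_spread_peak <= 0:
            raise ValueError("body_lunge must be >= 0 and lateral_spread_peak > 0")
        if self.noise_sd_pixels < 0:
            raise ValueError("noise_sd_pixels must be >= 0")
        min_frames = 10
        if (self.approach_duration * self.frame_rate < min_frames
                or self.sweep_duration * self.frame_rate < min_frames):
            raise ValueError(
                f"approach and sweep must each span >= {min_frames} frames "
                f"at {self.frame_rate} fps"
            )


@dataclass
class GroundTruthStrike:
    """A synthetic strike with its generating truth.

    ``trajectory`` is the noiseless 3D landmark trajectory; ``true_angles``
    holds the generating joint-angle series per frame; ``true_record`` the
    kinematic record known from the generating profiles (closed form for
    angular quantities and times, dense quadrature for path-based maxima).
    """

    trajectory: Trajectory3D
    true_angles: dict[str, np.ndarray]
    true_record: KinematicRecord
    prey_track: np.ndarray
    params: StrikeParams
    events: dict[str, float]


class _StrikeModel:
    """Continuous-time forward model used internally by make_strike."""

    def __init__(self, p: StrikeParams, config: PipelineConfig):
        self.p = p
        fps = p.frame_rate
        g = config.approach_start_frac * config.coxa_peak_factor
        c5 = math.acos(1.0 - 2.0 * g) / math.pi
        self.t0 = p.pre_roll_frames / fps
        self.Tc = p.approach_duration / (1.0 - c5)
        self.t5 = self.t0 + c5 * self.Tc
        self.t_ae = self.t0 + self.Tc              # = t5 + approach_duration
        Ts = p.sweep_duration
        self.t_cap = self.t_ae + Ts
        self.D_fo = _FEMUR_OPEN_FRAC * Ts
        self.t_fo = self.t_ae - (self.D_fo / math.pi) * math.asin(config.approach_end_frac)
        self.D_fc = _FEMUR_CLOSE_FRAC * Ts
        self.t_tpk = self.t_ae + _TIBIA_PEAK_FRAC * Ts
        self.D_tc = _TIBIA_CLOSE_FRAC * Ts
        if self.t_fo < self.t0:
            raise ValueError("femur opening would begin before strike onset; "
                             "increase approach_duration or reduce sweep_duration")
        self._phi_peak = None  # set by calibrate_spread

    # angle profiles (deg)
    def coxa(self, t):
        p = self.p
        return p.coxa_start_angle + (p.coxa_peak_angle - p.coxa_start_angle) * \
            _rc(t, self.t0, self.Tc)

    def femur(self, t):
        p = self.p
        return (p.femur_start_angle
                + (p.femur_peak_angle - p.femur_start_angle) * _rc(t, self.t_fo, self.D_fo)
                - (p.femur_peak_angle - p.femur_end_angle)
                * _rc(t, self.t_fo + self.D_fo, self.D_fc))

    def tibia(self, t):
        p = self.p
        return (p.tibia_start_angle
                + (p.tibia_peak_angle - p.tibia_start_angle) * _rc(t, self.t0, self.t_tpk - self.t0)
                - (p.tibia_peak_angle - p.tibia_end_angle) * _rc(t, self.t_tpk, self.D_tc))

    def spread(self, t):
        p = self.p
        phi0 = math.radians(p.spread_start_deg)
        return phi0 + (self._phi_peak - phi0) * _rc(t, self.t0, self.t_tpk - self.t0)

    def body_x(self, t):
        return self.p.body_lunge * _rc(t, self.t0, self.t_cap - self.t0)

    def chain(self, t, phi_peak=None):
        """Landmark positions at times t; returns (len(t), 10, 3)."""
        if phi_peak is not None:
            saved, self._phi_peak = self._phi_peak, phi_peak
        t = np.atleast_1d(np.asarray(t, dtype=float))
        p = self.p
        L = p.segment_lengths
        thc = np.radians(self.coxa(t))
        thf = np.radians(self.femur(t))
        tht = np.radians(self.tibia(t))
        phi = self.spread(t)
        if phi_peak is not None:
            self._phi_peak = saved

        out = np.empty((t.size, 10, 3))
        x = self.body_x(t)
        p1 = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        u = np.array([-1.0, 0.0, 0.0])
        out[:, P1] = p1
        out[:, P5] = p1 + L.metazona * u
        out[:, P7] = p1 + np.array([0.30 * L.metazona, 0.06 * L.metazona,
                                    0.12 * L.metazona])
        a_coxa = thc
        a_femur = thc + math.pi - thf
        a_tibia = thc - thf + tht
        for side, (i2, i3, i4) in ((+1, (P2, P3, P4)), (-1, (P8, P9, P10))):
            w = np.column_stack([np.zeros_like(phi),
                                 side * np.sin(phi), np.cos(phi)])

            def direction(alpha):
                return np.cos(alpha)[:, None] * u + np.sin(alpha)[:, None] * w

            out[:, i2] = out[:, P1] + L.coxa * direction(a_coxa)
            out[:, i3] = out[:, i2] + L.femur * direction(a_femur)
            out[:, i4] = out[:, i3] + L.tibia * direction(a_tibia)
        return out

    def calibrate_spread(self) -> None:
        """Choose the peak spread half-angle so the maximum tibia-tip
        separation over the strike equals ``lateral_spread_peak``."""
        p = self.p
        tt = np.linspace(self.t0, self.t_cap, 220)
        phi0 = math.radians(p.spread_start_deg)

        def max_sep(phi_peak: float) -> float:
            c = self.chain(tt, phi_peak=phi_peak)
            return float(np.max(np.linalg.norm(c[:, P4] - c[:, P10], axis=1)))

        target = p.lateral_spread_peak
        lo, hi = phi0 + 1e-6, math.radians(80.0)
        if max_sep(lo) >= target:
            raise ValueError(
                "lateral_spread_peak smaller than the baseline spread; "
                "reduce spread_start_deg or increase the target")
        if max_sep(hi) <= target:
            raise ValueError("lateral_spread_peak unreachable for this geometry")
        self._phi_peak = brentq(lambda v: max_sep(v) - target, lo, hi, xtol=1e-10)


def make_strike(
    params: StrikeParams,
    config: PipelineConfig | None = None,
) -> GroundTruthStrike:
    """Generate one noiseless synthetic strike with closed-form ground truth.

    The coxa abducts from its start to its peak angle across the approach;
    the femur and tibia open and then close rapidly during the sweep (the
    tibia flexing to secure the prey); the body lunges forward along its
    axis; the prey moves linearly into the foreleg triangle, crossing it on
    the final strike frame.
    """
    config = config or PipelineConfig()
    m = _StrikeModel(params, config)
    m.calibrate_spread()
    p = params
    fps = p.frame_rate

    cap_frame_nominal = int(round(m.t_cap * fps))
    n_frames = cap_frame_nominal + p.post_roll_frames + 1
    t_frames = np.arange(n_frames) / fps
    coords = m.chain(t_frames)

    # prey: hold, then dart on a straight line into the capture triangle's
    # centroid, arriving on the nominal capture frame (an evasive fly passing
    # as the legs close).  The motion onset is delayed adaptively so that the
    # first containment frame -- under the same geometric rule the detector
    # uses -- is the nominal capture frame, not an accidental early crossing
    # of the sweeping triangle.
    tri = capture_triangle(coords[cap_frame_nominal])
    target = (tri[0] + tri[1] + tri[2]) / 3.0
    if p.prey_start_position is not None:
        prey0 = np.asarray(p.prey_start_position, dtype=float)
    else:
        head0 = coords[0, P7]
        ang = math.radians(p.prey_angle_deg)
        prey0 = head0 + p.prey_distance * np.array([math.cos(ang), 0.0, math.sin(ang)])

    tol = config.capture_plane_tol_frac * p.segment_lengths.femur

    def first_containment(prey_path: np.ndarray) -> int | None:
        for f in range(p.pre_roll_frames + 1, n_frames):
            a, b, mid = capture_triangle(coords[f])
            if _triangle_contains(a, b, mid, prey_path[f], tol):
                return f
        return None

    t_pm = m.t_ae
    min_dart = 3.0 / fps
    prey = None
    cap_frame = None
    for _ in range(10):
        frac = np.clip((t_frames - t_pm) / (m.t_cap - t_pm), 0.0, 1.0)
        prey = prey0[None, :] + frac[:, None] * (target - prey0)[None, :]
        cap_frame = first_containment(prey)
        if cap_frame is None:
            cap_frame = cap_frame_nominal
            break
        if cap_frame >= cap_frame_nominal - 1 or (m.t_cap - t_pm) <= min_dart:
            break
        t_pm = m.t_cap - 0.6 * (m.t_cap - t_pm)
    coords[:, P6] = prey

    traj = Trajectory3D(coords=coords, frame_rate=fps)

    # closed-form angular truths
    d_coxa = p.coxa_peak_angle - p.coxa_start_angle
    coxa_av = d_coxa * math.pi / (2.0 * m.Tc)
    femur_av = (p.femur_peak_angle - p.femur_start_angle) * math.pi / (2.0 * m.D_fo)
    tibia_av = (p.tibia_peak_angle - p.tibia_end_angle) * math.pi / (2.0 * m.D_tc)

    # dense-quadrature truths for path-based quantities
    tf = np.arange(m.t0 * fps, cap_frame + 0.01, 0.125) / fps
    dense = m.chain(tf)
    dt = tf[1] - tf[0]

    def max_speed(idx: int) -> float:
        d = np.linalg.norm(np.diff(dense[:, idx], axis=0), axis=1) / dt
        return float(np.max(d))

    def max_pair(i: int, j: int) -> float:
        return float(np.max(np.linalg.norm(dense[:, i] - dense[:, j], axis=1)))

    # displacement truth evaluated at the realized capture frame (the lunge
    # ramp is flat at its end, so a frame of slack changes this negligibly)
    body_disp = p.body_lunge * float(_rc(cap_frame / fps, m.t0, m.t_cap - m.t0))
    body_vel = p.body_lunge * math.pi / (2.0 * (m.t_cap - m.t0)) if p.body_lunge else 0.0

    head0 = coords[p.pre_roll_frames, P7]
    prey_at_start = prey[p.pre_roll_frames]
    pp_vec = prey_at_start - head0
    pp_dist = float(np.linalg.norm(pp_vec))
    axis = coords[p.pre_roll_frames, P1] - coords[p.pre_roll_frames, P5]
    cosang = float(np.dot(axis, pp_vec) / (np.linalg.norm(axis) * pp_dist))
    pp_angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    phases = StrikePhases(
        strike_start_frame=p.pre_roll_frames,
        approach_start_frame=int(round(m.t5 * fps)),
        approach_end_frame=int(round(m.t_ae * fps)),
        capture_frame=cap_frame,
        frame_rate=fps,
    )
    record = KinematicRecord(
        coxa_lv=max_speed(P2),
        femur_lv=max_speed(P3),
        coxa_av=coxa_av,
        femur_av=femur_av,
        tibia_av=tibia_av,
        tibia_lv=max_speed(P4),
        coxa_start_angle=p.coxa_start_angle,
        approach_time=p.approach_duration,
        pp_angle=pp_angle,
        pp_dist=pp_dist,
        body_velocity=body_vel,
        body_displacement=body_disp,
        sweep_time=cap_frame / fps - m.t_ae,
        coxa_femur_ld=max_pair(P2, P8),
        femur_tibia_ld=max_pair(P3, P9),
        tibia_ld=max_pair(P4, P10),
        phases=phases,
        morphology=MorphologyRecord(
            coxa_length=p.segment_lengths.coxa,
            femur_length=p.segment_lengths.femur,
            tibia_length=p.segment_lengths.tibia,
            metazona_length=p.segment_lengths.metazona,
        ),
        metadata={"seed": p.seed},
    )
    true_angles = {
        "coxa": m.coxa(t_frames),
        "femur": m.femur(t_frames),
        "tibia": m.tibia(t_frames),
    }
    events = {
        "onset": m.t0, "coxa_5pct": m.t5, "approach_end": m.t_ae,
        "capture": cap_frame / fps, "capture_frame": float(cap_frame),
    }
    return GroundTruthStrike(
        trajectory=traj,
        true_angles=true_angles,
        true_record=record,
        prey_track=prey,
        params=params,
        events=events,
    )


def lateral_spread_bounds(
    params: StrikeParams,
    config: PipelineConfig | None = None,
) -> tuple[float, float]:
    """Reachable (baseline, maximum) tibia-tip separation for this geometry,
    evaluated at the resting and near-maximal spread half-angles."""
    m = _StrikeModel(params, config or PipelineConfig())
    tt = np.linspace(m.t0, m.t_cap, 220)

    def max_sep(phi_peak: float) -> float:
        c = m.chain(tt, phi_peak=phi_peak)
        return float(np.max(np.linalg.norm(c[:, P4] - c[:, P10], axis=1)))

    return (max_sep(math.radians(params.spread_start_deg) + 1e-6),
            max_sep(math.radians(80.0)))


def strike_params_for_velocities(
    femur_av: float,
    tibia_av: float,
    coxa_start_angle: float = 30.0,
    approach_duration: float = 0.020,
    body_lunge: float = 0.6,
    lateral_spread_peak: float = 2.5,
    segment_lengths: SegmentLengths | None = None,
    seed: int = 0,
    **extra,
) -> StrikeParams:
    """Build :class:`StrikeParams` whose analytic angular-velocity maxima hit
    the requested femur and tibia values (deg/s).

    The femur opening amplitude and sweep duration are solved from the target
    velocities under the generator's fixed phase-layout fractions; amplitudes
    are capped at anatomically sensible values.
    """
    ratio = tibia_av / femur_av
    frac = _TIBIA_CLOSE_FRAC / _FEMUR_OPEN_FRAC
    d_f = min(75.0, 100.0 / (frac * ratio))  # keep tibia close amplitude <= 100 deg
    d_f = max(d_f, 25.0)
    d_fo = d_f * math.pi / (2.0 * femur_av)
    sweep = d_fo / _FEMUR_OPEN_FRAC
    d_tc = _TIBIA_CLOSE_FRAC * sweep
    d_t_close = tibia_av * 2.0 * d_tc / math.pi
    tibia_start = 22.0
    tibia_end = tibia_start + 3.0
    tibia_peak = tibia_end + d_t_close
    if tibia_peak > 178.0:
        raise ValueError("requested tibia velocity implies an impossible amplitude")
    femur_start = 45.0
    femur_peak = femur_start + d_f
    coxa_peak = min(coxa_start_angle + 40.0, 178.0)
    return StrikeParams(
        segment_lengths=segment_lengths or SegmentLengths(),
        coxa_start_angle=coxa_start_angle,
        coxa_peak_angle=coxa_peak,
        femur_start_angle=femur_start,
        femur_peak_angle=femur_peak,
        femur_end_angle=femur_peak - min(25.0, d_f - 1.0),
        tibia_start_angle=tibia_start,
        tibia_peak_angle=tibia_peak,
        tibia_end_angle=tibia_end,
        approach_duration=approach_duration,
        sweep_duration=sweep,
        body_lunge=body_lunge,
        lateral_spread_peak=lateral_spread_peak,
        seed=seed,
        **extra,
    )


# ---------------------------------------------------------------------------
# cameras

def _look_at(center: np.ndarray, target: np.ndarray, up: np.ndarray) -> np.ndarray:
    z = target - center
    z = z / np.linalg.norm(z)
    x = np.cross(up, z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def _pinhole_dlt(center: np.ndarray, target: np.ndarray, up: np.ndarray,
                 focal_px: float = 2500.0, pp: tuple[float, float] = (512.0, 512.0),
                 ) -> CameraDLT:
    R = _look_at(center, target, up)
    K = np.array([[focal_px, 0.0, pp[0]],
                  [0.0, focal_px, pp[1]],
                  [0.0, 0.0, 1.0]])
    P = K @ np.hstack([R, -R @ center[:, None]])
    L = (P / P[2, 3]).ravel()
    return CameraDLT(L[:11])


def make_cameras_and_calibration(
    volume_cm: tuple[float, float, float] = (9.0, 5.0, 8.0),
    n_points: int = 12,
    seed: int = 0,
    center: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> tuple[CalibrationSet, tuple[CameraDLT, CameraDLT]]:
    """Two synthetic pinhole views (ventral and lateral) of a calibration
    point cloud filling ``volume_cm``, with exact DLT coefficients and
    noiseless observations.

    Raises :class:`DegenerateCalibrationError` for fewer than 6 points (the
    DLT minimum) or a coplanar cloud.
    """
    if n_points < 6:
        raise DegenerateCalibrationError("DLT calibration needs >= 6 points")
    rng = np.random.default_rng(seed)
    c = np.asarray(center, dtype=float)
    vol = np.asarray(volume_cm, dtype=float)
    for _ in range(32):
        pts = c + (rng.random((n_points, 3)) - 0.5) * vol
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[2] > 1e-6 * sv[0]:
            break
    else:  # pragma: no cover - uniform draws are never coplanar in practice
        raise DegenerateCalibrationError("could not draw a non-coplanar point set")

    dist = 6.0 * float(np.max(vol))
    cam_ventral = _pinhole_dlt(c + np.array([0.0, 0.0, -dist]), c,
                               up=np.array([0.0, 1.0, 0.0]))
    cam_lateral = _pinhole_dlt(c + np.array([0.0, -dist, 0.0]), c,
                               up=np.array([0.0, 0.0, 1.0]))
    obs = [reproject(cam_ventral, pts), reproject(cam_lateral, pts)]
    return CalibrationSet(points_3d=pts, observations=obs), (cam_ventral, cam_lateral)


def project_strike(
    strike: GroundTruthStrike | Trajectory3D,
    cameras: tuple[CameraDLT, CameraDLT],
    noise_sd_pixels: float = 0.0,
    seed: int = 0,
) -> tuple[TrackedTrajectory2D, TrackedTrajectory2D]:
    """Project a strike through both cameras with i.i.d. Gaussian pixel noise.

    Returns one tracked 2D trajectory per camera with unit confidence.
    """
    if noise_sd_pixels < 0:
        raise ValueError("noise_sd_pixels must be >= 0")
    traj = strike.trajectory if isinstance(strike, GroundTruthStrike) else strike
    rng = np.random.default_rng(seed)
    out = []
    F, Lm, _ = traj.coords.shape
    flat = traj.coords.reshape(-1, 3)
    for cam in cameras:
        px = reproject(cam, flat).reshape(F, Lm, 2)
        if noise_sd_pixels > 0:
            px = px + rng.normal(0.0, noise_sd_pixels, size=px.shape)
        out.append(TrackedTrajectory2D(points=px, labels=traj.labels,
                                       frame_rate=traj.frame_rate))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# phylogenies and comparative traits

def make_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Seeded pure-birth tree with ``n_species`` tips, ultrametric, height 1.

    Tips are labelled ``sp01 .. spNN`` deterministically.
    """
    if n_species < 2:
        raise ValueError("a phylogeny needs at least 2 species")
    rng = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng,
    )
    # the simulation stops at the nth birth, leaving that pair of tips with
    # zero-length edges; extend every extant lineage by the waiting time to
    # the next (uncommitted) event, as in the standard pure-birth construction
    delta = rng.expovariate(n_species * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + delta
    tree.seed_node.edge.length = None
    # relabel tips deterministically in traversal order
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        label = f"sp{i:02d}"
        leaf.taxon.label = label
    # scale to unit height
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    h = max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / h
    return tree


@dataclass
class ComparativeSimSpec:
    """Generative model for a species-structured comparative trait table.

    The response is
    ``y = intercept + camouflage effect + beta_between * species-mean
    morphology + beta_within * individual deviation + phylogenetic species
    effect + i.i.d. species effect + residual``,
    where the phylogenetic effect is multivariate normal with covariance
    ``sigma2_phylo * Sigma(lambda_true)`` and ``Sigma(lambda_true)`` is the
    unit-height tree covariance with off-diagonals multiplied by
    ``lambda_true`` (the Pagel transform).
    """

    n_individuals_per_species: int = 5
    lambda_true: float = 1.0
    sigma2_phylo: float = 1.0
    sigma2_species: float = 0.0
    sigma2_resid: float = 0.25
    intercept: float = 0.0
    beta_camouflage: dict[str, float] = field(default_factory=dict)
    beta_morph_between: float = 0.0
    beta_morph_within: float = 0.0
    seed: int = 0
    n_species: int | None = None  # informative; checked against the tree

    def __post_init__(self) -> None:
        for name in ("sigma2_phylo", "sigma2_species", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.n_individuals_per_species < 1:
            raise ValueError("n_individuals_per_species must be >= 1")


def simulate_traits(tree: dendropy.Tree, spec: ComparativeSimSpec) -> pd.DataFrame:
    """Simulate a comparative trait table on ``tree`` under ``spec``.

    Returns one row per individual with columns ``species``, ``individual``,
    ``camouflage``, ``morph_species_mean``, ``morph_within``, ``morph`` and
    the response ``y``.
    """
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n_sp = len(species)
    if n_sp < 2:
        raise ValueError("tree must have >= 2 tips")
    if spec.n_species is not None and spec.n_species != n_sp:
        raise ValueError(f"spec.n_species={spec.n_species} but tree has {n_sp} tips")

    rng = np.random.default_rng(spec.seed)
    sigma = build_phylo_covariance(tree, species).to_numpy()
    sig_l = sigma * spec.lambda_true
    np.fill_diagonal(sig_l, np.diag(sigma))

    if spec.sigma2_phylo > 0:
        chol = np.linalg.cholesky(spec.sigma2_phylo * sig_l + 1e-12 * np.eye(n_sp))
        a = chol @ rng.standard_normal(n_sp)
    else:
        a = np.zeros(n_sp)
    u = rng.normal(0.0, math.sqrt(spec.sigma2_species), n_sp) \
        if spec.sigma2_species > 0 else np.zeros(n_sp)
    morph_mean = rng.standard_normal(n_sp)

    rows = []
    for si, sp in enumerate(species):
        cam = CAMOUFLAGE_LEVELS[si % len(CAMOUFLAGE_LEVELS)]
        beta_cam = spec.beta_camouflage.get(cam, 0.0)
        for k in range(spec.n_individuals_per_species):
            within = rng.standard_normal()
            eps = rng.normal(0.0, math.sqrt(spec.sigma2_resid)) \
                if spec.sigma2_resid > 0 else 0.0
            y = (spec.intercept + beta_cam
                 + spec.beta_morph_between * morph_mean[si]
                 + spec.beta_morph_within * within
                 + a[si] + u[si] + eps)
            rows.append({
                "species": sp,
                "individual": f"{sp}_i{k + 1}",
                "camouflage": cam,
                "morph_species_mean": morph_mean[si],
                "morph_within": within,
                "morph": morph_mean[si] + within,
                "y": y,
            })
    return pd.DataFrame(rows)
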