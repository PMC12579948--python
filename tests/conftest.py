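import numpy as np
import pytest

from strikekin import (
    PipelineConfig,
    StrikeParams,
    make_cameras_and_calibration,
    make_strike,
    project_strike,
    reconstruct_3d,
)


@pytest.fixture(scope="session")
def cameras():
    """Calibration set and the two exact synthetic cameras."""
    return make_cameras_and_calibration(volume_cm=(9.0, 5.0, 8.0),
                                        n_points=12, seed=3)


@pytest.fixture(scope="session")
def default_strike():
    return make_strike(StrikeParams())


@pytest.fixture(scope="session")
def noiseless_trajectory(default_strike, cameras):
    """The default strike projected through both cameras and reconstructed."""
    _, cams = cameras
    t1, t2 = project_strike(default_strike, cams, noise_sd_pixels=0.0, seed=1)
    return reconstruct_3d(t1, t2, cams[0], cams[1])


@pytest.fixture()
def config():
    return PipelineConfig()


def planar_chain_trajectory(coxa_deg, femur_deg, tibia_deg, frame_rate=1000.0,
                            lengths=(1.0, 1.6, 0.9, 1.4), spread_deg=15.0,
                            prey=None):
    """Minimal forward kinematics independent of the package generator.

    Builds a 10-landmark trajectory from per-frame joint-angle arrays with
    mirror-symmetric legs; used as a hand-rolled oracle for the angle and
    event extractors.
    """
    coxa = np.radians(np.asarray(coxa_deg, dtype=float))
    femur = np.radians(np.asarray(femur_deg, dtype=float))
    tibia = np.radians(np.asarray(tibia_deg, dtype=float))
    F = coxa.size
    Lc, Lf, Lt, Lm = lengths
    phi = np.radians(spread_deg)
    coords = np.full((F, 10, 3), np.nan)
    p1 = np.zeros((F, 3))
    u = np.array([-1.0, 0.0, 0.0])
    coords[:, 0] = p1
    coords[:, 4] = p1 + Lm * u
    coords[:, 6] = p1 + np.array([0.3 * Lm, 0.06 * Lm, 0.12 * Lm])
    for side, (i2, i3, i4) in ((+1, (1, 2, 3)), (-1, (7, 8, 9))):
        w = np.array([0.0, side * np.sin(phi), np.cos(phi)])

        def direction(alpha):
            return np.cos(alpha)[:, None] * u + np.sin(alpha)[:, None] * w

        a2 = coxa
        a3 = coxa + np.pi - femur
        a4 = coxa - femur + tibia
        coords[:, i2] = coords[:, 0] + Lc * direction(a2)
        coords[:, i3] = coords[:, i2] + Lf * direction(a3)
        coords[:, i4] = coords[:, i3] + Lt * direction(a4)
    coords[:, 5] = prey if prey is not None else coords[:, 6] + np.array([2.0, 0.0, 1.0])
    from strikekin import Trajectory3D

    return Trajectory3D(coords=coords, frame_rate=frame_rate)
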