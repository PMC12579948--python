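"""Readers and writers for the pipeline's interchange formats.

CSV is the interchange format throughout: tracked 2D points in either the
three-header-row markerless-tracking dialect (scorer/bodyparts/coords) or a
flat x,y-per-point dialect; calibration point sets; tidy 3D trajectories;
one-row-per-trial kinematics tables.  Trees are Newick (dendropy), model
summaries JSON, configuration YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core import LANDMARKS, TrackedTrajectory2D, Trajectory3D
from .dlt import CalibrationSet
from .kinematics import TABLE1_LABELS, KinematicRecord

__all__ = [
    "write_tracking_csv",
    "read_tracking_csv",
    "write_calibration_csv",
    "read_calibration_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "records_to_table",
    "write_kinematics_csv",
    "read_kinematics_csv",
    "read_newick",
    "write_newick",
    "write_truth_json",
]

_MORPH_COLS = ("coxa_length", "femur_length", "tibia_length", "metazona_length")


# ---------------------------------------------------------------------------
# tracked 2D trajectories

def write_tracking_csv(
    track: TrackedTrajectory2D,
    path: str | Path,
    dialect: str = "dlc",
    scorer: str = "strikekin",
) -> None:
    """Write a 2D track in the ``dlc`` (scorer/bodyparts/coords, with a
    likelihood column per point) or ``flat`` (label_x, label_y) dialect."""
    path = Path(path)
    F = track.n_frames
    if dialect == "dlc":
        cols = pd.MultiIndex.from_tuples(
            [(scorer, lab, c) for lab in track.labels
             for c in ("x", "y", "likelihood")],
            names=["scorer", "bodyparts", "coords"],
        )
        data = np.empty((F, 3 * len(track.labels)))
        for i in range(len(track.labels)):
            data[:, 3 * i:3 * i + 2] = track.points[:, i, :]
            data[:, 3 * i + 2] = track.confidence[:, i]
        pd.DataFrame(data, columns=cols).to_csv(path, index_label=None)
    elif dialect == "flat":
        out = {"frame": np.arange(F)}
        for i, lab in enumerate(track.labels):
            out[f"{lab}_x"] = track.points[:, i, 0]
            out[f"{lab}_y"] = track.points[:, i, 1]
            out[f"{lab}_conf"] = track.confidence[:, i]
        pd.DataFrame(out).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown tracking dialect {dialect!r}")


def _detect_dialect(path: Path) -> str:
    head = path.open().readline()
    return "dlc" if head.split(",")[0].strip().lower() == "scorer" else "flat"


def read_tracking_csv(
    path: str | Path,
    dialect: str | None = None,
    confidence_cutoff: float = 0.6,
    frame_rate: float = 1000.0,
    labels: tuple[str, ...] = LANDMARKS,
) -> TrackedTrajectory2D:
    """Read a tracked 2D trajectory.

    Points whose likelihood falls below ``confidence_cutoff`` are marked
    missing (NaN coordinates).  Raises ``ValueError`` naming the landmark for
    missing columns and the file for malformed input.
    """
    path = Path(path)
    dialect = dialect or _detect_dialect(path)
    if dialect == "dlc":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
        dupes = [b for b in set(bodyparts) if bodyparts.count(b) > 1]
        if dupes:
            raise ValueError(f"{path}: duplicate landmark labels {dupes}")
        F = len(df)
        pts = np.full((F, len(labels), 2), np.nan)
        conf = np.zeros((F, len(labels)))
        scorer = df.columns.get_level_values(0)[0]
        for i, lab in enumerate(labels):
            try:
                x = df[(scorer, lab, "x")].to_numpy(float)
                y = df[(scorer, lab, "y")].to_numpy(float)
                lk = df[(scorer, lab, "likelihood")].to_numpy(float)
            except KeyError as exc:
                raise ValueError(f"{path}: missing landmark column {lab!r}") from exc
            pts[:, i, 0], pts[:, i, 1], conf[:, i] = x, y, lk
    elif dialect == "flat":
        df = pd.read_csv(path)
        F = len(df)
        pts = np.full((F, len(labels), 2), np.nan)
        conf = np.ones((F, len(labels)))
        for i, lab in enumerate(labels):
            if f"{lab}_x" not in df.columns or f"{lab}_y" not in df.columns:
                raise ValueError(f"{path}: missing landmark column {lab!r}")
            pts[:, i, 0] = df[f"{lab}_x"].to_numpy(float)
            pts[:, i, 1] = df[f"{lab}_y"].to_numpy(float)
            if f"{lab}_conf" in df.columns:
                conf[:, i] = df[f"{lab}_conf"].to_numpy(float)
    else:
        raise ValueError(f"unknown tracking dialect {dialect!r}")

    below = conf < confidence_cutoff
    pts[below] = np.nan
    return TrackedTrajectory2D(points=pts, labels=tuple(labels),
                               confidence=conf, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# calibration

def write_calibration_csv(calib: CalibrationSet, path: str | Path) -> None:
    """Point id, world X/Y/Z (cm), and per-camera pixel observations."""
    n = calib.points_3d.shape[0]
    out = {"point": np.arange(1, n + 1)}
    out["X"], out["Y"], out["Z"] = calib.points_3d.T
    for c, obs in enumerate(calib.observations, start=1):
        out[f"cam{c}_u"], out[f"cam{c}_v"] = obs.T
    pd.DataFrame(out).to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> CalibrationSet:
    df = pd.read_csv(path)
    for col in ("X", "Y", "Z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing calibration column {col!r}")
    pts = df[["X", "Y", "Z"]].to_numpy(float)
    obs = []
    c = 1
    while f"cam{c}_u" in df.columns:
        obs.append(df[[f"cam{c}_u", f"cam{c}_v"]].to_numpy(float))
        c += 1
    if len(obs) < 2:
        raise ValueError(f"{path}: need observations for at least 2 cameras")
    return CalibrationSet(points_3d=pts, observations=obs)


# ---------------------------------------------------------------------------
# 3D trajectories (tidy)

def write_trajectory_csv(traj: Trajectory3D, path: str | Path) -> None:
    """Tidy frame/landmark/x/y/z CSV with the frame rate in a comment line."""
    path = Path(path)
    F, L, _ = traj.coords.shape
    frames = np.repeat(np.arange(F), L)
    landmarks = np.tile(np.array(traj.labels), F)
    flat = traj.coords.reshape(F * L, 3)
    df = pd.DataFrame({
        "frame": frames, "landmark": landmarks,
        "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2],
    })
    with path.open("w") as fh:
        fh.write(f"# frame_rate={traj.frame_rate}\n")
        df.to_csv(fh, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory3D:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# frame_rate="):
            raise ValueError(f"{path}: missing '# frame_rate=' header line")
        frame_rate = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    labels = tuple(dict.fromkeys(df["landmark"]))
    F = int(df["frame"].max()) + 1
    coords = np.full((F, len(labels), 3), np.nan)
    li = {lab: i for i, lab in enumerate(labels)}
    coords[df["frame"].to_numpy(int), df["landmark"].map(li).to_numpy(int)] = \
        df[["x", "y", "z"]].to_numpy(float)
    return Trajectory3D(coords=coords, frame_rate=frame_rate, labels=labels)


# ---------------------------------------------------------------------------
# kinematics tables

def records_to_table(records: list[KinematicRecord]) -> pd.DataFrame:
    """One row per trial: metadata, the 16 variables (table labels), phase
    frames and morphology lengths."""
    rows = []
    for rec in records:
        row = dict(rec.metadata)
        row.update(rec.kinematic_values())
        if rec.morphology is not None:
            for c in _MORPH_COLS:
                row[c] = getattr(rec.morphology, c)
        if rec.phases is not None:
            row["strike_start_frame"] = rec.phases.strike_start_frame
            row["approach_start_frame"] = rec.phases.approach_start_frame
            row["approach_end_frame"] = rec.phases.approach_end_frame
            row["capture_frame"] = rec.phases.capture_frame
        rows.append(row)
    return pd.DataFrame(rows)


def write_kinematics_csv(records_or_table, path: str | Path) -> None:
    table = (records_or_table if isinstance(records_or_table, pd.DataFrame)
             else records_to_table(records_or_table))
    table.to_csv(path, index=False)


def read_kinematics_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a kinematics table; ``column_map`` renames foreign column layouts
    (e.g. a supplementary raw-data export) onto the canonical table labels."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [lab for lab in TABLE1_LABELS.values() if lab not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing kinematic columns {missing}")
    return df


# ---------------------------------------------------------------------------
# trees

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; requires labelled tips and branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError(f"{path}: unlabeled tip in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(f"{path}: tree edge without branch length")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True))


# ---------------------------------------------------------------------------
# ground-truth sidecars

def write_truth_json(strike, path: str | Path) -> None:
    """JSON sidecar with the generating parameters, events and true record."""
    rec = strike.true_record
    payload = {
        "params": {k: (v.as_dict() if hasattr(v, "as_dict") else v)
                   for k, v in asdict(strike.params).items()},
        "events": strike.events,
        "true_record": rec.kinematic_values(),
        "morphology": asdict(rec.morphology) if rec.morphology else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
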