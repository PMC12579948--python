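"""Dataset simulation and end-to-end pipeline orchestration.

``simulate_dataset`` writes a synthetic two-camera cohort to disk (tracking
CSVs per trial, calibration CSV, metadata table, companion Newick tree and
ground-truth sidecars).  ``run_pipeline`` consumes such a directory and runs
calibrate -> reconstruct -> extract -> select -> PCA/broken-stick -> PGLMM ->
contrasts -> classification, persisting every intermediate table and a
machine-readable run log.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import COHORT_NEWICK, video_trial_params
from .config import PipelineConfig
from .dlt import calibrate_dlt, reconstruct_3d
from .exceptions import PipelineError, StrikekinError
from .io import (read_calibration_csv, read_newick, read_tracking_csv,
                 records_to_table, write_calibration_csv,
                 write_kinematics_csv, write_tracking_csv,
                 write_trajectory_csv, write_truth_json)
from .kinematics import TABLE1_LABELS, extract_kinematic_record
from .stats import (add_within_species_centering, aicc_compare, broken_stick,
                    classify_hunting_style, fit_pglmm, individual_means,
                    pairwise_contrasts, pca_correlation, select_fastest)
from .synth import make_cameras_and_calibration, make_strike, project_strike

__all__ = ["simulate_dataset", "run_pipeline"]

_MORPH_COLS = ["coxa_length", "femur_length", "tibia_length", "metazona_length"]


def simulate_dataset(
    out_dir: str | Path,
    species: list[str] | None = None,
    n_individuals: int = 2,
    n_trials: int = 3,
    seed: int = 0,
    noise_sd_pixels: float = 0.0,
    config: PipelineConfig | None = None,
) -> Path:
    """Write a synthetic two-camera cohort under ``out_dir``.

    Produces ``calibration.csv``, ``tree.nwk``, ``meta.csv``,
    ``tracks/<trial>_cam{1,2}.csv`` (markerless-tracking dialect) and
    ``truth/<trial>.json`` sidecars.
    """
    from .cohort import _BASE  # species parameter table

    config = config or PipelineConfig()
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    species = species or list(_BASE)
    rng = np.random.default_rng(seed)

    calib, cams = make_cameras_and_calibration(seed=seed)
    write_calibration_csv(calib, out / "calibration.csv")
    (out / "tree.nwk").write_text(COHORT_NEWICK + "\n")

    meta_rows = []
    for sp in species:
        for ind in range(1, n_individuals + 1):
            for trial in range(1, n_trials + 1):
                trial_id = f"{sp}_{ind:02d}_t{trial}"
                params = video_trial_params(sp, rng=rng)
                strike = make_strike(params, config)
                t1, t2 = project_strike(strike, cams, noise_sd_pixels,
                                        seed=int(rng.integers(0, 2**31 - 1)))
                write_tracking_csv(t1, out / "tracks" / f"{trial_id}_cam1.csv")
                write_tracking_csv(t2, out / "tracks" / f"{trial_id}_cam2.csv")
                write_truth_json(strike, out / "truth" / f"{trial_id}.json")
                meta_rows.append({
                    "trial_id": trial_id, "species": sp,
                    "individual": f"{sp}_{ind:02d}", "trial": trial,
                    "camouflage": _species_camouflage(sp),
                })
    pd.DataFrame(meta_rows).to_csv(out / "meta.csv", index=False)
    return out


def _species_camouflage(sp: str) -> str:
    from .reference import SPECIES_MEANS

    return SPECIES_MEANS[sp.replace("_", " ")]["camouflage"]


def run_pipeline(
    config: PipelineConfig,
    input_dir: str | Path,
    out_dir: str | Path | None = None,
) -> Path:
    """Run the full analysis on a simulated or digitized cohort directory.

    Any stage failure aborts with the stage name and the offending trial ids.
    Returns the results directory.
    """
    inp = Path(input_dir)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "trajectories").mkdir(exist_ok=True)

    # --- calibrate
    try:
        calib = read_calibration_csv(inp / "calibration.csv")
        cams = [calibrate_dlt(calib, c) for c in range(len(calib.observations))]
    except (StrikekinError, ValueError, OSError) as exc:
        raise PipelineError("calibrate", str(exc)) from exc

    meta = pd.read_csv(inp / "meta.csv")
    tree = read_newick(inp / "tree.nwk")

    # --- reconstruct + extract
    records = []
    for _, row in meta.iterrows():
        trial_id = row["trial_id"]
        try:
            t1 = read_tracking_csv(inp / "tracks" / f"{trial_id}_cam1.csv",
                                   confidence_cutoff=config.confidence_cutoff,
                                   frame_rate=config.frame_rate)
            t2 = read_tracking_csv(inp / "tracks" / f"{trial_id}_cam2.csv",
                                   confidence_cutoff=config.confidence_cutoff,
                                   frame_rate=config.frame_rate)
            traj = reconstruct_3d(t1, t2, cams[0], cams[1])
        except (StrikekinError, ValueError, OSError) as exc:
            raise PipelineError("reconstruct", str(exc), [trial_id]) from exc
        write_trajectory_csv(traj, out / "trajectories" / f"{trial_id}.csv")
        try:
            rec = extract_kinematic_record(traj, metadata=dict(row), config=config)
        except StrikekinError as exc:
            raise PipelineError("extract", str(exc), [trial_id]) from exc
        records.append(rec)

    table = records_to_table(records)
    write_kinematics_csv(table, out / "kinematics.csv")

    results = analyze_strike_table(table, tree, config, out)

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "n_trials": len(records),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return out


def analyze_strike_table(
    table: pd.DataFrame,
    tree,
    config: PipelineConfig,
    out: Path | None = None,
) -> dict:
    """Statistical back end on a one-row-per-trial kinematics table.

    Selects the fastest strikes, runs both PCAs with broken-stick counts,
    fits the phylogenetic mixed models for each significant kinematic axis
    (camouflage-only and camouflage+morphology variants), compares them by
    AICc, computes camouflage contrasts and classifies hunting styles.
    """
    kin_cols = list(TABLE1_LABELS.values())
    selected = select_fastest(table)
    inds = individual_means(selected)

    kin_pca = pca_correlation(selected, kin_cols)
    kin_bs = broken_stick(kin_pca.proportion_variance.to_numpy())
    morph_pca = pca_correlation(inds, _MORPH_COLS)
    morph_bs = broken_stick(morph_pca.proportion_variance.to_numpy())

    # scores for the individual-mean table (same standardization rules)
    ind_kin_pca = pca_correlation(inds, kin_cols)
    for j in range(max(kin_bs.n_significant, 1)):
        inds[f"kPC{j + 1}"] = ind_kin_pca.scores[f"PC{j + 1}"]
    for j in range(max(morph_bs.n_significant, 1)):
        inds[f"mPC{j + 1}"] = morph_pca.scores[f"PC{j + 1}"]

    morph_pcs = [f"mPC{j + 1}" for j in range(max(morph_bs.n_significant, 1))]
    inds = add_within_species_centering(inds, morph_pcs)

    n_levels = inds["camouflage"].nunique() if "camouflage" in inds else 0
    models: dict[str, dict] = {}
    for j in range(max(kin_bs.n_significant, 1)):
        resp = f"kPC{j + 1}"
        fixed_cam = ["camouflage"] if n_levels >= 2 else []
        fixed_full = fixed_cam + [c for pc in morph_pcs
                                  for c in (f"{pc}_species_mean", f"{pc}_within")]
        entry: dict = {}
        try:
            fit_cam = fit_pglmm(inds, resp, fixed_cam, tree)
            fit_full = fit_pglmm(inds, resp, fixed_full, tree)
            entry["aicc"] = aicc_compare(
                {"camouflage_only": fit_cam, "camouflage_morphology": fit_full})
            entry["fits"] = {"camouflage_only": fit_cam,
                             "camouflage_morphology": fit_full}
            if n_levels >= 2:
                entry["contrasts"] = pairwise_contrasts(fit_cam, "camouflage")
        except (StrikekinError, ValueError) as exc:
            entry["error"] = str(exc)
        models[resp] = entry

    species_angles = inds.groupby("species")["Coxa start angle"].mean()
    styles = pd.DataFrame({
        "species": species_angles.index,
        "coxa_start_angle": species_angles.to_numpy(),
        "hunting_style": classify_hunting_style(
            species_angles.to_numpy(), config.hunting_style_cut_deg),
    })

    results = {
        "selected": selected,
        "individual_means": inds,
        "kinematic_pca": kin_pca,
        "kinematic_broken_stick": kin_bs,
        "morphology_pca": morph_pca,
        "morphology_broken_stick": morph_bs,
        "models": models,
        "hunting_styles": styles,
    }

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        selected.to_csv(out / "selected_strikes.csv", index=False)
        inds.to_csv(out / "individual_means.csv", index=False)
        kin_pca.loadings.to_csv(out / "kinematic_pca_loadings.csv")
        morph_pca.loadings.to_csv(out / "morphology_pca_loadings.csv")
        styles.to_csv(out / "hunting_styles.csv", index=False)
        summary = {
            "kinematic_pc_proportions": kin_pca.proportion_variance.round(6).to_dict(),
            "n_significant_kinematic_pcs": kin_bs.n_significant,
            "morphology_pc_proportions": morph_pca.proportion_variance.round(6).to_dict(),
            "n_significant_morphology_pcs": morph_bs.n_significant,
            "models": {
                resp: {
                    name: {
                        "lambda": fit.lambda_, "AICc": fit.aicc,
                        "sigma2_phylo": fit.sigma2_phylo,
                        "sigma2_species": fit.sigma2_species,
                        "sigma2_resid": fit.sigma2_resid,
                        "beta": fit.beta.to_dict(),
                        "pvalues": fit.pvalues.to_dict(),
                    }
                    for name, fit in entry.get("fits", {}).items()
                }
                for resp, entry in models.items()
            },
        }
        (out / "model_summary.json").write_text(json.dumps(summary, indent=2))
        for resp, entry in models.items():
            if "contrasts" in entry:
                entry["contrasts"].to_csv(
                    out / f"contrasts_{resp}.csv", index=False)
    return results
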