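"""Synthetic study cohort: ten species, four camouflage strategies, 48
individuals, five attempts each.

The cohort emulates the comparative study's design at the kinematic-table
level: per-species mean values are taken from the published species means
where printed (see :mod:`strikekin.reference`) and filled with realistic
values elsewhere; individuals and trials add lognormal-style multiplicative
variation (additive for angles).  The companion phylogeny groups species by
family on an ultrametric unit-height tree.

This table-level generator drives the statistical back end quickly; the
video-level pipeline (strike generation, projection, reconstruction,
extraction) is exercised separately on smaller cohorts.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from .kinematics import TABLE1_LABELS
from .reference import SPECIES_MEANS

__all__ = ["cohort_tree", "simulate_study_cohort", "video_trial_params",
           "COHORT_NEWICK"]

COHORT_NEWICK = (
    "(((Tenodera_sinensis:0.35,Stagmomantis_limbata:0.35):0.45,"
    "(Chopardiella_pouliani:0.55,Pseudovates_chlorophaea:0.55):0.25):0.2,"
    "((Deroplatys_truncata:0.6,Euchomenella_heteroptera:0.6):0.3,"
    "((Hymenopus_coronatus:0.4,Pseudocreobotra_wahlbergi:0.4):0.3,"
    "(Theopropus_elegans:0.5,Phyllocrania_paradoxa:0.5):0.2):0.2):0.1);"
)

# per-species means of the 16 kinematic variables and 4 segment lengths;
# values printed in the study are used verbatim, the rest are realistic
# fill-ins consistent with the family-level patterns it describes
_BASE = {
    #                 cLV  fLV  cAV  fAV   tAV   tLV  cSA   appr  ppA ppD  bV   bD   swp   cfLD ftLD tLD  cox  fem  tib  met
    "Hymenopus_coronatus":      (75, 260, 2600, 9258.7, 14140.0, 310, 87.02, 0.011, 35, 2.4, 38, 0.38, 0.014, 1.1, 2.1, 2.9, 0.90, 1.35, 0.62, 0.852),
    "Pseudocreobotra_wahlbergi": (72, 240, 2400, 8200, 12500, 280, 61.18, 0.013, 30, 2.2, 36, 0.45, 0.015, 1.0, 2.0, 2.7, 0.85, 1.28, 0.58, 0.795),
    "Theopropus_elegans":       (84.2, 220, 2500, 7000, 11000, 250, 30.6, 0.018, 18, 2.8, 63.3, 0.70, 0.016, 0.9, 1.8, 2.4, 0.88, 1.30, 0.60, 0.961),
    "Phyllocrania_paradoxa":    (70, 210, 2100, 6500, 10500, 240, 32.0, 0.026, 20, 2.6, 40, 0.65, 0.018, 1.0, 1.9, 2.6, 1.05, 1.55, 0.70, 1.60),
    "Tenodera_sinensis":        (90, 180, 1900, 4045.3, 7650.5, 200, 25.0, 0.022, 15, 4.2, 55, 1.33, 0.024, 1.4, 2.8, 3.8, 1.808, 2.52, 1.05, 2.90),
    "Stagmomantis_limbata":     (85, 175, 2000, 4500, 8200, 205, 29.0, 0.021, 16, 3.8, 50, 1.10, 0.023, 1.3, 2.6, 3.5, 1.50, 2.10, 0.90, 2.40),
    "Chopardiella_pouliani":    (80, 170, 2100, 4800, 8500, 210, 27.5, 0.020, 17, 3.6, 48, 1.00, 0.022, 1.2, 2.4, 3.2, 1.30, 1.85, 0.80, 2.10),
    "Pseudovates_chlorophaea":  (78, 200, 2300, 6000, 10000, 235, 47.6, 0.019, 26, 3.0, 42, 0.80, 0.020, 1.3, 2.5, 3.4, 1.45, 2.00, 0.78, 3.172),
    "Deroplatys_truncata":      (69.3, 185, 1700, 5500, 9500, 215, 30.5, 0.031, 14, 2.9, 32.4, 0.90, 0.021, 1.2, 2.3, 3.1, 1.35, 1.95, 0.82, 2.30),
    "Euchomenella_heteroptera": (116.7, 195, 2200, 5000, 9000, 220, 33.0, 0.016, 13, 4.5, 52.3, 1.05, 0.022, 1.4, 2.7, 3.6, 1.91, 2.67, 0.744, 4.369),
}

_KIN_COLS = list(TABLE1_LABELS.values())
_MORPH_COLS = ["coxa_length", "femur_length", "tibia_length", "metazona_length"]
_ANGLE_COLS = {"Coxa start angle", "PP angle"}

#: individuals per species (sums to 48, three to five females each)
_N_INDIVIDUALS = {
    "Hymenopus_coronatus": 5, "Pseudocreobotra_wahlbergi": 5,
    "Theopropus_elegans": 5, "Phyllocrania_paradoxa": 5,
    "Tenodera_sinensis": 5, "Stagmomantis_limbata": 4,
    "Chopardiella_pouliani": 4, "Pseudovates_chlorophaea": 5,
    "Deroplatys_truncata": 5, "Euchomenella_heteroptera": 5,
}


def cohort_tree() -> dendropy.Tree:
    """The cohort's ultrametric, unit-height companion phylogeny."""
    return dendropy.Tree.get(data=COHORT_NEWICK, schema="newick",
                             preserve_underscores=True)


def _species_info(name: str) -> dict:
    key = name.replace("_", " ")
    return SPECIES_MEANS[key]


def simulate_study_cohort(
    seed: int = 0,
    n_attempts: int = 5,
    individual_cv: float = 0.06,
    trial_cv: float = 0.09,
    angle_sd_individual: float = 3.0,
    angle_sd_trial: float = 4.0,
) -> pd.DataFrame:
    """Simulate the full study's strike table.

    Returns one row per prey-capture attempt with the 16 kinematic variables
    (table-labelled columns), the four morphology lengths, and metadata
    (species, individual, trial, camouflage, family).  One attempt is dropped
    from the last individual, matching the study's 239 total attempts when
    ``n_attempts=5``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    species_names = list(_BASE)
    for sp in species_names:
        info = _species_info(sp)
        base = dict(zip(_KIN_COLS + _MORPH_COLS, _BASE[sp]))
        for ind in range(1, _N_INDIVIDUALS[sp] + 1):
            ind_id = f"{sp}_{ind:02d}"
            ind_mult = {c: 1.0 + rng.normal(0.0, individual_cv) for c in _KIN_COLS}
            ind_angle = {c: rng.normal(0.0, angle_sd_individual) for c in _ANGLE_COLS}
            morph_mult = 1.0 + rng.normal(0.0, 0.03)
            for trial in range(1, n_attempts + 1):
                row = {
                    "species": sp,
                    "individual": ind_id,
                    "trial": trial,
                    "camouflage": info["camouflage"],
                    "family": info["family"],
                }
                for c in _KIN_COLS:
                    if c in _ANGLE_COLS:
                        v = base[c] + ind_angle[c] + rng.normal(0.0, angle_sd_trial)
                        v = float(np.clip(v, 1.0, 175.0))
                    else:
                        v = base[c] * ind_mult[c] * (1.0 + rng.normal(0.0, trial_cv))
                        v = max(v, 1e-6)
                    row[c] = v
                for c in _MORPH_COLS:
                    row[c] = base[c] * morph_mult * (1.0 + rng.normal(0.0, 0.01))
                rows.append(row)
    df = pd.DataFrame(rows)
    # the study collected 239 attempts rather than a full 240
    df = df.iloc[:-1].reset_index(drop=True) if n_attempts == 5 else df
    return df


def video_trial_params(species: str, rng: np.ndarray | None = None, seed: int = 0):
    """Strike parameters for one video-level trial of ``species``.

    Species means drive the angular-velocity targets, coxa start angle,
    approach time, lunge and segment lengths; the trial adds individual-style
    multiplicative variation.  Used by the simulation CLI and the end-to-end
    pipeline tests.
    """
    from .core import SegmentLengths
    from .synth import strike_params_for_velocities

    if rng is None:
        rng = np.random.default_rng(seed)
    base = dict(zip(_KIN_COLS + _MORPH_COLS, _BASE[species]))
    jitter = lambda v, cv=0.08: float(v * (1.0 + rng.normal(0.0, cv)))
    coxa_sa = float(np.clip(base["Coxa start angle"] + rng.normal(0.0, 4.0),
                            5.0, 130.0))
    lengths = SegmentLengths(
        coxa=jitter(base["coxa_length"], 0.02),
        femur=jitter(base["femur_length"], 0.02),
        tibia=jitter(base["tibia_length"], 0.02),
        metazona=jitter(base["metazona_length"], 0.02),
    )
    params = strike_params_for_velocities(
        femur_av=jitter(base["Femur AV"]),
        tibia_av=jitter(base["Tibia AV"]),
        coxa_start_angle=coxa_sa,
        approach_duration=max(0.011, jitter(base["Approach time"])),
        body_lunge=max(0.05, jitter(base["Body disp."])),
        lateral_spread_peak=jitter(base["Tibia LD"], 0.05),
        segment_lengths=lengths,
        prey_distance=jitter(base["PP dist."], 0.05),
        prey_angle_deg=float(np.clip(base["PP angle"] + rng.normal(0.0, 3.0),
                                     2.0, 85.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    # clamp the tip-separation target into the reachable range: with
    # partially folded femora only a fraction of the chain length is usable
    from .synth import lateral_spread_bounds

    lo, hi = lateral_spread_bounds(params)
    params.lateral_spread_peak = float(
        np.clip(params.lateral_spread_peak, 1.05 * lo, 0.9 * hi))
    return params
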