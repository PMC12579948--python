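"""Published summary values for the ten-species strike study.

These are the printed species-level means and PCA variance proportions from
the original comparative study of raptorial strike kinematics across ten
mantis species and four camouflage strategies.  They serve two roles:

* desk-check inputs (percent differences between species means; broken-stick
  counts on the printed variance proportions);
* parameter values for the synthetic study cohort, so the pipeline can be
  exercised under the study's own conditions without the raw trial videos.
"""

from __future__ import annotations

import numpy as np

#: Proportion of variance of the 16 kinematic PCs (144 selected attempts).
KINEMATIC_PCA_PROPORTIONS = np.array([
    0.2591, 0.1618, 0.1504, 0.0952, 0.0779, 0.0617, 0.0477, 0.0335,
    0.0251, 0.0226, 0.0172, 0.0144, 0.0118, 0.0091, 0.0067, 0.0058,
])

#: Proportion of variance of the 4 morphology PCs (PC1, PC2 printed; the
#: remainder is split over PC3/PC4, which does not affect the broken-stick
#: count because PC3 falls below its null expectation either way).
MORPHOLOGY_PCA_PROPORTIONS = np.array([0.6800, 0.2872, 0.0220, 0.0108])

#: Printed species means used in worked examples and as generator parameters.
SPECIES_MEANS = {
    "Hymenopus coronatus": {
        "camouflage": "flower", "family": "Hymenopodidae",
        "Femur AV": 9258.7, "Tibia AV": 14140.0,
        "Coxa start angle": 87.02, "Body disp.": 0.38,
        "Approach time": 0.011, "metazona_length": 0.852,
    },
    "Pseudocreobotra wahlbergi": {
        "camouflage": "flower", "family": "Hymenopodidae",
        "Coxa start angle": 61.18, "metazona_length": 0.795,
    },
    "Theopropus elegans": {
        "camouflage": "flower", "family": "Hymenopodidae",
        "Coxa start angle": 30.6, "metazona_length": 0.961,
        "Coxa LV": 84.2, "Body vel.": 63.3,
    },
    "Tenodera sinensis": {
        "camouflage": "generalist", "family": "Mantidae",
        "Femur AV": 4045.3, "Tibia AV": 7650.5,
        "Coxa start angle": 25.0, "Body disp.": 1.33,
        "coxa_length": 1.808, "femur_length": 2.52, "tibia_length": 1.05,
    },
    "Stagmomantis limbata": {
        "camouflage": "generalist", "family": "Mantidae",
        "Coxa start angle": 29.0,
    },
    "Chopardiella pouliani": {
        "camouflage": "generalist", "family": "Mantidae",
        "Coxa start angle": 27.5,
    },
    "Deroplatys truncata": {
        "camouflage": "dead leaf", "family": "Deroplatyidae",
        "Coxa start angle": 30.5, "Approach time": 0.031,
        "Coxa LV": 69.3, "Body vel.": 32.4,
    },
    "Phyllocrania paradoxa": {
        "camouflage": "dead leaf", "family": "Hymenopodidae",
        "Coxa start angle": 32.0,
    },
    "Euchomenella heteroptera": {
        "camouflage": "stick", "family": "Deroplatyidae",
        "Coxa start angle": 33.0, "Approach time": 0.016,
        "Coxa LV": 116.7, "Body vel.": 52.3,
        "metazona_length": 4.369, "coxa_length": 1.91,
        "femur_length": 2.67, "tibia_length": 0.744,
    },
    "Pseudovates chlorophaea": {
        "camouflage": "stick", "family": "Mantidae",
        "Coxa start angle": 47.6, "metazona_length": 3.172,
    },
}

#: Mean coxa start angle of the basigrade group (generalists, dead-leaf
#: mimics and T. elegans).
BASIGRADE_MEAN_COXA_START = 29.1


def percent_increase(new: float, old: float) -> float:
    """Percent increase of ``new`` over ``old``."""
    return (new - old) / old * 100.0
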