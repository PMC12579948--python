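"""Phylogenetic covariance construction from a tree with branch lengths.

Under Brownian motion on a tree, the covariance between two tips equals the
shared root-to-tip path length (the depth of their most recent common
ancestor).  The matrix is scaled so its maximum diagonal is 1, making
variance components comparable across trees.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from .exceptions import MissingTipError

__all__ = ["build_phylo_covariance"]


def build_phylo_covariance(
    tree: dendropy.Tree,
    species_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Shared-branch-length covariance matrix among tips, max diagonal 1.

    ``species_labels`` selects and orders the rows/columns; every label must
    match a tip, otherwise :class:`MissingTipError` lists the offenders.
    """
    tree.calc_node_root_distances()
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if species_labels is None:
        species_labels = list(tips)
    missing = [s for s in species_labels if s not in tips]
    if missing:
        raise MissingTipError(f"species not on the tree: {missing}")

    pdm = tree.phylogenetic_distance_matrix()
    n = len(species_labels)
    cov = np.empty((n, n))
    depth = {s: tips[s].root_distance for s in species_labels}
    for i, si in enumerate(species_labels):
        cov[i, i] = depth[si]
        for j in range(i + 1, n):
            sj = species_labels[j]
            d = pdm.patristic_distance(tips[si].taxon, tips[sj].taxon)
            cov[i, j] = cov[j, i] = 0.5 * (depth[si] + depth[sj] - d)
    scale = float(np.max(np.diag(cov)))
    if scale <= 0:
        raise ValueError("tree has zero height; covariance undefined")
    return pd.DataFrame(cov / scale, index=species_labels, columns=species_labels)
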