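"""Jaccard similarity between latitudinal bands, UPGMA dendrogram and
SIMPROF tests of internal structure.

Bands are compared by the Jaccard index of their species sets and
clustered by average linkage (UPGMA) on the complementary dissimilarity.
SIMPROF (similarity profile permutation test) then decides, top-down
from the root, which dendrogram nodes contain significant internal
structure: the observed sorted profile of pairwise similarities is
compared with profiles obtained by permuting each species' presences
independently across the bands under the node.  Descent stops at
homogeneous nodes, whose leaves form the reported biogeographic groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import IncidenceMatrix

__all__ = [
    "Dendrogram",
    "jaccard_similarity",
    "upgma",
    "simprof",
    "simprof_tree",
    "significant_groups",
]


def jaccard_similarity(
    m: IncidenceMatrix, drop_empty: bool = True
) -> pd.DataFrame:
    """Band-by-band Jaccard similarity J = |A n B| / |A u B|.

    Empty bands (no species) are excluded by default since J is
    undefined between two empty sets; the dropped labels are recorded in
    ``df.attrs['dropped_bands']``.
    """
    values = m.values
    labels = np.asarray(m.col_labels)
    occupied = values.sum(axis=0) > 0
    dropped = [x.item() if hasattr(x, "item") else x for x in labels[~occupied]]
    if drop_empty:
        values = values[:, occupied]
        labels = labels[occupied]
    B = values.astype(float)
    inter = B.T @ B
    sizes = B.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    df = pd.DataFrame(sim, index=labels, columns=labels)
    df.attrs["dropped_bands"] = dropped
    return df


@dataclass
class Dendrogram:
    """UPGMA merge tree over band labels.

    ``linkage`` is a scipy linkage matrix on dissimilarity 1 - J;
    ``node_p`` and ``node_significant`` are filled by
    :func:`simprof_tree` for internal nodes (keyed by scipy node id).
    """

    linkage: np.ndarray
    labels: list
    node_p: dict[int, float] = field(default_factory=dict)
    node_significant: dict[int, bool] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        """Merge heights (cophenetic dissimilarities), leaf-to-root order."""
        return self.linkage[:, 2].copy()

    def cophenetic(self) -> pd.DataFrame:
        d = hierarchy.cophenet(self.linkage)
        return pd.DataFrame(
            squareform(d), index=self.labels, columns=self.labels
        )

    def leaves_under(self, node_id: int) -> list:
        tree = hierarchy.to_tree(self.linkage)
        node = _find_node(tree, node_id)
        return [self.labels[i] for i in node.pre_order(lambda x: x.id)]

    def to_newick(self) -> str:
        """Newick string; branch lengths span the merge-height gaps so
        leaf-to-root distances equal the cophenetic height."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            length = parent_height - node.dist
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist).rstrip(":0.") + ";"


def _find_node(tree, node_id: int):
    if tree.id == node_id:
        return tree
    if tree.is_leaf():
        return None
    return _find_node(tree.left, node_id) or _find_node(tree.right, node_id)


def upgma(similarity: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram on dissimilarity d = 1 - J."""
    if similarity.shape[0] < 2:
        raise ValueError("need at least 2 bands to cluster")
    sim = similarity.to_numpy(dtype=float)
    if not np.allclose(sim, sim.T):
        raise ValueError("similarity matrix must be symmetric")
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=list(similarity.index))


# ---------------------------------------------------------------------------
# SIMPROF
# ---------------------------------------------------------------------------


def _profile(B: np.ndarray) -> np.ndarray:
    """Sorted pairwise Jaccard similarities between columns of B."""
    inter = B.T @ B
    sizes = B.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    iu = np.triu_indices(B.shape[1], k=1)
    return np.sort(sim[iu])


def _permute_rows(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    order = rng.random(B.shape).argsort(axis=1)
    return np.take_along_axis(B, order, axis=1)


def simprof(
    values: np.ndarray,
    n_perm_mean: int = 666,
    n_perm_test: int = 333,
    seed: int = 0,
) -> tuple[float, float]:
    """Similarity-profile test on a species x bands submatrix.

    pi = sum of rank-wise absolute deviations of the observed sorted
    similarity profile from the mean profile of ``n_perm_mean``
    permutations (each species' presences shuffled independently across
    bands).  The p-value compares pi against ``n_perm_test`` further
    permuted profiles scored the same way, with the add-one correction.
    """
    B = np.asarray(values, dtype=float)
    if B.shape[1] < 3:
        raise ValueError("SIMPROF needs at least 3 bands")
    rng = np.random.default_rng(seed)
    obs = _profile(B)
    mean_prof = np.zeros_like(obs)
    for _ in range(n_perm_mean):
        mean_prof += _profile(_permute_rows(B, rng))
    mean_prof /= n_perm_mean
    pi_obs = float(np.abs(obs - mean_prof).sum())
    pi_null = np.empty(n_perm_test)
    for k in range(n_perm_test):
        pi_null[k] = np.abs(_profile(_permute_rows(B, rng)) - mean_prof).sum()
    p = (1.0 + int((pi_null >= pi_obs - 1e-12).sum())) / (1.0 + n_perm_test)
    return pi_obs, float(p)


def simprof_tree(
    m: IncidenceMatrix,
    dend: Dendrogram | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> Dendrogram:
    """Recursive top-down SIMPROF over a UPGMA dendrogram.

    The root is tested first; descent continues into the children of
    significant (p <= alpha) nodes and stops at homogeneous ones.  Nodes
    spanning fewer than 3 bands cannot be tested and are treated as
    homogeneous.  ``n_perm`` is split 2/3 for the mean profile and 1/3
    for the test distribution.
    """
    sim = jaccard_similarity(m)
    if dend is None:
        dend = upgma(sim)
    label_to_col = {lab: i for i, lab in enumerate(m.col_labels)}
    n_mean = max(1, (2 * n_perm) // 3)
    n_test = max(1, n_perm - n_mean)
    tree = hierarchy.to_tree(dend.linkage)
    rng = np.random.default_rng(seed)

    def visit(node) -> None:
        if node.is_leaf():
            return
        leaves = [dend.labels[i] for i in node.pre_order(lambda x: x.id)]
        if len(leaves) < 3:
            dend.node_significant[node.id] = False
            return
        cols = [label_to_col[lab] for lab in leaves]
        sub = m.values[:, cols]
        sub = sub[sub.sum(axis=1) > 0]  # species absent from the node are inert
        _, p = simprof(
            sub, n_mean, n_test, seed=int(rng.integers(0, 2**31 - 1))
        )
        dend.node_p[node.id] = p
        significant = p <= alpha
        dend.node_significant[node.id] = significant
        if significant:
            visit(node.left)
            visit(node.right)

    visit(tree)
    return dend


def significant_groups(dend: Dendrogram) -> list[list]:
    """Partition of the leaves induced by cutting at the shallowest
    homogeneous (non-significant) nodes.

    Untested nodes below a homogeneous ancestor are absorbed into the
    ancestor's group; leaves hanging directly off significant nodes form
    singleton groups.
    """
    tree = hierarchy.to_tree(dend.linkage)
    groups: list[list] = []

    def visit(node) -> None:
        if node.is_leaf():
            groups.append([dend.labels[node.id]])
            return
        if dend.node_significant.get(node.id, False):
            visit(node.left)
            visit(node.right)
        else:
            groups.append(
                [dend.labels[i] for i in node.pre_order(lambda x: x.id)]
            )

    visit(tree)
    return groups
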