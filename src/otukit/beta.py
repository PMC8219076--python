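"""Beta diversity: Bray-Curtis distances, PCoA, UPGMA, and permutation tests.

ANOSIM and one-factor PERMANOVA (Adonis) are implemented directly so the
permutation scheme is seeded and the p-value uses the +1-smoothed estimator
p = (1 + #{permuted statistic >= observed}) / (n_perm + 1), whose floor at
999 permutations is 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

__all__ = [
    "bray_curtis",
    "Ordination",
    "pcoa",
    "Dendrogram",
    "upgma",
    "PermTestResult",
    "anosim",
    "adonis",
]


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns of a count table).

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1] for non-negative
    abundances.  Usually computed on rarefied counts.
    """
    totals = table.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    condensed = pdist(table.to_numpy().T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.columns))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ordination:
    """Principal-coordinates embedding of a distance matrix.

    ``coordinates`` holds one column per positive-eigenvalue axis
    (PC1, PC2, ...).  ``eigenvalues`` is the full descending spectrum,
    negative values included; ``proportion_explained`` is each positive
    eigenvalue's share of the positive-eigenvalue sum.  ``degenerate`` flags
    inputs with fewer than 3 samples (only trivial axes exist).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    degenerate: bool = False


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical metric scaling: eigendecomposition of the Gower-centred
    -0.5 * D^2 matrix.

    Axis signs are fixed deterministically by making each axis's
    largest-magnitude coordinate positive.  No correction is applied to
    negative eigenvalues; they are reported as-is.
    """
    d = dm.data
    n = d.shape[0]
    b = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
    )
    return Ordination(frame, eigvals, prop, degenerate=n < 3)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Node:
    leaves: tuple[str, ...]  # sorted; doubles as the tie-break label
    height: float
    children: tuple["_Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA tree: merge list, leaf order, Newick export, and k-cut.

    Merge heights are *half* the average between-cluster distance, so the
    tree is ultrametric with leaf-to-root path length equal to the height of
    the root.  Heights are non-decreasing along the merge sequence.
    """

    root: _Node
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]

    @property
    def leaf_order(self) -> list[str]:
        order: list[str] = []

        def walk(node: _Node) -> None:
            if node.is_leaf:
                order.append(node.leaves[0])
            else:
                for ch in node.children:
                    walk(ch)

        walk(self.root)
        return order

    def to_newick(self) -> str:
        def fmt(node: _Node, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.leaves[0]}:{blen:.10g}"
            inner = ",".join(fmt(ch, node.height) for ch in node.children)
            return f"({inner}):{blen:.10g}"

        inner = ",".join(fmt(ch, self.root.height) for ch in self.root.children)
        return f"({inner});"

    def cut(self, k: int) -> dict[str, int]:
        """Partition leaves into k clusters by undoing the k-1 highest merges."""
        if not 1 <= k <= len(self.root.leaves):
            raise ValueError(f"k={k} out of range")
        clusters = [self.root]
        while len(clusters) < k:
            i = max(
                range(len(clusters)),
                key=lambda idx: (not clusters[idx].is_leaf, clusters[idx].height),
            )
            node = clusters.pop(i)
            clusters.extend(node.children)
        out = {}
        for cid, node in enumerate(sorted(clusters, key=lambda nd: nd.leaves)):
            for leaf in node.leaves:
                out[leaf] = cid
        return out


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage agglomeration of a distance matrix.

    Cluster-pair distance is the mean over all leaf pairs; the merge height
    is half that distance.  Ties are broken by the lexicographically
    smallest (sorted-leaf-tuple) pair, which makes the tree deterministic.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    d = pd.DataFrame(dm.data, index=ids, columns=ids)
    nodes: list[_Node] = [_Node((i,), 0.0) for i in sorted(ids)]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    def avg_dist(a: _Node, b: _Node) -> float:
        sub = d.loc[list(a.leaves), list(b.leaves)].to_numpy()
        return float(sub.mean())

    while len(nodes) > 1:
        best = None
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                a, b = sorted((nodes[i], nodes[j]), key=lambda nd: nd.leaves)
                key = (avg_dist(a, b), a.leaves, b.leaves)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dist, _, _), a, b = best
        merged = _Node(
            tuple(sorted(a.leaves + b.leaves)), dist / 2.0, children=(a, b)
        )
        merges.append((a.leaves, b.leaves, dist / 2.0))
        nodes = [nd for nd in nodes if nd is not a and nd is not b] + [merged]
    return Dendrogram(nodes[0], tuple(merges))


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermTestResult:
    method: str  # "ANOSIM" or "Adonis"
    statistic: float  # R (ANOSIM) or pseudo-F (Adonis)
    p_value: float
    n_permutations: int
    r_squared: float | None = None  # Adonis only


def _check_groups(labels: Sequence[str], n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size != n:
        raise ValueError(f"{labels.size} labels for {n} samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    small = uniq[counts < 2].tolist()
    if small:
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    return labels


def _permuter(labels: np.ndarray, strata: Sequence[str] | None, rng):
    """Label permutation, optionally restricted within strata.

    With strata, labels are shuffled only among samples sharing a stratum —
    the exchangeability structure of a stratified (e.g. blocked-by-habitat)
    design; a free shuffle in such a design is conservative because the
    observed labeling is balanced by construction.
    """
    if strata is None:
        return lambda: rng.permutation(labels)
    strata = np.asarray(strata)
    if strata.size != labels.size:
        raise ValueError("strata length must match labels")
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]

    def draw():
        out = labels.copy()
        for idx in groups:
            out[idx] = labels[idx][rng.permutation(idx.size)]
        return out

    return draw


def anosim(
    dm: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    strata: Sequence[str] | None = None,
) -> PermTestResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with midranks for tied distances; R is 1 when every between-group
    distance exceeds every within-group distance and 0 when ranks carry no
    group signal.  One-sided permutation p with +1 smoothing; ``strata``
    restricts permutations within blocks (e.g. habitat, when testing the
    breeding mode in a habitat-balanced design).
    """
    n = dm.shape[0]
    labels = _check_groups(labels, n)
    iu = np.triu_indices(n, 1)
    ranks = rankdata(squareform(dm.data, checks=False))
    denom = n * (n - 1) / 4.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(labels)
    draw = _permuter(labels, strata, np.random.default_rng(seed))
    hits = sum(r_stat(draw()) >= r_obs for _ in range(n_perm))
    p = (1 + hits) / (n_perm + 1)
    return PermTestResult("ANOSIM", r_obs, p, n_perm)


def adonis(
    dm: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    strata: Sequence[str] | None = None,
) -> PermTestResult:
    """One-factor PERMANOVA (Adonis) on a distance matrix.

    SS_total = sum of squared distances / n; SS_within sums each group's
    squared within-group distances / group size; pseudo-F =
    (SS_between/(g-1)) / (SS_within/(n-g)); R^2 = SS_between/SS_total.
    SS_within = 0 yields F = +inf.  Permutation p (and ``strata``) as in
    :func:`anosim`.
    """
    n = dm.shape[0]
    labels = _check_groups(labels, n)
    d2 = dm.data**2
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    g = np.unique(labels).size

    def f_stat(lab: np.ndarray) -> tuple[float, float]:
        ss_within = 0.0
        for grp in np.unique(lab):
            idx = np.flatnonzero(lab == grp)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        ss_between = ss_total - ss_within
        if ss_within == 0.0:
            return np.inf, ss_between
        f = (ss_between / (g - 1)) / (ss_within / (n - g))
        return float(f), ss_between

    f_obs, ss_between = f_stat(labels)
    r2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    draw = _permuter(labels, strata, np.random.default_rng(seed))
    hits = sum(f_stat(draw())[0] >= f_obs for _ in range(n_perm))
    p = (1 + hits) / (n_perm + 1)
    return PermTestResult("Adonis", f_obs, p, n_perm, r_squared=r2)
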