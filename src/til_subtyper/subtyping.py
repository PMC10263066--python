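"""Immune subtype discovery: Ward.D2 clustering on Spearman distance.

Samples are compared by Spearman correlation distance (1 - rho) over their
combined density + %CD45 feature vectors and agglomerated with the Ward.D2
criterion: the Lance-Williams recurrence with Ward coefficients applied to
*squared* input dissimilarities, with merge heights reported on the unsquared
scale.  The agglomerator is implemented natively so merge order and
tie-breaking (lowest leaf index) are fully specified and testable against a
brute-force oracle.

Cutting the tumor tree at k = 3 and applying a composition decision rule
yields the Cold / Myeloid / CD8 subtype labels: the cluster with the lowest
mean total CD45+ cell density is Cold (scant infiltration); of the remaining
two, the one with the higher mean myeloid-lineage %CD45 (macrophage + mMDSC
+ CD14+ monocyte) is Myeloid and the other is CD8, with ties broken toward
CD8 by higher T-cell %CD45.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import cell_density
from .gating import GatingTree, default_gating_tree

__all__ = [
    "Dendrogram",
    "spearman_distance",
    "ward_d2_linkage",
    "cut_clusters",
    "label_subtypes",
    "adjusted_rand_index",
    "to_newick",
    "merge_table",
]


# ---------------------------------------------------------------------------
# Spearman correlation distance


def spearman_distance(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Spearman rho between sample feature vectors.

    Ranks use the average-rank convention for ties; missing values are
    handled pairwise-complete.  A sample pair sharing < 3 non-missing
    features, or a sample with < 3 non-missing features overall, is an error.
    """
    if features.shape[0] < 2 or features.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 features")
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    n_ok = (~np.isnan(X)).sum(axis=1)
    bad = features.index[n_ok < 3]
    if len(bad):
        raise ValueError(
            f"samples with < 3 non-missing features: {list(bad)}"
        )
    if not np.isnan(X).any():
        ranks = np.apply_along_axis(rankdata, 1, X)
        rho = np.corrcoef(ranks)
    else:
        rho = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(X[i]) & ~np.isnan(X[j])
                if ok.sum() < 3:
                    raise ValueError(
                        f"samples {features.index[i]!r} and {features.index[j]!r} "
                        f"share only {int(ok.sum())} non-missing features"
                    )
                ri, rj = rankdata(X[i, ok]), rankdata(X[j, ok])
                rho[i, j] = rho[j, i] = np.corrcoef(ri, rj)[0, 1]
    if np.isnan(rho).any():
        warnings.warn(
            "undefined Spearman correlation (constant rank vector); "
            "treating as rho = 0",
            stacklevel=2,
        )
        rho = np.nan_to_num(rho, nan=0.0)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=features.index, columns=features.index)


# ---------------------------------------------------------------------------
# Ward.D2 agglomeration


@dataclass
class Dendrogram:
    """Merge list in scipy convention: leaves 0..n-1, merge t creates n+t."""

    merges: np.ndarray  # (n-1, 4): left id, right id, height, size
    n_leaves: int
    labels: list  # leaf sample ids

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[int]:
        """Depth-first leaf ordering of the tree (left subtree first)."""
        if self.n_leaves == 1:
            return [0]

        order: list[int] = []
        stack = [int(self.n_leaves + len(self.merges) - 1)]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right = self.merges[node - self.n_leaves, :2]
                stack.append(int(right))
                stack.append(int(left))
        return order


def _check_distance(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")


def ward_d2_linkage(dist: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Agglomerate with the Ward.D2 criterion.

    The Lance-Williams recurrence with Ward coefficients is applied to the
    squared input dissimilarities; reported merge heights are square roots of
    the merged squared dissimilarity (the ward.D2 convention).  Ties are
    broken deterministically toward the pair containing the lowest leaf
    index.
    """
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    d = np.asarray(dist, dtype=float)
    _check_distance(d)
    n = d.shape[0]
    if labels is None:
        labels = list(range(n))
    if n == 1:
        return Dendrogram(np.empty((0, 4)), 1, labels)

    D2 = d.astype(float) ** 2
    np.fill_diagonal(D2, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    reps = np.arange(n)  # lowest member leaf per cluster, for tie-breaking
    cluster_id = np.arange(n)
    merges = np.empty((n - 1, 4))
    work = D2.copy()

    for t in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], work, np.inf)
        mval = masked.min()
        ii, jj = np.nonzero(masked == mval)
        pairs = [(i, j) for i, j in zip(ii, jj) if i < j]
        i, j = min(
            pairs, key=lambda p: (min(reps[p[0]], reps[p[1]]),
                                  max(reps[p[0]], reps[p[1]]))
        )
        left, right = cluster_id[i], cluster_id[j]
        if reps[j] < reps[i]:
            left, right = right, left
        merges[t] = (left, right, np.sqrt(mval), sizes[i] + sizes[j])

        ni, nj = sizes[i], sizes[j]
        others = active.copy()
        others[[i, j]] = False
        nk = sizes[others]
        new = (
            (ni + nk) * work[i, others]
            + (nj + nk) * work[j, others]
            - nk * mval
        ) / (ni + nj + nk)
        work[i, others] = new
        work[others, i] = new
        active[j] = False
        sizes[i] = ni + nj
        reps[i] = min(reps[i], reps[j])
        cluster_id[i] = n + t
    return Dendrogram(merges, n, labels)


def cut_clusters(dend: Dendrogram, k: int) -> pd.Series:
    """Cut the merge sequence into exactly ``k`` groups.

    Group numbers 1..k are assigned stably by dendrogram leaf order (the
    group containing the first leaf in display order is 1, and so on).
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + max(0, n - k)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        left, right, _, _ = dend.merges[t]
        new = n + t
        parent[find(int(left))] = new
        parent[find(int(right))] = new
    roots = [find(i) for i in range(n)]
    group_of: dict[int, int] = {}
    for leaf in dend.leaf_order():
        r = roots[leaf]
        if r not in group_of:
            group_of[r] = len(group_of) + 1
    codes = [group_of[r] for r in roots]
    return pd.Series(codes, index=dend.labels, name="cluster")


def to_newick(dend: Dendrogram) -> str:
    """Newick serialization of the dendrogram.

    Branch lengths are the height drop from each parent merge to its child
    (0 at the leaves' own level for singleton children).
    """
    n = dend.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for t, (_, _, h, _) in enumerate(dend.merges):
        heights[n + t] = float(h)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            return f"{dend.labels[node]}:{length:.6g}"
        left, right, h, _ = dend.merges[node - n]
        inner = f"({render(int(left), h)},{render(int(right), h)})"
        return f"{inner}:{length:.6g}"

    if n == 1:
        return f"{dend.labels[0]};"
    root = n + len(dend.merges) - 1
    left, right, h, _ = dend.merges[-1]
    return f"({render(int(left), h)},{render(int(right), h)});" if root else ""


def merge_table(dend: Dendrogram) -> pd.DataFrame:
    """Merge list as a frame (left, right, height, size), scipy ids."""
    return pd.DataFrame(
        dend.merges, columns=["left", "right", "height", "size"]
    ).astype({"left": int, "right": int, "size": int})


# ---------------------------------------------------------------------------
# subtype labeling


def label_subtypes(
    groups: pd.Series,
    counts: pd.DataFrame,
    masses: pd.Series,
    tree: GatingTree | None = None,
) -> pd.Series:
    """Map exactly three clusters to Cold / Myeloid / CD8 by composition.

    Lowest mean total CD45+ density -> Cold; of the remainder, higher mean
    myeloid-lineage %CD45 -> Myeloid, the other -> CD8 (tie broken toward
    CD8 by higher T-cell %CD45).  The mapping depends only on cluster
    contents, so renumbering the input groups leaves the labels unchanged.
    """
    tree = tree or default_gating_tree()
    groups = pd.Series(groups)
    uniq = sorted(groups.unique())
    if len(uniq) != 3:
        raise ValueError(f"expected exactly 3 groups, got {len(uniq)}")
    myeloid_tops = [p.population_id for p in tree.populations if p.myeloid]
    myeloid_core = [p for p in ("macrophage", "mmdsc", "cd14_monocyte")
                    if p in counts.columns] or myeloid_tops
    dens = pd.Series(
        [cell_density(int(counts.loc[s, "total_cd45"]), float(masses.loc[s]))
         for s in groups.index],
        index=groups.index,
    )
    total = counts.loc[groups.index, "total_cd45"].replace(0, np.nan)
    mye_pct = counts.loc[groups.index, myeloid_core].sum(axis=1) / total * 100
    t_pct = counts.loc[groups.index, ["cd4_t", "cd8_t"]].sum(axis=1) / total * 100

    mean_dens = dens.groupby(groups).mean()
    cold = mean_dens.idxmin()
    if (mean_dens == mean_dens.min()).sum() > 1:
        warnings.warn("tie on mean total density; lowest group id taken as Cold",
                      stacklevel=2)
        cold = mean_dens[mean_dens == mean_dens.min()].index.min()
    rest = [g for g in uniq if g != cold]
    mean_mye = mye_pct.groupby(groups).mean()
    mean_t = t_pct.groupby(groups).mean()
    a, b = rest
    if mean_mye[a] > mean_mye[b]:
        myeloid, cd8 = a, b
    elif mean_mye[b] > mean_mye[a]:
        myeloid, cd8 = b, a
    else:
        warnings.warn("tie on myeloid %CD45; breaking by T-cell %CD45",
                      stacklevel=2)
        cd8 = a if mean_t[a] >= mean_t[b] else b
        myeloid = b if cd8 == a else a
    mapping = {cold: "Cold", myeloid: "Myeloid", cd8: "CD8"}
    return groups.map(mapping).rename("subtype")


# ---------------------------------------------------------------------------
# partition agreement


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected Rand agreement between two labelings of one set."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(table).sum()
    sum_rows = comb2(table.sum(axis=1)).sum()
    sum_cols = comb2(table.sum(axis=0)).sum()
    expected = sum_rows * sum_cols / comb2(n)
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))
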