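"""Beta diversity: Bray-Curtis and weighted UniFrac distances, PCoA and
non-metric MDS ordination, and the ANOSIM / PERMANOVA permutation tests.

Dissimilarities are computed on per-sample relative abundances by
default, so sequencing depth differences between samples do not leak
into community comparisons; pass ``relative=False`` for raw counts.
Permutation p-values use the (count + 1)/(permutations + 1) estimator
and therefore can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode

from .io import CommunityTable, ValidationError

__all__ = [
    "bray_curtis",
    "weighted_unifrac",
    "pcoa",
    "nmds",
    "anosim",
    "permanova",
    "OrdinationResult",
    "PermutationTestResult",
]


def bray_curtis(table: CommunityTable, relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis: BC_jk = sum|x_ij - x_ik| / sum(x_ij + x_ik)."""
    t = table.relative() if relative else table
    condensed = pdist(t.counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed, checks=False), ids=t.sample_ids)


def _branch_table(tree: TreeNode, taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and branch x taxon tip-membership matrix.

    Row b of the membership matrix flags the taxa descending from the
    branch above node b (every non-root node contributes one branch).
    """
    taxon_pos = {t: i for i, t in enumerate(taxa)}
    tip_names = {tip.name for tip in tree.tips()}
    missing = sorted(set(taxa) - tip_names)
    if missing:
        raise ValidationError(f"table taxa missing from tree: {missing[:10]}")
    lengths, members = [], []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            row = np.zeros(len(taxa))
            if node.name in taxon_pos:
                row[taxon_pos[node.name]] = 1.0
        else:
            row = np.sum([below[id(c)] for c in node.children], axis=0)
        below[id(node)] = row
        if not node.is_root():
            lengths.append(node.length)
            members.append(row)
    return np.asarray(lengths, dtype=float), np.asarray(members)


def weighted_unifrac(
    table: CommunityTable, tree: TreeNode, normalized: bool = True,
) -> DistanceMatrix:
    """Pairwise weighted UniFrac over the phylogeny.

    For each branch b of length l_b, with A_b and B_b the fractions of
    each sample's total abundance descending from b, the distance is
    sum_b l_b |A_b - B_b|, divided in the normalized form by
    sum_b l_b (A_b + B_b) so values lie in [0, 1].  Because A_b and B_b
    are per-sample fractions, the result is identical for raw counts
    and relative abundances.
    """
    t = table.relative()
    lengths, members = _branch_table(tree, t.taxon_ids)
    if not (lengths > 0).any():
        raise ValidationError("tree has zero total branch length")
    # fractions of each sample descending from each branch: branches x samples
    frac = members @ t.counts.T
    n = t.n_samples
    out = np.zeros((n, n))
    for j in range(n):
        diff = np.abs(frac[:, j, None] - frac[:, j + 1:])
        num = lengths @ diff
        if normalized:
            den = lengths @ (frac[:, j, None] + frac[:, j + 1:])
            num = num / den
        out[j, j + 1:] = num
    out = out + out.T
    return DistanceMatrix(out, ids=t.sample_ids)


@dataclass(frozen=True)
class OrdinationResult:
    method: str
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray | None = None  # PCoA, raw incl. negatives
    proportion_explained: np.ndarray | None = None  # PCoA, positive axes
    stress: float | None = None  # NMDS Kruskal stress-1


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis (classical/metric MDS).

    Gower-centers -D^2/2, eigendecomposes, and returns axes ordered by
    descending eigenvalue.  Coordinates are built from positive
    eigenvalues only; negative eigenvalues (from non-Euclidean
    dissimilarities) are reported raw, with proportion explained taken
    over the positive part of the spectrum.
    """
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals.max(), 0) * 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    prop = eigvals[pos] / eigvals[pos].sum()
    return OrdinationResult(
        method="PCoA",
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def _stress1(d_obs_condensed: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 with monotone (isotonic) disparities."""
    from sklearn.isotonic import IsotonicRegression

    d_emb = pdist(coords)
    order = np.argsort(d_obs_condensed, kind="stable")
    iso = IsotonicRegression()
    disparities = np.empty_like(d_emb)
    disparities[order] = iso.fit_transform(
        np.arange(len(order)), d_emb[order]
    )
    denom = (d_emb**2).sum()
    if denom == 0:
        return 1.0
    return float(np.sqrt(((d_emb - disparities) ** 2).sum() / denom))


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    eps: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF with monotone regression.

    Runs one start initialized from the PCoA configuration (the usual
    metaMDS-style warm start) plus ``n_starts - 1`` random starts, and
    keeps the solution with the lowest Kruskal stress-1.  NMDS depends
    only on the rank order of the input dissimilarities.
    """
    from sklearn.manifold import smacof

    n = dm.shape[0]
    if k >= n:
        raise ValidationError(f"k = {k} must be < number of samples ({n})")
    if k < 1 or n_starts < 1:
        raise ValidationError("k and n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    d = dm.data
    condensed = squareform(d, checks=False)
    inits = [pcoa(dm).coordinates.to_numpy()[:, :k]]
    if inits[0].shape[1] < k:  # degenerate configurations may yield < k axes
        pad = np.zeros((n, k - inits[0].shape[1]))
        inits[0] = np.hstack([inits[0], pad])
    for _ in range(n_starts - 1):
        inits.append(rng.normal(size=(n, k)))
    best_coords, best_stress = None, np.inf
    for init in inits:
        coords, _ = smacof(
            d, metric=False, n_components=k, init=init, n_init=1,
            max_iter=max_iter, eps=eps, normalized_stress=True,
            random_state=0,
        )
        s1 = _stress1(condensed, coords)
        if s1 < best_stress:
            best_stress, best_coords = s1, coords
    axes = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        method="NMDS",
        coordinates=pd.DataFrame(best_coords, index=list(dm.ids), columns=axes),
        stress=best_stress,
    )


@dataclass(frozen=True)
class PermutationTestResult:
    method: str
    statistic: float  # ANOSIM R or PERMANOVA pseudo-F
    effect_size: float | None  # PERMANOVA R^2
    p_value: float
    n_permutations: int
    seed: int | None


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(groups == g) for g in pd.unique(groups)]


def anosim(
    dm: DistanceMatrix, groups, n_permutations: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """Analysis of similarities on ranked pairwise distances.

    R = (mean between-group rank - mean within-group rank) / (M / 2)
    with M = n(n-1)/2 total pairs; R near 1 means between-group
    distances dominate.  p is the one-sided permutation tail.
    """
    groups = np.asarray(groups)
    n = dm.shape[0]
    if len(groups) != n:
        raise ValueError("groups length must match distance matrix")
    if len(pd.unique(groups)) < 2:
        raise ValidationError("need >= 2 groups")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.data[iu])
    m = len(ranks)
    denom = m / 2.0

    def r_stat(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        if within.all() or not within.any():
            raise ValidationError("grouping yields no within- or no between-pairs")
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(groups)) >= observed:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermutationTestResult("ANOSIM", float(observed), None, p, n_permutations, seed)


def permanova(
    dm: DistanceMatrix, groups, n_permutations: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """One-way PERMANOVA partitioning squared-distance sums of squares.

    SS_total = (1/n) sum_{j<k} d_jk^2; SS_within sums the analogous
    per-group quantities; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a))
    and R^2 = SS_between / SS_total.
    """
    groups = np.asarray(groups)
    n = dm.shape[0]
    if len(groups) != n:
        raise ValueError("groups length must match distance matrix")
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise ValidationError("need >= 2 groups")
    if (sizes < 2).any():
        raise ValidationError(
            f"groups with < 2 samples: {sizes[sizes < 2].index.tolist()}"
        )
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    d2 = dm.data**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    a = len(sizes)

    def ss_within(g: np.ndarray) -> float:
        total = 0.0
        for idx in _group_indices(g):
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
        return total

    ssw = ss_within(groups)
    ssb = ss_total - ssw
    if ssw == 0 and ssb == 0:
        raise ValidationError("degenerate input: all distances zero")
    if ssw == 0:
        observed_f = np.inf
    else:
        observed_f = (ssb / (a - 1)) / (ssw / (n - a))
    r2 = ssb / ss_total
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        ssw_p = ss_within(rng.permutation(groups))
        f_p = np.inf if ssw_p == 0 else ((ss_total - ssw_p) / (a - 1)) / (ssw_p / (n - a))
        if f_p >= observed_f:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermutationTestResult(
        "PERMANOVA", float(observed_f), float(r2), p, n_permutations, seed
    )
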