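"""Null-model partitioning of community assembly into ecological
processes.

The inference follows the two-stage turnover framework widely used for
microbial communities.  Stage one asks whether phylogenetic turnover
between a pair of communities deviates from what random taxon placement
on the phylogeny would produce: the observed beta mean nearest taxon
distance (betaMNTD) is compared against a null distribution generated by
shuffling taxon identities across all tree tips, giving the
beta nearest taxon index

    betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null).

betaNTI above +2 indicates divergent (variable) selection, below -2
convergent (homogeneous) selection.  Stage two takes the remaining
pairs -- those whose phylogenetic turnover is indistinguishable from
the null -- and asks whether their taxonomic turnover deviates from a
probabilistic assembly null: null communities preserving each sample's
richness and total abundance are drawn from the metacommunity
(occupancy-weighted occurrence, abundance-weighted individual draws),
Bray-Curtis is computed per draw, and the rescaled tail probability

    RCbray = ((#null < obs) + 0.5 (#null = obs)) / n_null, mapped to [-1, 1]

flags dispersal limitation (> +0.95) or homogenizing dispersal
(< -0.95); pairs exceeding neither threshold are labelled undominated
(drift and weak/mixed processes).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .io import AlignedBundle, CommunityTable, SampleMetadata, ValidationError
from .io import tip_distance_matrix

logger = logging.getLogger("ecoassembly")

__all__ = [
    "NullModelConfig",
    "Process",
    "PairProcessRecord",
    "ProcessSummary",
    "beta_mntd",
    "beta_mntd_matrix",
    "bnti_matrix",
    "rc_bray",
    "rc_bray_matrix",
    "classify_pair",
    "classify_pairs",
    "process_fractions",
    "Metacommunity",
]


@dataclass(frozen=True)
class NullModelConfig:
    """Settings shared by the betaNTI and RCbray null models.

    n_null is the number of null replicates; bnti_threshold and
    rc_threshold are the significance cutoffs (|betaNTI| = 2 and
    |RCbray| = 0.95 by convention); abundance_weighted selects
    abundance-weighted betaMNTD (presence/absence when False).
    """

    n_null: int = 999
    seed: int | None = None
    abundance_weighted: bool = True
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValueError("thresholds must be > 0")


class Process(str, enum.Enum):
    VARIABLE_SELECTION = "variable_selection"
    HOMOGENEOUS_SELECTION = "homogeneous_selection"
    DISPERSAL_LIMITATION = "dispersal_limitation"
    HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
    UNDOMINATED = "undominated"


SELECTION_PROCESSES = (Process.VARIABLE_SELECTION, Process.HOMOGENEOUS_SELECTION)
DISPERSAL_PROCESSES = (Process.DISPERSAL_LIMITATION, Process.HOMOGENIZING_DISPERSAL)


@dataclass(frozen=True)
class PairProcessRecord:
    sample_a: str
    sample_b: str
    comparison_scope: str  # "within_group" | "between_group"
    beta_mntd_obs: float
    bnti: float
    rc_bray: float | None
    process: Process


def _rel_weights(x: np.ndarray, abundance_weighted: bool) -> np.ndarray:
    present = x > 0
    if not present.any():
        raise ValidationError("empty community")
    w = np.zeros(len(x))
    if abundance_weighted:
        w[present] = x[present] / x[present].sum()
    else:
        w[present] = 1.0 / present.sum()
    return w


def beta_mntd(
    x_a, x_b, dist: np.ndarray, abundance_weighted: bool = True
) -> float:
    """betaMNTD for one community pair.

    ``dist`` is the taxon-by-taxon patristic distance matrix in the same
    taxon order as the abundance vectors.  Each taxon present in one
    community contributes its (relative-abundance-weighted) distance to
    the nearest taxon present in the other; a taxon shared by both
    contributes zero.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    w_a = _rel_weights(x_a, abundance_weighted)
    w_b = _rel_weights(x_b, abundance_weighted)
    in_a = np.flatnonzero(x_a > 0)
    in_b = np.flatnonzero(x_b > 0)
    min_to_b = dist[np.ix_(in_a, in_b)].min(axis=1)
    min_to_a = dist[np.ix_(in_b, in_a)].min(axis=1)
    return 0.5 * float((w_a[in_a] * min_to_b).sum() + (w_b[in_b] * min_to_a).sum())


def beta_mntd_matrix(
    weights: np.ndarray, presence: np.ndarray, dist: np.ndarray
) -> np.ndarray:
    """All-pairs betaMNTD, vectorized.

    ``weights`` is samples x taxa (rows already normalized to sum 1 over
    present taxa), ``presence`` the boolean mask, ``dist`` taxa x taxa.
    For each sample s, M[:, s] holds every taxon's distance to its
    nearest taxon present in s; the pair matrix is then a weighted
    average of M via one matrix product.
    """
    n_samples, n_taxa = weights.shape
    m = np.empty((n_taxa, n_samples))
    for s in range(n_samples):
        m[:, s] = dist[:, presence[s]].min(axis=1)
    t = weights @ m  # t[a, b] = sum_i w[a, i] * m[i, b]
    return 0.5 * (t + t.T)


def bnti_matrix(
    table: CommunityTable,
    tree: TreeNode,
    cfg: NullModelConfig,
    on_degenerate: str = "error",
) -> pd.DataFrame:
    """betaNTI for every sample pair.

    The null shuffles taxon labels across all tree tips (equivalently,
    applies a random simultaneous row/column permutation to the
    patristic distance matrix) while keeping the abundance matrix fixed,
    n_null times.  A null standard deviation of zero -- a star
    phylogeny, or a pair whose communities contain exactly the same
    taxa so that shuffling cannot change any nearest-taxon distance --
    raises an error naming the offending pair when
    ``on_degenerate="error"``; with ``"zero"`` such pairs get betaNTI 0
    (observed turnover equals the null exactly, i.e. no detectable
    phylogenetic signal) so downstream classification falls through to
    the taxonomic Raup-Crick stage.
    """
    if on_degenerate not in ("error", "zero"):
        raise ValueError("on_degenerate must be 'error' or 'zero'")
    dist = tip_distance_matrix(tree, table.taxon_ids)
    counts = table.counts
    presence = counts > 0
    weights = np.zeros_like(counts)
    if cfg.abundance_weighted:
        weights = counts / counts.sum(axis=1, keepdims=True)
    else:
        weights[presence] = (1.0 / presence.sum(axis=1))[
            np.nonzero(presence)[0]
        ]
    obs = beta_mntd_matrix(weights, presence, dist)
    rng = np.random.default_rng(cfg.seed)
    n_taxa = counts.shape[1]
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(cfg.n_null):
        perm = rng.permutation(n_taxa)
        null = beta_mntd_matrix(weights, presence, dist[np.ix_(perm, perm)])
        total += null
        total_sq += null * null
    mean = total / cfg.n_null
    if cfg.n_null > 1:
        var = (total_sq - cfg.n_null * mean**2) / (cfg.n_null - 1)
        var = np.maximum(var, 0.0)
    else:
        var = np.zeros_like(mean)
    sd = np.sqrt(var)
    n = counts.shape[0]
    iu = np.triu_indices(n, k=1)
    degenerate = sd[iu] <= 1e-12
    if degenerate.any():
        if on_degenerate == "error":
            j, k = iu[0][degenerate][0], iu[1][degenerate][0]
            raise ValidationError(
                "null betaMNTD distribution is degenerate (sd = 0) for pair "
                f"({table.sample_ids[j]}, {table.sample_ids[k]}); the null "
                "cannot move the observed value (star tree, or identical "
                "taxon memberships)"
            )
        logger.info(
            "betaNTI set to 0 for %d pair(s) with degenerate null sd",
            int(degenerate.sum()),
        )
    bnti = np.zeros_like(obs)
    safe_sd = np.where(sd[iu] > 1e-12, sd[iu], 1.0)
    bnti[iu] = np.where(degenerate, 0.0, (obs[iu] - mean[iu]) / safe_sd)
    bnti = bnti + bnti.T
    ids = table.sample_ids
    return pd.DataFrame(bnti, index=ids, columns=ids)


@dataclass(frozen=True)
class Metacommunity:
    """Taxon pool for the RCbray null: occupancy and pooled abundance."""

    occupancy: np.ndarray  # fraction of samples containing each taxon
    relative_abundance: np.ndarray  # pooled counts, normalized

    @classmethod
    def from_table(cls, table: CommunityTable) -> "Metacommunity":
        counts = table.counts
        occ = (counts > 0).mean(axis=0)
        pooled = counts.sum(axis=0)
        return cls(occupancy=occ, relative_abundance=pooled / pooled.sum())


def _null_community(
    richness: int,
    depth: int,
    meta: Metacommunity,
    rng: np.random.Generator,
) -> np.ndarray:
    """One null assembly preserving richness and total abundance.

    Occurrence: sequential occupancy-weighted sampling without
    replacement, realized exactly via the Gumbel top-k equivalence.
    Abundance: each occurring taxon gets one individual, the remaining
    depth - richness individuals are multinomial with pooled relative
    abundances restricted to the occurring taxa.
    """
    pool = np.flatnonzero(meta.occupancy > 0)
    if richness > len(pool):
        raise ValidationError(
            f"sample richness {richness} exceeds metacommunity pool {len(pool)}"
        )
    keys = np.log(meta.occupancy[pool]) + rng.gumbel(size=len(pool))
    chosen = pool[np.argpartition(-keys, richness - 1)[:richness]]
    counts = np.zeros(len(meta.occupancy), dtype=np.int64)
    counts[chosen] = 1
    extra = depth - richness
    if extra > 0:
        p = meta.relative_abundance[chosen]
        counts[chosen] += rng.multinomial(extra, p / p.sum())
    return counts


def _bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom)


def rc_bray(
    x_a,
    x_b,
    meta: Metacommunity,
    cfg: NullModelConfig,
) -> float:
    """Raup-Crick (Bray-Curtis flavour) index for one pair, in [-1, 1].

    Both null communities are re-assembled each replicate; the observed
    Bray-Curtis is located within the null distribution and the tail
    probability is rescaled so 0 means "as expected", +1 "far more
    dissimilar than expected" (dispersal limitation), -1 "far more
    similar" (homogenizing dispersal).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    for x in (x_a, x_b):
        if not (x > 0).any():
            raise ValidationError("zero-abundance sample")
        if not np.allclose(x, np.round(x)):
            raise ValidationError("RCbray requires integer counts")
    obs = _bray_curtis_pair(x_a, x_b)
    rng = np.random.default_rng(cfg.seed)
    rich_a, rich_b = int((x_a > 0).sum()), int((x_b > 0).sum())
    depth_a, depth_b = int(x_a.sum()), int(x_b.sum())
    below = ties = 0
    for _ in range(cfg.n_null):
        null_a = _null_community(rich_a, depth_a, meta, rng)
        null_b = _null_community(rich_b, depth_b, meta, rng)
        bc = _bray_curtis_pair(null_a.astype(float), null_b.astype(float))
        if np.isclose(bc, obs, rtol=0, atol=1e-12):
            ties += 1
        elif bc < obs:
            below += 1
    frac = (below + 0.5 * ties) / cfg.n_null
    return float((frac - 0.5) * 2.0)


def rc_bray_matrix(
    table: CommunityTable,
    cfg: NullModelConfig,
    meta: Metacommunity | None = None,
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """RCbray for many pairs sharing one set of per-replicate nulls.

    Per replicate, one null community is assembled for every sample and
    Bray-Curtis is computed across them, so the null preserves each
    sample's richness and depth exactly as in :func:`rc_bray` while
    amortizing assembly cost across pairs.  ``pairs`` restricts the
    computation (entries elsewhere are NaN).
    """
    counts = table.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("RCbray requires integer counts")
    counts = np.round(counts).astype(np.int64)
    if meta is None:
        meta = Metacommunity.from_table(table)
    n = table.n_samples
    if pairs is None:
        pairs = [(j, k) for j in range(n) for k in range(j + 1, n)]
    rng = np.random.default_rng(cfg.seed)
    richness = (counts > 0).sum(axis=1)
    depths = counts.sum(axis=1)
    obs = squareform(pdist(counts.astype(float), metric="braycurtis"), checks=False)
    below = np.zeros((n, n))
    ties = np.zeros((n, n))
    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    for _ in range(cfg.n_null):
        nulls = np.stack(
            [
                _null_community(int(richness[s]), int(depths[s]), meta, rng)
                for s in range(n)
            ]
        ).astype(float)
        num = np.abs(nulls[rows] - nulls[cols]).sum(axis=1)
        den = (nulls[rows] + nulls[cols]).sum(axis=1)
        bc = num / den
        o = obs[rows, cols]
        tie_mask = np.isclose(bc, o, rtol=0, atol=1e-12)
        below[rows, cols] += (~tie_mask) & (bc < o)
        ties[rows, cols] += tie_mask
    rc = np.full((n, n), np.nan)
    rc[rows, cols] = ((below[rows, cols] + 0.5 * ties[rows, cols]) / cfg.n_null - 0.5) * 2
    rc[cols, rows] = rc[rows, cols]
    np.fill_diagonal(rc, 0.0)
    ids = table.sample_ids
    return pd.DataFrame(rc, index=ids, columns=ids)


def classify_pair(
    bnti: float, rc: float | None, cfg: NullModelConfig | None = None
) -> Process:
    """Deterministic five-way process assignment for one pair.

    Boundary values (betaNTI exactly at +-threshold, RCbray exactly at
    +-threshold) fall to the non-selection / undominated side, so the
    classification is stable under strict-vs-non-strict readings.
    """
    cfg = cfg or NullModelConfig()
    significant = abs(bnti) > cfg.bnti_threshold
    if significant:
        if rc is not None:
            raise ValueError(
                "RCbray must be absent when |betaNTI| exceeds the threshold"
            )
        return (
            Process.VARIABLE_SELECTION if bnti > 0 else Process.HOMOGENEOUS_SELECTION
        )
    if rc is None:
        raise ValueError("RCbray required when betaNTI is non-significant")
    if rc > cfg.rc_threshold:
        return Process.DISPERSAL_LIMITATION
    if rc < -cfg.rc_threshold:
        return Process.HOMOGENIZING_DISPERSAL
    return Process.UNDOMINATED


def classify_pairs(
    bundle: AlignedBundle,
    cfg: NullModelConfig,
) -> list[PairProcessRecord]:
    """Full two-stage inference for every sample pair of a bundle.

    Runs the betaNTI null over all pairs, then the RCbray null only for
    pairs whose betaNTI is non-significant (matching the framework's
    sequential logic), and classifies each pair.  Seeds for the two
    stages are split deterministically from cfg.seed.
    """
    table, tree, metadata = bundle.table, bundle.tree, bundle.metadata
    ss = np.random.SeedSequence(cfg.seed)
    seed_bnti, seed_rc = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    bnti = bnti_matrix(
        table, tree, replace_seed(cfg, seed_bnti), on_degenerate="zero"
    )
    ids = table.sample_ids
    n = len(ids)
    need_rc = [
        (j, k)
        for j in range(n)
        for k in range(j + 1, n)
        if abs(bnti.iloc[j, k]) <= cfg.bnti_threshold
    ]
    if need_rc:
        rc = rc_bray_matrix(table, replace_seed(cfg, seed_rc), pairs=need_rc)
    else:
        rc = pd.DataFrame(np.nan, index=ids, columns=ids)
    groups = metadata.groups_for(ids)
    presence = table.counts > 0
    dist = tip_distance_matrix(tree, table.taxon_ids)
    if cfg.abundance_weighted:
        weights = table.counts / table.counts.sum(axis=1, keepdims=True)
    else:
        weights = np.zeros_like(table.counts)
        weights[presence] = np.repeat(
            1.0 / presence.sum(axis=1), presence.sum(axis=1)
        )
    bmntd_obs = beta_mntd_matrix(weights, presence, dist)
    records = []
    for j in range(n):
        for k in range(j + 1, n):
            b = float(bnti.iloc[j, k])
            r = None if abs(b) > cfg.bnti_threshold else float(rc.iloc[j, k])
            records.append(
                PairProcessRecord(
                    sample_a=ids[j],
                    sample_b=ids[k],
                    comparison_scope=(
                        "within_group" if groups[j] == groups[k] else "between_group"
                    ),
                    beta_mntd_obs=float(bmntd_obs[j, k]),
                    bnti=b,
                    rc_bray=r,
                    process=classify_pair(b, r, cfg),
                )
            )
    return records


def replace_seed(cfg: NullModelConfig, seed: int) -> NullModelConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


@dataclass(frozen=True)
class ProcessSummary:
    scope: str
    counts: dict[Process, int]
    fractions: dict[Process, float]
    selection_total: float
    dispersal_total: float
    n_pairs: int = field(default=0)


def _summarize(records: list[PairProcessRecord], scope: str) -> ProcessSummary:
    if not records:
        raise ValidationError(f"no pairs in scope {scope!r}")
    counts = {p: 0 for p in Process}
    for r in records:
        counts[r.process] += 1
    total = len(records)
    fractions = {p: c / total for p, c in counts.items()}
    return ProcessSummary(
        scope=scope,
        counts=counts,
        fractions=fractions,
        selection_total=sum(fractions[p] for p in SELECTION_PROCESSES),
        dispersal_total=sum(fractions[p] for p in DISPERSAL_PROCESSES),
        n_pairs=total,
    )


def process_fractions(
    records: list[PairProcessRecord],
    metadata: SampleMetadata | None = None,
    scope: str = "within",
    include_within_pairs: bool = True,
) -> ProcessSummary | dict[str, ProcessSummary]:
    """Process counts/fractions over a comparison scope.

    scope "within" / "between" summarize the same-group and
    different-group pairs respectively; "per_group" returns one summary
    per group over every pair involving at least one member of that
    group (``include_within_pairs=False`` restricts a group's summary
    to its between-group pairs, the alternative denominator).
    """
    if scope == "within":
        return _summarize(
            [r for r in records if r.comparison_scope == "within_group"], "within"
        )
    if scope == "between":
        return _summarize(
            [r for r in records if r.comparison_scope == "between_group"], "between"
        )
    if scope != "per_group":
        raise ValueError(f"unknown scope: {scope!r}")
    if metadata is None:
        raise ValueError("per_group scope requires metadata")
    by_sample = metadata.data["group"].to_dict()
    out: dict[str, ProcessSummary] = {}
    for group in sorted(set(by_sample.values())):
        members = {s for s, g in by_sample.items() if g == group}
        recs = [
            r
            for r in records
            if (r.sample_a in members) != (r.sample_b in members)
            or (
                include_within_pairs
                and r.sample_a in members
                and r.sample_b in members
            )
        ]
        out[group] = _summarize(recs, f"per_group:{group}")
    return out
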