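"""Alpha diversity: richness estimators, evenness indices, rarefaction,
and group comparison by one-way ANOVA with Tukey HSD letters.

Index conventions (chosen to match the magnitudes mothur/vegan report
for gut 16S data): Shannon H = -sum p_i ln p_i in nats; Simpson is the
dominance form D = sum p_i^2, so a community collapsed onto one dominant
taxon scores near 1 and an even one near 1/S.  Chao1 uses the classic
formula S_obs + F1^2/(2 F2) when doubletons exist and the bias-corrected
form S_obs + F1(F1-1)/(2(F2+1)) when F2 = 0; ACE uses the standard
rare/abundant threshold of 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityTable, SampleMetadata, ValidationError

logger = logging.getLogger("ecoassembly")

__all__ = [
    "AlphaRecord",
    "alpha_indices",
    "alpha_table",
    "rarefaction_curve",
    "anova_tukey",
    "GroupComparison",
]

ACE_RARE_THRESHOLD = 10


@dataclass(frozen=True)
class AlphaRecord:
    sample_id: str
    observed_otus: int
    chao1: float
    ace: float
    shannon: float
    simpson: float
    goods_coverage: float


def _check_counts(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValidationError("negative counts")
    if not (x > 0).any():
        raise ValidationError("all-zero count vector")
    if not np.allclose(x, np.round(x), atol=1e-9):
        raise ValidationError(
            "Chao1/ACE/Good's coverage require integer counts; "
            "pass counts or compute Shannon/Simpson only"
        )
    return np.round(x).astype(np.int64)


def _chao1(s_obs: int, f1: int, f2: int) -> float:
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(x: np.ndarray) -> float:
    rare = x[(x > 0) & (x <= ACE_RARE_THRESHOLD)]
    s_abund = int((x > ACE_RARE_THRESHOLD).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if f1 == n_rare:
        # every rare taxon a singleton: coverage estimate is 0; fall back
        # to Chao1 as EstimateS does
        s_obs = int((x > 0).sum())
        f2 = int((x == 2).sum())
        return _chao1(s_obs, f1, f2)
    c_ace = 1.0 - f1 / n_rare
    ks = np.arange(1, ACE_RARE_THRESHOLD + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    gamma2 = (s_rare / c_ace) * (ks * (ks - 1) * fk).sum() / (
        n_rare * (n_rare - 1.0)
    ) - 1.0
    gamma2 = max(gamma2, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def alpha_indices(counts, sample_id: str = "") -> AlphaRecord:
    """All six per-sample indices from one integer count vector."""
    x = _check_counts(counts)
    n = int(x.sum())
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    p = x[x > 0] / n
    return AlphaRecord(
        sample_id=sample_id,
        observed_otus=s_obs,
        chao1=_chao1(s_obs, f1, f2),
        ace=_ace(x),
        shannon=float(-(p * np.log(p)).sum()),
        simpson=float((p * p).sum()),
        goods_coverage=1.0 - f1 / n,
    )


def alpha_table(table: CommunityTable, metadata: SampleMetadata | None = None) -> pd.DataFrame:
    """Per-sample alpha indices as a DataFrame (plus group if metadata given)."""
    records = [
        alpha_indices(table.data.loc[s].to_numpy(), sample_id=s)
        for s in table.sample_ids
    ]
    df = pd.DataFrame([{f.name: getattr(r, f.name) for f in fields(r)} for r in records])
    df = df.set_index("sample_id")
    if metadata is not None:
        df.insert(0, "group", metadata.groups_for(df.index))
    return df


def _log_comb(n: float, k: float) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def expected_richness(counts, depth: int) -> float:
    """Analytic rarefaction: E[S] = sum_i 1 - C(N - x_i, n)/C(N, n)."""
    x = _check_counts(counts)
    n_total = int(x.sum())
    if depth > n_total:
        raise ValueError(f"depth {depth} exceeds sample total {n_total}")
    x = x[x > 0]
    terms = np.zeros(len(x))
    for i, xi in enumerate(x):
        if n_total - xi >= depth:
            terms[i] = 1.0 - np.exp(
                _log_comb(n_total - xi, depth) - _log_comb(n_total, depth)
            )
        else:
            terms[i] = 1.0  # taxon certain to appear
    return float(terms.sum())


def rarefaction_curve(
    counts,
    depths: Sequence[int],
    iterations: int = 10,
    seed: int | None = None,
    method: str = "subsample",
) -> pd.DataFrame:
    """Mean observed richness at each subsampling depth.

    ``method="subsample"`` draws without replacement ``iterations`` times;
    ``method="analytic"`` uses the exact hypergeometric expectation.
    """
    x = _check_counts(counts)
    n_total = int(x.sum())
    if any(d > n_total for d in depths):
        raise ValueError("a requested depth exceeds the sample total")
    if any(d < 1 for d in depths):
        raise ValueError("depths must be >= 1")
    if method == "analytic":
        return pd.DataFrame(
            {"depth": list(depths), "richness": [expected_richness(x, d) for d in depths]}
        )
    if method != "subsample":
        raise ValueError(f"unknown method: {method!r}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(x)), x)
    means = []
    for d in depths:
        vals = np.empty(iterations)
        for it in range(iterations):
            draw = rng.choice(pool, size=d, replace=False)
            vals[it] = len(np.unique(draw))
        means.append(vals.mean())
    return pd.DataFrame({"depth": list(depths), "richness": means})


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA + Tukey HSD with a compact letter display."""

    f_statistic: float
    p_value: float
    summary: pd.DataFrame  # index group; columns mean, sd, n, letters
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, reject
    alpha: float


def _compact_letters(groups: list[str], not_different: dict[tuple[str, str], bool],
                     order: list[str]) -> dict[str, str]:
    """Letters from maximal cliques of the 'not significantly different' graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    for (a, b), nd in not_different.items():
        if nd:
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    # order letters by the best (first-in-order) member of each clique
    cliques.sort(key=lambda c: min(order.index(m) for m in c))
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i) if i < 26 else f"z{i}"
        for member in clique:
            letters[member].append(letter)
    return {grp: "".join(sorted(v)) for grp, v in letters.items()}


def anova_tukey(values, groups, alpha: float = 0.05) -> GroupComparison:
    """Compare a per-sample index across groups.

    Classic fixed-effects one-way ANOVA followed by Tukey's HSD; groups
    sharing a letter are not significantly different at ``alpha``. With
    the study design's n = 3 replicates per group the power is modest; a
    caution is logged.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise ValidationError("need >= 2 groups")
    if (sizes < 2).any():
        raise ValidationError(
            f"groups with < 2 observations: {sizes[sizes < 2].index.tolist()}"
        )
    if (sizes <= 3).any():
        logger.info("some groups have <= 3 replicates; ANOVA/Tukey power is low")
    samples = [values[groups == g] for g in sizes.index]
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*samples)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tuk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pair_df = pd.DataFrame(
        tuk.summary().data[1:],
        columns=[str(c) for c in tuk.summary().data[0]],
    )
    pair_df = pair_df.rename(
        columns={"group1": "group_a", "group2": "group_b", "meandiff": "mean_diff",
                 "p-adj": "p_adj"}
    )[["group_a", "group_b", "mean_diff", "p_adj", "reject"]]
    not_diff = {
        (str(r.group_a), str(r.group_b)): not bool(r.reject)
        for r in pair_df.itertuples()
    }
    group_names = [str(g) for g in sizes.index]
    means = {g: values[groups == g].mean() for g in sizes.index}
    order = sorted(group_names, key=lambda g: -means[g])
    letters = _compact_letters(group_names, not_diff, order)
    summary = pd.DataFrame(
        {
            "mean": [means[g] for g in group_names],
            "sd": [values[groups == g].std(ddof=1) for g in group_names],
            "n": [int(sizes[g]) for g in group_names],
            "letters": [letters[g] for g in group_names],
        },
        index=pd.Index(group_names, name="group"),
    ).sort_index()
    return GroupComparison(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        summary=summary,
        pairwise=pair_df,
        alpha=alpha,
    )
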