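"""End-to-end orchestration: from the three input files to alpha/beta
summaries, permutation tests, and per-pair assembly-process calls.

A single config seed fans out to per-stage seeds through a fixed
``numpy.random.SeedSequence`` splitting scheme, so the pipeline as a
whole, and every stage independently, is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import alpha_table, anova_tukey
from .assembly import (
    NullModelConfig,
    Process,
    classify_pairs,
    process_fractions,
)
from .beta import anosim, bray_curtis, nmds, pcoa, permanova, weighted_unifrac
from .io import (
    AlignedBundle,
    align_inputs,
    read_community_table,
    read_metadata,
    read_phylogeny,
    write_distance_matrix,
)

logger = logging.getLogger("ecoassembly")

__all__ = ["RunConfig", "run_pipeline", "report_summary", "rarefy_table"]

STAGES = ("alpha", "beta_distance", "ordination", "tests", "assembly")


@dataclass(frozen=True)
class RunConfig:
    table_path: str
    tree_path: str
    metadata_path: str
    output_dir: str
    seed: int
    rarefy_depth: int | None = None
    permutations: int = 999
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    nmds_starts: int = 20

    def __post_init__(self) -> None:
        if self.permutations < 99:
            logger.warning(
                "permutations = %d is low; p-value resolution is %0.3f",
                self.permutations,
                1 / (self.permutations + 1),
            )


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def rarefy_table(table, depth: int, seed: int | None = None):
    """Subsample every sample to ``depth`` reads without replacement."""
    from .io import CommunityTable

    counts = np.round(table.counts).astype(np.int64)
    if (counts.sum(axis=1) < depth).any():
        short = [
            s
            for s, n in zip(table.sample_ids, counts.sum(axis=1))
            if n < depth
        ]
        raise ValueError(f"samples shallower than rarefaction depth: {short}")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        pool = np.repeat(np.arange(len(row)), row)
        keep = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(keep, minlength=len(row))
    df = pd.DataFrame(out, index=table.sample_ids, columns=table.taxon_ids)
    return CommunityTable(df)


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_a": r.sample_a,
                "sample_b": r.sample_b,
                "scope": r.comparison_scope,
                "beta_mntd": r.beta_mntd_obs,
                "bnti": r.bnti,
                "rc_bray": np.nan if r.rc_bray is None else r.rc_bray,
                "process": r.process.value,
            }
            for r in records
        ]
    )


def _summary_dict(summary) -> dict:
    return {
        "scope": summary.scope,
        "n_pairs": summary.n_pairs,
        "counts": {p.value: c for p, c in summary.counts.items()},
        "fractions": {p.value: f for p, f in summary.fractions.items()},
        "selection_total": summary.selection_total,
        "dispersal_total": summary.dispersal_total,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; write TSV/JSON outputs; return the report dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    logger.info("stage seeds: %s", seeds)

    table = read_community_table(cfg.table_path, orientation="taxa_rows")
    tree = read_phylogeny(cfg.tree_path)
    metadata = read_metadata(cfg.metadata_path)
    bundle = align_inputs(table, tree, metadata)
    bundle.metadata.require_grouped()
    if cfg.rarefy_depth is not None:
        rarefied = rarefy_table(bundle.table, cfg.rarefy_depth, seeds["alpha"])
        bundle = AlignedBundle(
            table=rarefied,
            tree=bundle.tree,
            metadata=bundle.metadata,
            dropped_taxa=bundle.dropped_taxa,
        )
    table = bundle.table
    groups = bundle.groups

    report: dict = {
        "version": __version__,
        "config": {
            **{
                k: v
                for k, v in asdict(cfg).items()
                if k != "null_model"
            },
            "null_model": asdict(cfg.null_model),
        },
        "stage_seeds": seeds,
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "n_dropped_taxa": len(bundle.dropped_taxa),
    }

    # --- alpha -----------------------------------------------------------
    alpha_df = alpha_table(table, bundle.metadata)
    alpha_df.to_csv(out / "alpha_per_sample.tsv", sep="\t")
    group_rows = []
    alpha_report = {}
    for index in ("observed_otus", "chao1", "ace", "shannon", "simpson",
                  "goods_coverage"):
        cmp_res = anova_tukey(alpha_df[index].to_numpy(), groups)
        alpha_report[index] = {
            "F": cmp_res.f_statistic,
            "p": cmp_res.p_value,
        }
        s = cmp_res.summary.copy()
        s.insert(0, "index", index)
        group_rows.append(s)
    pd.concat(group_rows).to_csv(out / "alpha_group_summary.tsv", sep="\t")
    report["alpha_anova"] = alpha_report
    report["alpha_group_summary_path"] = str(out / "alpha_group_summary.tsv")

    # --- beta distances --------------------------------------------------
    bc = bray_curtis(table)
    wu = weighted_unifrac(table, bundle.tree)
    write_distance_matrix(bc, out / "bray_curtis.tsv")
    write_distance_matrix(wu, out / "weighted_unifrac.tsv")

    # --- ordination ------------------------------------------------------
    ordination_report = {}
    for name, dm in (("bray_curtis", bc), ("weighted_unifrac", wu)):
        ord_res = pcoa(dm)
        coords = ord_res.coordinates.iloc[:, :2]
        coords.to_csv(out / f"pcoa_{name}.tsv", sep="\t")
        ordination_report[f"pcoa_{name}_pct"] = [
            float(100 * p) for p in ord_res.proportion_explained[:2]
        ]
    nm = nmds(bc, k=2, n_starts=cfg.nmds_starts, seed=seeds["ordination"])
    nm.coordinates.to_csv(out / "nmds_bray_curtis.tsv", sep="\t")
    ordination_report["nmds_stress"] = nm.stress
    report["ordination"] = ordination_report

    # --- permutation tests ----------------------------------------------
    tests_report = {}
    for name, dm in (("bray_curtis", bc), ("weighted_unifrac", wu)):
        an = anosim(dm, groups, cfg.permutations, seeds["tests"])
        pe = permanova(dm, groups, cfg.permutations, seeds["tests"])
        tests_report[name] = {
            "anosim_R": an.statistic,
            "anosim_p": an.p_value,
            "permanova_F": pe.statistic,
            "permanova_R2": pe.effect_size,
            "permanova_p": pe.p_value,
            "permutations": cfg.permutations,
        }
    report["tests"] = tests_report
    with open(out / "permutation_tests.json", "w") as fh:
        json.dump(tests_report, fh, indent=2)

    # --- assembly processes ---------------------------------------------
    null_cfg = replace(cfg.null_model, seed=seeds["assembly"])
    records = classify_pairs(bundle, null_cfg)
    rec_df = _records_frame(records)
    rec_df.to_csv(out / "pair_processes.tsv", sep="\t", index=False)
    within = process_fractions(records, bundle.metadata, scope="within")
    between = process_fractions(records, bundle.metadata, scope="between")
    per_group = process_fractions(records, bundle.metadata, scope="per_group")
    assembly_report = {
        "within": _summary_dict(within),
        "between": _summary_dict(between),
        "per_group": {g: _summary_dict(s) for g, s in per_group.items()},
    }
    report["assembly"] = assembly_report
    with open(out / "process_summary.json", "w") as fh:
        json.dump(assembly_report, fh, indent=2)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def report_summary(report: dict) -> str:
    """Human-readable text rendering of a pipeline report."""
    lines = [f"ecoassembly v{report['version']} run summary", "=" * 40]
    lines.append(
        f"samples: {report['n_samples']}  taxa: {report['n_taxa']}"
        f"  dropped taxa: {report['n_dropped_taxa']}"
    )
    if "alpha_anova" in report:
        lines.append("")
        lines.append("alpha diversity, one-way ANOVA across groups")
        for index, res in report["alpha_anova"].items():
            lines.append(f"  {index:>15}: F = {res['F']:.3f}, p = {res['p']:.4g}")
    if "ordination" in report:
        o = report["ordination"]
        lines.append("")
        if "pcoa_bray_curtis_pct" in o:
            p1, p2 = o["pcoa_bray_curtis_pct"]
            lines.append(f"PCoA (Bray-Curtis) axis %: {p1:.2f}, {p2:.2f}")
        if "nmds_stress" in o and o["nmds_stress"] is not None:
            lines.append(f"NMDS stress = {o['nmds_stress']:.3f}")
    if "tests" in report:
        lines.append("")
        for metric, res in report["tests"].items():
            lines.append(
                f"{metric}: ANOSIM R = {res['anosim_R']:.3f} (p = {res['anosim_p']:.4g}); "
                f"PERMANOVA R2 = {res['permanova_R2']:.3f} (p = {res['permanova_p']:.4g})"
            )
    if "assembly" in report:
        lines.append("")
        lines.append("assembly processes (% of pairs)")
        header = "  scope          " + "".join(
            f"{p.value[:14]:>16}" for p in Process
        )
        lines.append(header)
        for scope in ("within", "between"):
            s = report["assembly"][scope]
            row = f"  {scope:<14}" + "".join(
                f"{100 * s['fractions'][p.value]:>15.2f}%" for p in Process
            )
            lines.append(row + f"   (n = {s['n_pairs']})")
    return "\n".join(lines)
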