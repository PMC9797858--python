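"""Readers, writers and validation for the three pipeline inputs.

The pipeline consumes an OTU count table (QIIME-classic TSV, taxa as
rows), a rooted newick phylogeny whose tips cover the table's taxa, and
a two-column sample metadata TSV mapping each sample to its group (here,
geographic source).  Everything downstream assumes the validated,
lexicographically ordered bundle produced by :func:`align_inputs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger("ecoassembly")

__all__ = [
    "CommunityTable",
    "SampleMetadata",
    "FormatError",
    "ValidationError",
    "read_community_table",
    "write_community_table",
    "read_phylogeny",
    "read_metadata",
    "write_distance_matrix",
    "read_distance_matrix",
    "align_inputs",
]


class FormatError(ValueError):
    """A file could be read but violates the expected dialect."""


class ValidationError(ValueError):
    """Inputs are well-formed but mutually or internally inconsistent."""


@dataclass(frozen=True)
class CommunityTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa. Non-negative counts or
        relative abundances.
    is_relative : bool
        True when rows are relative abundances summing to one.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon identifiers: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise FormatError("non-finite abundance value")
        if (values < 0).any():
            raise FormatError("negative abundance value")
        row_sums = values.sum(axis=1)
        empty = df.index[row_sums <= 0].tolist()
        if empty:
            raise ValidationError(f"samples with zero total abundance: {empty}")
        if self.is_relative and np.abs(row_sums - 1.0).max() > 1e-9:
            raise ValidationError("relative-abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def relative(self) -> "CommunityTable":
        """Per-sample relative abundances (identity if already relative)."""
        if self.is_relative:
            return self
        rel = self.data.div(self.data.sum(axis=1), axis=0)
        return CommunityTable(rel, is_relative=True)

    def has_integer_counts(self) -> bool:
        v = self.counts
        return bool(np.allclose(v, np.round(v), atol=1e-9)) and not self.is_relative

    def sort(self) -> "CommunityTable":
        """Lexicographic ordering of samples and taxa."""
        return CommunityTable(
            self.data.sort_index(axis=0).sort_index(axis=1), self.is_relative
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Sample -> group mapping with optional extra covariates."""

    data: pd.DataFrame  # indexed by sample_id, must contain a "group" column

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise FormatError("metadata must contain a 'group' column")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate metadata sample identifiers: {dups}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def groups_for(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        return self.data.loc[list(sample_ids), "group"].to_numpy()

    def require_grouped(self, min_groups: int = 2, min_per_group: int = 2) -> None:
        sizes = self.data["group"].value_counts()
        if len(sizes) < min_groups:
            raise ValidationError(f"need >= {min_groups} groups, found {len(sizes)}")
        small = sizes[sizes < min_per_group]
        if len(small):
            raise ValidationError(
                f"groups with < {min_per_group} samples: {small.index.tolist()}"
            )


@dataclass(frozen=True)
class AlignedBundle:
    """Table, tree and metadata restricted to a common, sorted taxon/sample set."""

    table: CommunityTable
    tree: TreeNode
    metadata: SampleMetadata
    dropped_taxa: tuple[str, ...] = field(default=())

    @property
    def groups(self) -> np.ndarray:
        return self.metadata.groups_for(self.table.sample_ids)


def read_community_table(path, orientation: str = "taxa_rows") -> CommunityTable:
    """Read an abundance TSV.

    ``orientation="taxa_rows"`` is the QIIME-classic dialect (first header
    cell ``#OTU ID``, taxa as rows); ``"samples_rows"`` reads the
    transpose. The result always has samples as rows.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance value in {path}: {exc}") from exc
    if orientation == "taxa_rows":
        df = df.T
    values = df.to_numpy()
    is_relative = bool(
        np.allclose(values.sum(axis=1), 1.0, atol=1e-9)
        and not np.allclose(values, np.round(values))
    )
    return CommunityTable(df, is_relative=is_relative)


def write_community_table(table: CommunityTable, path, orientation: str = "taxa_rows") -> None:
    df = table.data
    if orientation == "taxa_rows":
        out = df.T.rename_axis("#OTU ID")
    else:
        out = df.rename_axis("sample_id")
    if table.has_integer_counts():
        out = out.astype(int)
    out.to_csv(path, sep="\t")


def read_phylogeny(path) -> TreeNode:
    """Read a newick tree; midpoint-root if unrooted (>2 root children).

    Patristic distances are rooting-invariant, so midpoint rooting only
    standardizes downstream bookkeeping.
    """
    tree = TreeNode.read(str(path), format="newick")
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        seen, dups = set(), set()
        for n in names:
            (dups if n in seen else seen).add(n)
        raise FormatError(f"duplicate tip labels: {sorted(dups)}")
    for node in tree.postorder(include_self=True):
        if node.is_root():
            continue
        if node.length is None:
            raise FormatError(f"missing branch length on edge above {node.name!r}")
        if node.length < 0:
            raise FormatError(f"negative branch length above {node.name!r}")
    if len(tree.children) > 2:
        logger.info("input tree is unrooted; midpoint-rooting")
        tree = tree.root_at_midpoint()
    return tree


def read_metadata(path) -> SampleMetadata:
    """Read a metadata TSV with header ``sample_id<TAB>group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError("metadata header must include 'sample_id'")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def tip_distance_matrix(tree: TreeNode, taxon_ids) -> np.ndarray:
    """Patristic distances among ``taxon_ids``, in that order."""
    dm = tree.tip_tip_distances()
    idx = [dm.index(t) for t in taxon_ids]
    return dm.data[np.ix_(idx, idx)]


def align_inputs(
    table: CommunityTable, tree: TreeNode, metadata: SampleMetadata
) -> AlignedBundle:
    """Restrict taxa to the table/tree intersection and order everything.

    Taxa in the table but absent from the tree are dropped with a logged
    warning (OTU pipelines routinely leave unplaced taxa); an empty
    intersection or a sample without metadata is an error. Idempotent.
    """
    tip_names = {t.name for t in tree.tips()}
    table_taxa = set(table.taxon_ids)
    shared = sorted(table_taxa & tip_names)
    if not shared:
        raise ValidationError("no taxa shared between table and tree")
    dropped = tuple(sorted(table_taxa - tip_names))
    if dropped:
        logger.warning(
            "dropping %d/%d table taxa absent from the tree (%.1f%%): %s",
            len(dropped),
            len(table_taxa),
            100 * len(dropped) / len(table_taxa),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    extra_tips = len(tip_names - table_taxa)
    if extra_tips:
        logger.info("tree has %d tips not present in the table", extra_tips)
    missing_meta = [s for s in table.sample_ids if s not in metadata.data.index]
    if missing_meta:
        raise ValidationError(f"samples without metadata: {missing_meta}")
    # constructor re-validates: dropping taxa may leave a sample empty
    sub_data = table.data.loc[:, shared]
    sums = sub_data.sum(axis=1)
    emptied = sums.index[sums <= 0].tolist()
    if emptied:
        raise ValidationError(
            f"samples with zero total abundance after taxon alignment: {emptied}"
        )
    if table.is_relative and dropped:
        sub_data = sub_data.div(sums, axis=0)
    sub = CommunityTable(sub_data, table.is_relative).sort()
    tree = tree.shear(shared)
    meta = SampleMetadata(metadata.data.loc[sorted(sub.sample_ids)])
    return AlignedBundle(table=sub, tree=tree, metadata=meta, dropped_taxa=dropped)
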