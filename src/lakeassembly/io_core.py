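"""Readers, validation, QC filtering and normalization for community datasets.

The three input artifacts are a sample x taxon count table (TSV), a rooted
Newick phylogeny whose tips cover the table's taxa, and a per-sample metadata
table (TSV, ISO-8601 dates).  Everything downstream consumes the validated
in-memory objects defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode


class ValidationError(ValueError):
    """Raised when an input artifact violates a structural contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CommunityTable:
    """Sample x taxon matrix of non-negative integer read counts.

    Rows are samples, columns are taxa (ASVs).  Relative abundances are
    derived on demand and always sum to one per sample.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = sorted(c.index[c.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        if c.columns.duplicated().any():
            dups = sorted(c.columns[c.columns.duplicated()].unique())
            raise ValidationError(f"duplicate taxon ids: {dups}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        if np.any(np.mod(vals, 1) != 0):
            raise ValidationError("counts must be integers")
        row_sums = vals.sum(axis=1)
        if (row_sums == 0).any():
            empty = list(c.index[row_sums == 0])
            raise ValidationError(f"samples with zero total count: {empty}")
        # normalize dtype and labels so round-trips are bit-exact
        c = c.astype(np.int64)
        c.index = c.index.astype(str)
        c.index.name = "sample_id"
        c.columns = c.columns.astype(str)
        c.columns.name = None
        self.counts = c

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def rel_abund(self) -> pd.DataFrame:
        """Row-normalized relative abundances (rows sum to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def subset_samples(self, sample_ids, drop_empty_taxa: bool = False) -> "CommunityTable":
        """Subset rows; all taxon columns are kept by default, since the
        table's full taxon set defines the null-model pool downstream."""
        sub = self.counts.loc[list(sample_ids)]
        if drop_empty_taxa:
            sub = sub.loc[:, sub.sum(axis=0) > 0]
        return CommunityTable(sub)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


class PhylogeneticTree:
    """Rooted, branch-lengthed phylogeny; thin wrapper around skbio TreeNode.

    Provides patristic (tip-to-tip path length) distances in a stable taxon
    order and pruning to a taxon subset.
    """

    def __init__(self, tree: TreeNode):
        tips = [t.name for t in tree.tips()]
        if len(tips) != len(set(tips)):
            seen, dups = set(), set()
            for t in tips:
                (dups if t in seen else seen).add(t)
            raise ValidationError(f"duplicate tip labels: {sorted(dups)}")
        for node in tree.traverse():
            if node.is_root():
                continue
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise ValidationError("negative branch length on tree")
        self._tree = tree
        self._tip_names = tips
        self._dist_cache: tuple[tuple[str, ...], np.ndarray] | None = None

    @classmethod
    def read(cls, path) -> "PhylogeneticTree":
        return cls(TreeNode.read(str(path), format="newick"))

    def write(self, path) -> None:
        self._tree.write(str(path), format="newick")

    @property
    def skbio_tree(self) -> TreeNode:
        return self._tree

    @property
    def tip_names(self) -> list[str]:
        return list(self._tip_names)

    @property
    def n_tips(self) -> int:
        return len(self._tip_names)

    @property
    def total_branch_length(self) -> float:
        return float(
            sum(n.length or 0.0 for n in self._tree.traverse() if not n.is_root())
        )

    def prune_to(self, taxa) -> "PhylogeneticTree":
        """Return a copy pruned to exactly the given tip set."""
        taxa = list(taxa)
        missing = sorted(set(taxa) - set(self._tip_names))
        if missing:
            raise ValidationError(f"taxa absent from tree: {missing}")
        sheared = self._tree.shear(taxa)
        sheared.prune()
        return PhylogeneticTree(sheared)

    def patristic_matrix(self, taxa=None) -> tuple[np.ndarray, list[str]]:
        """Pairwise patristic distances as (matrix, taxon order)."""
        if taxa is None:
            taxa = self._tip_names
        taxa = list(taxa)
        if self._dist_cache is None:
            dm = self._tree.tip_tip_distances()
            self._dist_cache = (tuple(dm.ids), np.asarray(dm.data, dtype=float))
        ids, data = self._dist_cache
        pos = {t: i for i, t in enumerate(ids)}
        try:
            idx = np.array([pos[t] for t in taxa])
        except KeyError as e:
            raise ValidationError(f"taxon absent from tree: {e.args[0]}") from None
        return data[np.ix_(idx, idx)], taxa


# required metadata columns; everything else numeric is treated as an
# environmental variable, plus the boolean ice_cover flag
_REQUIRED_META = ("date", "lake", "scale")


@dataclass
class SampleMetadata:
    """Per-sample collection and environmental metadata."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        missing = [c for c in _REQUIRED_META if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        if "ice_cover" in df.columns:
            df["ice_cover"] = df["ice_cover"].astype(bool)
        for col in self._env_columns(df):
            vals = df[col].dropna()
            if not np.isfinite(vals.to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite values in metadata column {col!r}")
        self.data = df

    @staticmethod
    def _env_columns(df: pd.DataFrame) -> list[str]:
        skip = set(_REQUIRED_META) | {"ice_cover", "depth", "replicate"}
        return [
            c
            for c in df.columns
            if c not in skip and np.issubdtype(df[c].dtype, np.number)
        ]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def env_columns(self) -> list[str]:
        return self._env_columns(self.data)

    def env_table(self, variables=None, include_ice=True) -> pd.DataFrame:
        """Numeric environmental matrix (ice_cover encoded 0/1)."""
        cols = list(variables) if variables is not None else self.env_columns
        out = {}
        for c in cols:
            if c == "ice_cover":
                out[c] = self.data[c].astype(float)
            else:
                out[c] = self.data[c].astype(float)
        df = pd.DataFrame(out, index=self.data.index)
        if variables is None and include_ice and "ice_cover" in self.data.columns:
            df["ice_cover"] = self.data["ice_cover"].astype(float)
        return df

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"])
    )
    removed_taxa: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["taxon_id", "reason"])
    )

    @property
    def n_removed(self) -> int:
        return len(self.removed_samples) + len(self.removed_taxa)

    def to_tsv(self, path) -> None:
        rows = [
            {"kind": "taxon", "id": r.taxon_id, "reason": r.reason}
            for r in self.removed_taxa.itertuples()
        ] + [
            {"kind": "sample", "id": r.sample_id, "reason": r.reason}
            for r in self.removed_samples.itertuples()
        ]
        pd.DataFrame(rows, columns=["kind", "id", "reason"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _read_count_table(table_path, metadata_ids: set[str]) -> pd.DataFrame:
    df = pd.read_csv(table_path, sep="\t", index_col=0)
    # auto-detect orientation: samples must be rows; match against metadata ids
    row_hits = len(set(map(str, df.index)) & metadata_ids)
    col_hits = len(set(map(str, df.columns)) & metadata_ids)
    if col_hits > row_hits:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_dataset(
    table_path, tree_path, metadata_path
) -> tuple[CommunityTable, PhylogeneticTree, SampleMetadata]:
    """Load and cross-validate the count table, phylogeny and metadata.

    The tree may carry extra tips; it is pruned to the table's taxa.  Sample
    ids of table and metadata must match exactly.
    """
    for p in (table_path, tree_path, metadata_path):
        if not Path(p).exists():
            raise ValidationError(f"input file not found: {p}")
    meta_df = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta_df.index = meta_df.index.astype(str)
    metadata = SampleMetadata(meta_df)
    counts = _read_count_table(table_path, set(metadata.sample_ids))
    table = CommunityTable(counts)

    tab_ids, meta_ids = set(table.sample_ids), set(metadata.sample_ids)
    if tab_ids != meta_ids:
        only_tab = sorted(tab_ids - meta_ids)
        only_meta = sorted(meta_ids - tab_ids)
        parts = []
        if only_tab:
            parts.append(f"samples missing from metadata: {only_tab}")
        if only_meta:
            parts.append(f"samples missing from table: {only_meta}")
        raise ValidationError("; ".join(parts))
    metadata = SampleMetadata(metadata.data.loc[table.sample_ids])

    tree = PhylogeneticTree.read(tree_path)
    missing_tips = sorted(set(table.taxon_ids) - set(tree.tip_names))
    if missing_tips:
        raise ValidationError(f"taxa absent from tree: {missing_tips}")
    if set(tree.tip_names) != set(table.taxon_ids):
        tree = tree.prune_to(table.taxon_ids)
    return table, tree, metadata


def write_dataset(
    table: CommunityTable,
    tree: PhylogeneticTree,
    metadata: SampleMetadata,
    out_dir,
) -> dict[str, Path]:
    """Write the triplet in the formats load_dataset reads (exact round-trip)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "table.tsv",
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
    }
    table.to_tsv(paths["table"])
    tree.write(paths["tree"])
    metadata.to_tsv(paths["metadata"])
    return paths


# taxon labels dropped during QC, per the standard 16S screening of
# non-target lineages and unclassifiable reads
_BAD_LABEL_SUBSTRINGS = ("archaea", "chloroplast")
_BAD_LABEL_EXACT = ("na", "unknown", "unclassified", "")


def _is_unwanted_label(label) -> str | None:
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return "unclassified (NA)"
    s = str(label).strip().lower()
    if s in _BAD_LABEL_EXACT:
        return "unclassified (NA)"
    for sub in _BAD_LABEL_SUBSTRINGS:
        if sub in s:
            return sub.capitalize()
    return None


def qc_filter(
    table: CommunityTable,
    taxonomy=None,
    min_reads: int = 10_000,
) -> tuple[CommunityTable, QCReport]:
    """Drop non-target taxa, then under-sequenced samples.

    Taxa labelled Archaea, chloroplast or unclassified (NA/unknown) are
    removed first; afterwards every sample whose remaining read total is
    below ``min_reads`` is removed.  Applying the filter twice is a no-op.
    """
    if min_reads < 0:
        raise ValidationError("min_reads must be >= 0")
    counts = table.counts
    removed_taxa = []
    if taxonomy is not None:
        for taxon in counts.columns:
            reason = _is_unwanted_label(taxonomy.get(taxon, "keep"))
            if reason is not None:
                removed_taxa.append({"taxon_id": taxon, "reason": reason})
        if removed_taxa:
            drop = [r["taxon_id"] for r in removed_taxa]
            counts = counts.drop(columns=drop)

    row_sums = counts.sum(axis=1)
    # samples left without any reads by the taxon filter are always dropped
    low = (row_sums < min_reads) | (row_sums == 0)
    removed_samples = [
        {"sample_id": s,
         "reason": f"total reads {int(row_sums[s])} < {max(min_reads, 1)}"}
        for s in counts.index[low]
    ]
    counts = counts.loc[~low]
    if counts.shape[0] == 0:
        raise ValidationError("empty table after QC")
    if low.any():
        # drop taxa that lost all their reads with the removed samples
        counts = counts.loc[:, counts.sum(axis=0) > 0]
    report = QCReport(
        removed_samples=pd.DataFrame(
            removed_samples, columns=["sample_id", "reason"]
        ),
        removed_taxa=pd.DataFrame(removed_taxa, columns=["taxon_id", "reason"]),
    )
    return CommunityTable(counts), report


@dataclass
class NormalizedTable:
    """Size-factor normalized, shifted-log2 transformed table.

    values[i, k] = log2(count[i, k] / s_i + 1) with median-of-ratios size
    factors s_i computed against the per-taxon geometric-mean reference.
    """

    values: pd.DataFrame
    size_factors: pd.Series


def size_factor_normalize(
    table: CommunityTable, allow_fallback: bool = True
) -> NormalizedTable:
    """Median-of-ratios size factors + shifted log2 transform.

    Taxa with a zero count in any sample are excluded from the geometric-mean
    reference.  If no taxon is usable, total-count ratios are used instead
    (with a warning) unless ``allow_fallback`` is false.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise ValidationError("size-factor normalization needs >= 2 samples")
    all_present = (counts > 0).all(axis=0)
    if all_present.any():
        ref = np.exp(np.mean(np.log(counts[:, all_present]), axis=0))
        ratios = counts[:, all_present] / ref
        s = np.median(ratios, axis=1)
    elif allow_fallback:
        warnings.warn(
            "no taxon present in all samples; falling back to total-count "
            "size factors",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = counts.sum(axis=1)
        s = totals / np.exp(np.mean(np.log(totals)))
    else:
        raise ValidationError(
            "no taxon present in all samples and fallback disabled"
        )
    values = np.log2(counts / s[:, None] + 1.0)
    return NormalizedTable(
        values=pd.DataFrame(
            values, index=table.counts.index, columns=table.counts.columns
        ),
        size_factors=pd.Series(s, index=table.counts.index, name="size_factor"),
    )
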