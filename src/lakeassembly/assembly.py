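"""Phylogenetic and taxonomic null models for community assembly inference.

The turnover between every pair of communities is scored twice:

* betaNTI — the z-score of the observed abundance-weighted beta mean nearest
  taxon distance (betaMNTD) against a null distribution obtained by
  randomizing the tips of the phylogeny (abundances untouched).  Strongly
  negative values mean phylogenetic turnover is lower than chance
  (homogeneous selection); strongly positive values mean it is higher
  (variable selection).

* RCbray — the Raup-Crick standardization of Bray-Curtis dissimilarity
  against a probabilistic assembly null that preserves each sample's
  richness and read total while drawing taxa by occurrence frequency and
  individuals by metacommunity relative abundance, rescaled to [-1, 1].

Pairs not dominated by selection (|betaNTI| <= 2) are attributed to
dispersal limitation (RCbray > 0.95), homogenizing dispersal
(RCbray < -0.95) or drift/undominated (|RCbray| <= 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CommunityTable, PhylogeneticTree, ValidationError
from .matrices import DissimilarityMatrix, pair_index

PROCESS_CATEGORIES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


@dataclass
class NullModelConfig:
    """Null-model settings: 999 randomizations by default, abundance-weighted."""

    n_null: int = 999
    seed: int = 0
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValidationError("n_null must be >= 1")


@dataclass
class NullModelResult:
    """Per-pair observed statistics and null-model scores.

    ``pairs`` is a long-format frame indexed by (sample_a, sample_b) in
    condensed order; which columns are present depends on the producing
    operation (betaMNTD/betaNTI columns, RCbray columns, or both after
    ``combine_null_results``).
    """

    ids: list[str]
    pairs: pd.DataFrame

    def matrix(self, column: str) -> DissimilarityMatrix:
        n = len(self.ids)
        data = np.zeros((n, n))
        pos = {s: i for i, s in enumerate(self.ids)}
        for (a, b), v in self.pairs[column].items():
            i, j = pos[a], pos[b]
            data[i, j] = data[j, i] = v
        return DissimilarityMatrix(data, self.ids, check_hollow=False)


def _pair_frame(ids, **columns) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(pair_index(ids), names=["sample_a", "sample_b"])
    return pd.DataFrame(columns, index=idx)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def _weights_and_presence(table: CommunityTable, weighted: bool):
    counts = table.counts.to_numpy(dtype=float)
    presence = counts > 0
    if not presence.any(axis=1).all():
        raise ValidationError("empty community in table")
    if weighted:
        w = counts / counts.sum(axis=1, keepdims=True)
    else:
        w = presence / presence.sum(axis=1, keepdims=True)
    return w, presence


def _bmntd_matrix(w: np.ndarray, presence: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given taxon weights and a patristic matrix.

    M[l, i] = distance from taxon i to its nearest taxon present in sample l;
    betaMNTD(k, l) = 1/2 (sum_i w_ik M[l, i] + sum_j w_jl M[k, j]).
    """
    n_samples = presence.shape[0]
    m = np.empty((n_samples, dist.shape[0]))
    for l in range(n_samples):
        m[l] = dist[:, presence[l]].min(axis=1)
    b = w @ m.T
    out = 0.5 * (b + b.T)
    np.fill_diagonal(out, 0.0)
    return out


def bmntd(
    table: CommunityTable, tree: PhylogeneticTree, weighted: bool = True
) -> DissimilarityMatrix:
    """Observed between-community mean nearest taxon distance (patristic units)."""
    dist, _ = tree.patristic_matrix(table.taxon_ids)
    w, presence = _weights_and_presence(table, weighted)
    return DissimilarityMatrix(_bmntd_matrix(w, presence, dist), table.sample_ids)


def bnti(
    table: CommunityTable, tree: PhylogeneticTree, cfg: NullModelConfig
) -> NullModelResult:
    """betaNTI: z-score of observed betaMNTD against tip-randomization nulls.

    The shuffle permutes tip labels among the taxa present in the analysed
    table only (the tree is pruned first), leaving abundances untouched.
    Pairs whose null distribution has zero spread are flagged undefined
    (NaN) rather than scored.
    """
    if set(tree.tip_names) != set(table.taxon_ids):
        tree = tree.prune_to(table.taxon_ids)
    dist, _ = tree.patristic_matrix(table.taxon_ids)
    w, presence = _weights_and_presence(table, cfg.weighted)
    obs = _bmntd_matrix(w, presence, dist)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    n_taxa = dist.shape[0]
    n = len(table.sample_ids)
    nulls = np.empty((cfg.n_null, n, n))
    for b in range(cfg.n_null):
        perm = rng.permutation(n_taxa)
        nulls[b] = _bmntd_matrix(w, presence, dist[np.ix_(perm, perm)])

    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0)  # population convention, matches the z-score
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - null_mean) / null_sd
    iu = np.triu_indices(n, k=1)
    sd_flat = null_sd[iu]
    # a spread at floating-point noise level means the null is degenerate
    defined = sd_flat > 1e-9 * np.maximum(null_mean[iu], 1e-12)
    pairs = _pair_frame(
        table.sample_ids,
        bmntd_obs=obs[iu],
        null_mean=null_mean[iu],
        null_sd=sd_flat,
        bnti=np.where(defined, z[iu], np.nan),
        bnti_defined=defined,
    )
    return NullModelResult(ids=table.sample_ids, pairs=pairs)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------


def _null_count_draws(rng, richness, total, occ_freq, ab_weight, n_null):
    """Null community counts preserving richness and total abundance.

    Taxa are drawn without replacement with probability proportional to
    occurrence frequency (exponential-race keys), receive one individual
    each, and the remaining individuals are allocated multinomially with
    probability proportional to mean relative abundance over the drawn taxa.
    """
    n_taxa = occ_freq.shape[0]
    with np.errstate(divide="ignore"):
        keys = rng.exponential(size=(n_null, n_taxa)) / occ_freq
    chosen = np.argpartition(keys, richness - 1, axis=1)[:, :richness]
    memb = np.zeros((n_null, n_taxa))
    memb[np.arange(n_null)[:, None], chosen] = 1.0
    p = memb * ab_weight
    p /= p.sum(axis=1, keepdims=True)
    counts = memb
    if total > richness:
        counts = memb + rng.multinomial(total - richness, p)
    return counts


def raup_crick_bray(table: CommunityTable, cfg: NullModelConfig) -> NullModelResult:
    """RCbray per sample pair, on raw counts.

    RCbray = ((#{null BC < obs BC} + 1/2 #{ties}) / n_null - 0.5) x 2,
    bounded in [-1, 1].  Null streams are derived per pair from the master
    seed, so results do not depend on iteration order.
    """
    if table.n_samples < 2:
        raise ValidationError("RCbray needs >= 2 samples")
    counts = table.counts.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    rel = counts / totals[:, None]
    occ = (counts > 0).mean(axis=0)
    ab = rel.mean(axis=0)
    n = table.n_samples

    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(1, i, j))
            )
            nk = _null_count_draws(
                rng, int((counts[i] > 0).sum()), int(totals[i]), occ, ab, cfg.n_null
            )
            nl = _null_count_draws(
                rng, int((counts[j] > 0).sum()), int(totals[j]), occ, ab, cfg.n_null
            )
            fk = nk / nk.sum(axis=1, keepdims=True)
            fl = nl / nl.sum(axis=1, keepdims=True)
            bc_null = 0.5 * np.abs(fk - fl).sum(axis=1)
            bc_obs = 0.5 * np.abs(rel[i] - rel[j]).sum()
            below = int(np.sum(bc_null < bc_obs))
            ties = int(np.sum(bc_null == bc_obs))
            rc = ((below + 0.5 * ties) / cfg.n_null - 0.5) * 2.0
            rows.append((bc_obs, rc))
    arr = np.array(rows)
    pairs = _pair_frame(table.sample_ids, bc_obs=arr[:, 0], rcbray=arr[:, 1])
    return NullModelResult(ids=table.sample_ids, pairs=pairs)


def combine_null_results(
    phylo: NullModelResult, taxo: NullModelResult
) -> NullModelResult:
    """Join betaNTI and RCbray per-pair tables over the same samples."""
    if phylo.ids != taxo.ids:
        raise ValidationError("null-model results cover different samples")
    pairs = phylo.pairs.join(taxo.pairs, how="inner")
    return NullModelResult(ids=phylo.ids, pairs=pairs)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class ProcessClassification:
    """Per-pair assembly-process categories plus the count of pairs that
    could not be scored (undefined betaNTI)."""

    pairs: pd.DataFrame
    n_undefined: int = 0

    def to_tsv(self, path) -> None:
        out = self.pairs.reset_index()
        out.to_csv(path, sep="\t", index=False)


def categorize_pair(bnti_value: float, rcbray_value: float) -> str:
    """Map one (betaNTI, RCbray) pair to an assembly process.

    Boundary convention: the selection calls require strictly |betaNTI| > 2
    and the dispersal calls strictly |RCbray| > 0.95; exact boundary values
    therefore fall to the stochastic / undominated side.
    """
    if np.isnan(bnti_value):
        raise ValidationError("betaNTI undefined; drop the pair before classifying")
    if bnti_value > 2.0:
        return "variable_selection"
    if bnti_value < -2.0:
        return "homogeneous_selection"
    if np.isnan(rcbray_value):
        raise ValidationError("RCbray required when |betaNTI| <= 2")
    if rcbray_value > 0.95:
        return "dispersal_limitation"
    if rcbray_value < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def classify_processes(res: NullModelResult) -> ProcessClassification:
    """Classify every scored pair into one of the five assembly processes."""
    pairs = res.pairs
    for col in ("bnti", "rcbray"):
        if col not in pairs.columns:
            raise ValidationError(f"missing column {col!r}; combine results first")
    defined = pairs["bnti"].notna()
    dropped = int((~defined).sum())
    scored = pairs.loc[defined].copy()
    scored["category"] = [
        categorize_pair(b, r) for b, r in zip(scored["bnti"], scored["rcbray"])
    ]
    return ProcessClassification(pairs=scored, n_undefined=dropped)


def summarize_fractions(
    cls: ProcessClassification, grouping: pd.Series | None = None
) -> pd.DataFrame:
    """Percentage of pairs per process category, per group.

    ``grouping`` maps sample id -> group label (e.g. lake x scale); only
    pairs whose two samples share a group are counted, and cross-group pairs
    are ignored.  Percentages sum to 100 within each group.
    """
    pairs = cls.pairs
    if grouping is not None:
        a = pairs.index.get_level_values("sample_a").map(grouping)
        b = pairs.index.get_level_values("sample_b").map(grouping)
        same = (a == b) & a.notna()
        pairs = pairs.loc[same]
        group_labels = a[same]
        expected_groups = set(grouping.dropna().unique())
    else:
        group_labels = pd.Index(["all"] * len(pairs))
        expected_groups = {"all"} if len(pairs) else set()
    if len(pairs) == 0:
        raise ValidationError("no classified pairs to summarize")

    rows = []
    seen_groups = set()
    for group in sorted(set(group_labels)):
        sub = pairs.loc[np.asarray(group_labels == group)]
        seen_groups.add(group)
        total = len(sub)
        counts = sub["category"].value_counts()
        for cat in PROCESS_CATEGORIES:
            n = int(counts.get(cat, 0))
            rows.append(
                {
                    "group": group,
                    "category": cat,
                    "n_pairs": n,
                    "percent": 100.0 * n / total,
                }
            )
    empty = sorted(expected_groups - seen_groups)
    if empty:
        raise ValidationError(f"groups with no classified pairs: {empty}")
    return pd.DataFrame(rows)
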