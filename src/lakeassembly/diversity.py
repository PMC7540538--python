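"""Alpha-diversity profiles and Bray-Curtis beta diversity.

Alpha diversity is reported as asymptotic Hill numbers: bias-corrected Chao1
richness (order 0), the Chao-Wang-Jost low-bias entropy estimator
exponentiated to an effective taxon count (order 1), and the unbiased
inverse-Simpson estimator (order 2), plus Faith's phylogenetic diversity.
Beta diversity is Bray-Curtis on relative abundances, with a percent
similarity view.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import digamma

from .io_core import CommunityTable, PhylogeneticTree, ValidationError
from .matrices import DissimilarityMatrix

__all__ = [
    "alpha_diversity_profile",
    "chao1",
    "asymptotic_shannon_hill",
    "asymptotic_simpson_hill",
    "faith_pd",
    "bray_curtis",
]


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 asymptotic richness.

    S_obs + F1 (F1 - 1) / (2 (F2 + 1)), defined also when no doubletons
    are observed.
    """
    x = np.asarray(counts)
    x = x[x > 0]
    s_obs = len(x)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def asymptotic_shannon_hill(counts: np.ndarray) -> float:
    """Asymptotic Shannon diversity as a Hill number (effective taxa).

    Uses the low-bias entropy estimator of Chao, Wang & Jost (2013), which
    combines the observed-frequency harmonic-sum term with a correction for
    undetected taxa driven by the singleton/doubleton counts, then
    exponentiates to Hill order 1.
    """
    x = np.asarray(counts, dtype=np.int64)
    x = x[x > 0]
    n = int(x.sum())
    if n < 2:
        raise ValidationError("asymptotic estimators need >= 2 reads")
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    # sum_{k=x_i}^{n-1} 1/k = psi(n) - psi(x_i)
    xs = x[x <= n - 1]
    part1 = float(np.sum(xs / n * (digamma(n) - digamma(xs))))
    if f1 == 0:
        a = 1.0
    elif f2 > 0:
        a = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
    else:
        a = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    part2 = 0.0
    if a < 1.0:
        r = np.arange(1, n, dtype=float)
        log1ma = np.log1p(-a)
        tail = -np.log(a) - float(np.sum(np.exp(r * log1ma) / r))
        if tail > 0.0 and (1 - n) * log1ma < 700.0:
            part2 = f1 / n * np.exp((1 - n) * log1ma) * tail
    return float(np.exp(part1 + part2))


def asymptotic_simpson_hill(counts: np.ndarray) -> float:
    """Asymptotic inverse-Simpson (Hill order 2), unbiased estimator.

    1 / sum_i [ x_i (x_i - 1) / (n (n - 1)) ].
    """
    x = np.asarray(counts, dtype=np.float64)
    x = x[x > 0]
    n = x.sum()
    if n < 2:
        raise ValidationError("asymptotic estimators need >= 2 reads")
    denom = float(np.sum(x * (x - 1))) / (n * (n - 1))
    if denom == 0.0:
        # every taxon a singleton; Simpson concentration unestimable, return
        # the maximal effective count consistent with the data
        return float(len(x))
    return 1.0 / denom


def faith_pd(
    presence_taxa, tree: PhylogeneticTree
) -> float:
    """Faith's PD: total branch length of the subtree spanning the present
    taxa and the root."""
    present = set(presence_taxa)
    if not present:
        raise ValidationError("Faith's PD undefined for an empty community")
    missing = present - set(tree.tip_names)
    if missing:
        raise ValidationError(f"taxa absent from tree: {sorted(missing)}")
    total = 0.0
    for node in tree.skbio_tree.postorder(include_self=False):
        if node.is_tip():
            node._pd_hit = node.name in present
        else:
            node._pd_hit = any(c._pd_hit for c in node.children)
        if node._pd_hit:
            total += node.length or 0.0
    for node in tree.skbio_tree.postorder(include_self=False):
        del node._pd_hit
    return total


def alpha_diversity_profile(
    table: CommunityTable, tree: PhylogeneticTree | None = None
) -> pd.DataFrame:
    """Per-sample alpha-diversity profile on raw (untransformed) counts.

    Columns: observed richness, singleton and doubleton counts, asymptotic
    richness (Chao1), asymptotic Shannon and Simpson Hill numbers and,
    when a tree is given, Faith's PD.
    """
    rows = {}
    for sample in table.sample_ids:
        x = table.counts.loc[sample].to_numpy()
        present = x > 0
        rec = {
            "richness_obs": int(present.sum()),
            "F1": int(np.sum(x == 1)),
            "F2": int(np.sum(x == 2)),
            "richness_asymptotic": chao1(x),
            "shannon_hill_asymptotic": asymptotic_shannon_hill(x),
            "simpson_hill_asymptotic": asymptotic_simpson_hill(x),
        }
        if tree is not None:
            taxa = [t for t, p in zip(table.taxon_ids, present) if p]
            rec["faith_pd"] = faith_pd(taxa, tree)
        rows[sample] = rec
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def bray_curtis(table: CommunityTable) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity on relative abundances.

    BC(k, l) = 1/2 sum_i |f_ik - f_il|; ``similarity_percent`` on the result
    gives the (1 - BC) x 100 view.
    """
    if table.n_samples < 2:
        raise ValidationError("Bray-Curtis needs >= 2 samples")
    f = table.rel_abund.to_numpy()
    d = squareform(pdist(f, metric="braycurtis"))
    return DissimilarityMatrix(d, table.sample_ids)
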