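"""Ordination, permutation statistics, and selection-driver identification.

Covers the multivariate toolbox of the pipeline: non-metric MDS on community
dissimilarities, ANOSIM and homogeneity-of-dispersion permutation tests,
vector fitting of environmental variables, the exhaustive BIOENV search for
the environment subset that best rank-correlates with community turnover,
distance-based Moran's eigenvector maps for temporal structure, PCA of
environment + temporal eigenvectors, and forward-selected distance-based RDA
of the (normalized) betaNTI matrix on those PCA axes.

All permutation p-values use the convention (1 + #{null >= observed}) /
(n_perm + 1), so p >= 1/(n_perm + 1) always.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .io_core import ValidationError
from .matrices import DissimilarityMatrix

_EIG_TOL = 1e-9


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    method: str
    scores: pd.DataFrame  # samples x axes
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    loadings: pd.DataFrame | None = None  # variables x axes (correlations)

    @property
    def proportion_explained(self) -> np.ndarray | None:
        if self.eigenvalues is None:
            return None
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class PermutationTestResult:
    name: str
    statistic: float
    p_value: float
    n_perm: int
    extras: dict = field(default_factory=dict)


@dataclass
class SelectionReport:
    """Forward-selection outcome of the distance-based RDA."""

    selected: pd.DataFrame  # axis, adj_r2_cum, adj_r2_gain, p_value, interpretation
    full_model_adj_r2: float
    loadings: pd.DataFrame | None = None
    loading_threshold: float = 0.4

    def to_tsv(self, path) -> None:
        self.selected.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            f"full-model adjusted R2: {self.full_model_adj_r2:.4f}",
            f"axes selected: {len(self.selected)}",
        ]
        for row in self.selected.itertuples():
            lines.append(
                f"  {row.axis}: cumulative adj R2 {row.adj_r2_cum:.4f} "
                f"(gain {row.adj_r2_gain:.4f}, p = {row.p_value:.4f}, "
                f"{row.interpretation})"
            )
        return "\n".join(lines)


def _perm_p(null: np.ndarray, observed: float) -> float:
    return (1.0 + np.sum(null >= observed)) / (len(null) + 1.0)


# ---------------------------------------------------------------------------
# Principal coordinates (shared helper)
# ---------------------------------------------------------------------------


def _gower_centered(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def principal_coordinates(d: np.ndarray):
    """Eigendecomposition of the Gower-centered matrix.

    Returns (eigenvalues desc, eigenvectors as columns), both real; callers
    pick positive / negative parts as needed.
    """
    b = _gower_centered(np.asarray(d, dtype=float))
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # deterministic sign: largest-magnitude entry positive
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


def _positive_coordinates(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample coordinates on the positive-eigenvalue axes, scaled sqrt(lambda)."""
    vals, vecs = principal_coordinates(d)
    keep = vals > _EIG_TOL * max(vals.max(), 1.0)
    return vecs[:, keep] * np.sqrt(vals[keep]), vals[keep]


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    include_pcoa_start: bool = True,
) -> OrdinationResult:
    """Non-metric MDS by iterative stress minimization (best of many starts).

    Runs ``n_starts`` random initializations plus (by default) one start from
    the principal-coordinates configuration, and returns the embedding with
    the lowest Kruskal stress-1.
    """
    from sklearn.manifold import MDS

    n = len(d)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n:
        raise ValidationError(f"k={k} must be below the sample count {n}")
    common = dict(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        normalized_stress=True,
        max_iter=500,
        eps=1e-6,
    )
    best_stress, best_scores = np.inf, None
    if n_starts >= 1:
        model = MDS(n_init=n_starts, init="random", random_state=seed, **common)
        model.fit(d.data)
        best_stress, best_scores = model.stress_, model.embedding_
    if include_pcoa_start:
        model = MDS(n_init=1, init="classical_mds", random_state=seed, **common)
        model.fit(d.data)
        if model.stress_ < best_stress:
            best_stress, best_scores = model.stress_, model.embedding_
    scores = best_scores - best_scores.mean(axis=0)
    return OrdinationResult(
        method="nmds",
        scores=pd.DataFrame(
            scores, index=d.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
        ),
        stress=float(best_stress),
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def _check_groups(ids, groups: pd.Series) -> np.ndarray:
    g = groups.reindex(ids)
    if g.isna().any():
        missing = sorted(g.index[g.isna()])
        raise ValidationError(f"group label missing for samples: {missing}")
    sizes = g.value_counts()
    if len(sizes) < 2:
        raise ValidationError("need at least 2 groups")
    singles = sorted(sizes.index[sizes < 2])
    if singles:
        raise ValidationError(f"singleton groups: {singles}")
    return g.to_numpy()


def anosim(
    d: DissimilarityMatrix, groups: pd.Series, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """ANOSIM R with a label-permutation test.

    R = (mean between-group rank - mean within-group rank) / (N (N - 1) / 4)
    on the ranked pairwise dissimilarities.
    """
    g = _check_groups(d.ids, groups)
    n = len(d.ids)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d.condensed())
    denom = n * (n - 1) / 4.0

    def stat(labels: np.ndarray) -> float:
        within = labels[iu[0]] == labels[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = stat(g)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(30,)))
    null = np.array([stat(rng.permutation(g)) for _ in range(n_perm)])
    return PermutationTestResult(
        name="anosim", statistic=float(observed), p_value=_perm_p(null, observed),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# PERMDISP (betadisper-style homogeneity of dispersion)
# ---------------------------------------------------------------------------


def permdisp(
    d: DissimilarityMatrix, groups: pd.Series, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersion around group centroids.

    Samples are embedded by principal coordinates; negative eigenvalues are
    kept as imaginary axes whose squared distances are subtracted.  The F
    statistic of a one-way ANOVA on the distances to own-group centroids is
    tested by permuting group labels.
    """
    g = _check_groups(d.ids, groups)
    vals, vecs = principal_coordinates(d.data)
    tol = _EIG_TOL * max(abs(vals).max(), 1.0)
    pos, neg = vals > tol, vals < -tol
    y_pos = vecs[:, pos] * np.sqrt(vals[pos])
    y_neg = vecs[:, neg] * np.sqrt(-vals[neg])

    labels = np.unique(g)

    def centroid_distances(assign: np.ndarray) -> np.ndarray:
        dist = np.empty(len(assign))
        for lab in labels:
            mask = assign == lab
            cp = y_pos[mask].mean(axis=0)
            cn = y_neg[mask].mean(axis=0) if y_neg.shape[1] else 0.0
            d2 = ((y_pos[mask] - cp) ** 2).sum(axis=1)
            if y_neg.shape[1]:
                d2 = d2 - ((y_neg[mask] - cn) ** 2).sum(axis=1)
            dist[mask] = np.sqrt(np.clip(d2, 0.0, None))
        return dist

    def f_stat(distances: np.ndarray, assign: np.ndarray) -> float:
        grand = distances.mean()
        ss_b = ss_w = 0.0
        for lab in labels:
            sub = distances[assign == lab]
            ss_b += len(sub) * (sub.mean() - grand) ** 2
            ss_w += ((sub - sub.mean()) ** 2).sum()
        df_b, df_w = len(labels) - 1, len(distances) - len(labels)
        return (ss_b / df_b) / (ss_w / df_w)

    obs_dist = centroid_distances(g)
    observed = f_stat(obs_dist, g)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(31,)))
    null = np.empty(n_perm)
    # betadisper permutes the distances-to-centroid among samples
    for b in range(n_perm):
        null[b] = f_stat(obs_dist[rng.permutation(len(g))], g)
    group_means = {
        lab: float(obs_dist[g == lab].mean()) for lab in labels
    }
    return PermutationTestResult(
        name="permdisp",
        statistic=float(observed),
        p_value=_perm_p(null, observed),
        n_perm=n_perm,
        extras={
            "group_mean_distance": group_means,
            "sample_distances": pd.Series(obs_dist, index=d.ids),
        },
    )


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------


def envfit(
    ordination: OrdinationResult,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Least-squares fit of environmental vectors into an ordination.

    Per variable: the arrow is the regression direction of the variable on
    the (centered) sample scores, R^2 is the squared correlation of the
    fitted projection with the variable, and p comes from sample shuffles.
    Zero-variance variables are flagged and skipped.
    """
    x = ordination.scores.to_numpy()
    x = x - x.mean(axis=0)
    env = env.reindex(ordination.scores.index)
    if env.isna().any().any():
        raise ValidationError("environment incomplete for ordinated samples")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(32,)))
    rows = []
    axes = list(ordination.scores.columns)
    for var in env.columns:
        y = env[var].to_numpy(dtype=float)
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot == 0.0:
            rows.append(
                {"variable": var, "r2": np.nan, "p_value": np.nan,
                 "skipped": True, **{f"arrow_{a}": np.nan for a in axes}}
            )
            continue

        def fit_r2(yv: np.ndarray) -> tuple[float, np.ndarray]:
            b, *_ = np.linalg.lstsq(x, yv - yv.mean(), rcond=None)
            fitted = x @ b
            return float(fitted @ fitted) / float(
                (yv - yv.mean()) @ (yv - yv.mean())
            ), b

        r2, b = fit_r2(y)
        null = np.array([fit_r2(rng.permutation(y))[0] for _ in range(n_perm)])
        norm = np.linalg.norm(b)
        direction = b / norm if norm > 0 else b
        rows.append(
            {"variable": var, "r2": r2, "p_value": _perm_p(null, r2),
             "skipped": False,
             **{f"arrow_{a}": direction[i] for i, a in enumerate(axes)}}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BIOENV
# ---------------------------------------------------------------------------


@dataclass
class BioenvResult:
    best_subset: tuple[str, ...]
    best_rho: float
    ranking: pd.DataFrame  # subset, size, rho -- all non-empty subsets


def bioenv(
    d: DissimilarityMatrix, env: pd.DataFrame, max_vars: int = 20
) -> BioenvResult:
    """Exhaustive search for the environment subset whose Euclidean
    distances best Spearman-correlate with the community dissimilarities.

    Variables are z-scored internally; every non-empty subset is scored on
    the upper triangles of the two matrices.
    """
    env = env.reindex(d.ids)
    if env.isna().any().any():
        raise ValidationError("environment incomplete for samples")
    if env.shape[1] < 1:
        raise ValidationError("need at least one environmental variable")
    if env.shape[1] > max_vars:
        raise ValidationError(
            f"{env.shape[1]} variables exceed the combinatorial guard "
            f"({max_vars}); raise max_vars explicitly to proceed"
        )
    x = env.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [c for c, s in zip(env.columns, sd) if s == 0]
        raise ValidationError(f"constant environmental variables: {const}")
    z = (x - x.mean(axis=0)) / sd
    target = d.condensed()
    iu = np.triu_indices(len(d.ids), k=1)

    rows = []
    variables = list(env.columns)
    for size in range(1, len(variables) + 1):
        for subset in itertools.combinations(range(len(variables)), size):
            sub = z[:, subset]
            diff = sub[:, None, :] - sub[None, :, :]
            ed = np.sqrt((diff**2).sum(axis=2))[iu]
            if np.ptp(ed) == 0.0 or np.ptp(target) == 0.0:
                rho = np.nan  # constant distances: correlation undefined
            else:
                rho = spearmanr(ed, target).statistic
            rows.append(
                {
                    "subset": tuple(variables[i] for i in subset),
                    "size": size,
                    "rho": float(rho),
                }
            )
    ranking = pd.DataFrame(rows).sort_values(
        "rho", ascending=False, kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    best = ranking.iloc[0]
    if pd.isna(best["rho"]):
        raise ValidationError("all candidate subsets have undefined rho")
    return BioenvResult(
        best_subset=tuple(best["subset"]),
        best_rho=float(best["rho"]),
        ranking=ranking,
    )


# ---------------------------------------------------------------------------
# PCA of environment + temporal eigenvectors
# ---------------------------------------------------------------------------


def pca_axes(env_table: pd.DataFrame) -> OrdinationResult:
    """PCA on the correlation matrix of the (jointly standardized) variables.

    Boolean columns (e.g. ice cover) are encoded 0/1 before standardization.
    Loadings are variable-axis correlations (eigenvector x sqrt(eigenvalue)).
    """
    df = env_table.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(float)
    x = df.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("PCA input must be complete")
    if x.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 variables")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [c for c, s in zip(df.columns, sd) if s == 0]
        raise ValidationError(f"constant columns: {const}")
    z = (x - x.mean(axis=0)) / sd
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    # deterministic sign: largest-magnitude loading positive
    for j in range(vt.shape[0]):
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    axes = [f"PC{i + 1}" for i in range(len(eigenvalues))]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_loadings = vt.T * np.sqrt(eigenvalues)
    return OrdinationResult(
        method="pca",
        scores=pd.DataFrame(scores, index=df.index, columns=axes),
        eigenvalues=eigenvalues,
        loadings=pd.DataFrame(corr_loadings, index=df.columns, columns=axes),
    )


# ---------------------------------------------------------------------------
# dbMEM temporal eigenvectors
# ---------------------------------------------------------------------------


def dbmem(times) -> pd.DataFrame:
    """Distance-based Moran's eigenvector maps on a 1-D (temporal) gradient.

    Pairwise |delta t| in days is truncated at the largest nearest-neighbour
    gap t* (distances beyond t* replaced by 4 t*), the truncated matrix is
    double-centered and eigendecomposed, and the unit-scaled eigenvectors
    with positive eigenvalues are returned as MEM1, MEM2, ...
    """
    times = pd.Series(times)
    ids = list(times.index)
    if np.issubdtype(times.dtype, np.datetime64):
        days = (times - times.min()).dt.total_seconds().to_numpy() / 86_400.0
    else:
        days = times.to_numpy(dtype=float)
    uniq = np.unique(days)
    if len(uniq) < 3:
        raise ValidationError("need at least 3 distinct time points")
    t_star = float(np.diff(uniq).max())
    d = np.abs(days[:, None] - days[None, :])
    d = np.where(d > t_star, 4.0 * t_star, d)
    vals, vecs = principal_coordinates(d)
    keep = vals > _EIG_TOL * vals.max()
    mem = vecs[:, keep]  # unit-norm columns
    out = pd.DataFrame(
        mem, index=ids, columns=[f"MEM{i + 1}" for i in range(mem.shape[1])]
    )
    out.attrs["eigenvalues"] = vals[keep]
    out.attrs["truncation"] = t_star
    return out


# ---------------------------------------------------------------------------
# Forward-selected distance-based RDA
# ---------------------------------------------------------------------------


def normalize_unit_interval(m: DissimilarityMatrix) -> DissimilarityMatrix:
    """Global min-max rescale of the off-diagonal values to [0, 1]."""
    vals = m.condensed()
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValidationError("cannot normalize a constant matrix")
    n = len(m.ids)
    data = (m.data - lo) / (hi - lo)
    np.fill_diagonal(data, 0.0)
    return DissimilarityMatrix(data, m.ids, check_hollow=False)


def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def forward_select_dbrda(
    response: DissimilarityMatrix,
    predictors: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    loadings: pd.DataFrame | None = None,
    loading_threshold: float = 0.4,
) -> SelectionReport:
    """Forward selection of predictor axes in a distance-based RDA.

    The response matrix (e.g. betaNTI rescaled to [0, 1]) is embedded by
    principal coordinates on its positive axes; predictors are added
    greedily by adjusted-R^2 gain while each addition is permutation-
    significant at ``alpha``; selection halts once the cumulative adjusted
    R^2 reaches the full model's (double stopping; the crossing step is
    kept because it passed the permutation gate).  When a PCA loading table is supplied, each
    selected axis is flagged 'measured' if any measured variable loads
    at least ``loading_threshold`` in magnitude on it, else 'unmeasured'.
    """
    vals = response.condensed()
    if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
        raise ValidationError("response must be normalized to [0, 1]")
    predictors = predictors.reindex(response.ids)
    if predictors.isna().any().any():
        raise ValidationError("predictors incomplete for response samples")
    y, _ = _positive_coordinates(response.data)
    n = y.shape[0]
    ss_tot = float((y**2).sum())
    x_all = predictors.to_numpy(dtype=float)
    x_all = x_all - x_all.mean(axis=0)
    names = list(predictors.columns)

    def fit_ss(cols: list[int]) -> float:
        if not cols:
            return 0.0
        xs = x_all[:, cols]
        beta, *_ = np.linalg.lstsq(xs, y, rcond=None)
        fitted = xs @ beta
        return float((fitted**2).sum())

    if len(names) >= n - 1:
        raise ValidationError(
            f"{len(names)} predictors leave no residual degrees of freedom "
            f"for {n} samples; drop minor axes first"
        )
    full_r2 = fit_ss(list(range(len(names)))) / ss_tot
    full_adj = _adj_r2(full_r2, n, len(names))

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(33,)))

    # global pre-test: forward selection only proceeds when the full model
    # is itself significant; this controls the selection-bias inflation of
    # the per-step tests (picking the best of several candidates)
    p_full = len(names)

    def global_f(ym: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(x_all, ym, rcond=None)
        ss_fit = float(((x_all @ beta) ** 2).sum())
        resid = float((ym**2).sum()) - ss_fit
        return (ss_fit / p_full) / (resid / (n - p_full - 1))

    observed_global = global_f(y)
    null_global = np.array(
        [global_f(y[rng.permutation(n)]) for _ in range(n_perm)]
    )
    global_p = _perm_p(null_global, observed_global)
    if global_p > alpha:
        empty = pd.DataFrame(
            columns=["axis", "adj_r2_cum", "adj_r2_gain", "p_value"]
        )
        empty["interpretation"] = []
        return SelectionReport(
            selected=empty,
            full_model_adj_r2=full_adj,
            loadings=loadings,
            loading_threshold=loading_threshold,
        )

    current: list[int] = []
    current_adj = 0.0
    records = []
    while len(current) < len(names):
        remaining = [i for i in range(len(names)) if i not in current]
        cand_adj = []
        for i in remaining:
            r2 = fit_ss(current + [i]) / ss_tot
            cand_adj.append(_adj_r2(r2, n, len(current) + 1))
        best_idx = int(np.argmax(cand_adj))
        best_var = remaining[best_idx]
        best_adj = cand_adj[best_idx]
        if best_adj <= current_adj:
            break

        ss_cur = fit_ss(current)
        p_new = len(current) + 1

        def pseudo_f(ym: np.ndarray) -> float:
            # partial F of the candidate given the current model
            xs = x_all[:, current + [best_var]]
            beta, *_ = np.linalg.lstsq(xs, ym, rcond=None)
            ss_fit = float(((xs @ beta) ** 2).sum())
            if current:
                xc = x_all[:, current]
                bc, *_ = np.linalg.lstsq(xc, ym, rcond=None)
                ss_base = float(((xc @ bc) ** 2).sum())
            else:
                ss_base = 0.0
            resid = float((ym**2).sum()) - ss_fit
            return (ss_fit - ss_base) / (resid / (n - p_new - 1))

        observed_f = pseudo_f(y)
        null = np.array(
            [pseudo_f(y[rng.permutation(n)]) for _ in range(n_perm)]
        )
        p_value = _perm_p(null, observed_f)
        if p_value > alpha:
            break
        records.append(
            {
                "axis": names[best_var],
                "adj_r2_cum": best_adj,
                "adj_r2_gain": best_adj - current_adj,
                "p_value": p_value,
            }
        )
        current.append(best_var)
        current_adj = best_adj
        # double stopping: once the cumulative adjusted R^2 reaches the
        # full model's, further additions would only chase noise.  The
        # crossing step itself is kept -- it already passed the
        # permutation gate (a submodel's adjusted R^2 can legitimately
        # exceed the full model's, whose extra terms cost df).
        if best_adj >= full_adj - 1e-12:
            break

    selected = pd.DataFrame(
        records, columns=["axis", "adj_r2_cum", "adj_r2_gain", "p_value"]
    )
    interps = []
    for axis in selected["axis"]:
        if loadings is None or axis not in loadings.columns:
            interps.append("unknown")
        elif (loadings[axis].abs() >= loading_threshold).any():
            interps.append("measured")
        else:
            interps.append("unmeasured")
    selected["interpretation"] = interps
    return SelectionReport(
        selected=selected,
        full_model_adj_r2=full_adj,
        loadings=loadings,
        loading_threshold=loading_threshold,
    )
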