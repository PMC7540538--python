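import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from lakeassembly import ValidationError
from lakeassembly.matrices import DissimilarityMatrix
from lakeassembly.multivariate import (
    OrdinationResult,
    anosim,
    bioenv,
    dbmem,
    envfit,
    forward_select_dbrda,
    nmds,
    normalize_unit_interval,
    pca_axes,
    permdisp,
    principal_coordinates,
)


def euclid_dm(points, ids=None):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DissimilarityMatrix(d, ids)


class TestNMDS:
    def test_exactly_embeddable_distances_reach_near_zero_stress(self):
        points = np.arange(8, dtype=float)[:, None]  # points on a line
        res = nmds(euclid_dm(points), k=2, n_starts=8, seed=0)
        assert res.stress < 0.01
        assert res.scores.shape == (8, 2)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_best_of_starts_not_worse_than_pcoa_start_alone(self):
        rng = np.random.default_rng(4)
        d = euclid_dm(rng.normal(size=(8, 5)))
        multi = nmds(d, k=2, n_starts=20, seed=1, include_pcoa_start=True)
        single = nmds(d, k=2, n_starts=0, seed=1, include_pcoa_start=True)
        assert multi.stress <= single.stress + 1e-12

    def test_k_must_be_below_sample_count(self):
        d = euclid_dm(np.eye(3))
        with pytest.raises(ValidationError):
            nmds(d, k=3)


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        points = [[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]]
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"s{i}" for i in range(6)])
        res = anosim(euclid_dm(points), groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value >= 1 / 100

    def test_hand_ranked_four_sample_example(self):
        # distances: within = {1, 2}, between = {5, 6, 7, 8}
        d = np.array(
            [
                [0, 1, 5, 6],
                [1, 0, 7, 8],
                [5, 7, 0, 2],
                [6, 8, 2, 0],
            ],
            dtype=float,
        )
        dm = DissimilarityMatrix(d, list("wxyz"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("wxyz"))
        # ranks: within (1, 2) -> mean 1.5; between (3,4,5,6) -> mean 4.5
        # R = (4.5 - 1.5) / (4*3/4) = 1.0
        res = anosim(dm, groups, n_perm=23, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_skbio_statistic(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(8)
        d = euclid_dm(rng.normal(size=(9, 4)))
        groups = pd.Series(
            ["a", "a", "a", "b", "b", "b", "c", "c", "c"], index=d.ids
        )
        ours = anosim(d, groups, n_perm=99, seed=0)
        theirs = skbio_anosim(
            SkbioDM(d.data, ids=d.ids), groups.to_numpy(), permutations=0
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"])

    def test_singleton_group_rejected(self):
        d = euclid_dm(np.eye(3))
        groups = pd.Series(["a", "a", "b"], index=d.ids)
        with pytest.raises(ValidationError, match="singleton"):
            anosim(d, groups)


class TestPermdisp:
    def test_mirror_groups_have_equal_dispersion(self):
        pts = np.array([[1.0, 0], [2, 1], [3, -1], [-1, 0], [-2, 1], [-3, -1]])
        groups = pd.Series(["r"] * 3 + ["l"] * 3, index=[f"s{i}" for i in range(6)])
        res = permdisp(euclid_dm(pts), groups, n_perm=99, seed=0)
        means = res.extras["group_mean_distance"]
        assert means["r"] == pytest.approx(means["l"])

    def test_scaled_group_is_more_dispersed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 2))
        pts = np.vstack([base, 3.0 * base + 10.0])
        groups = pd.Series(["tight"] * 6 + ["wide"] * 6,
                           index=[f"s{i}" for i in range(12)])
        res = permdisp(euclid_dm(pts), groups, n_perm=99, seed=0)
        means = res.extras["group_mean_distance"]
        assert means["wide"] > means["tight"]

    def test_euclidean_toy_matches_direct_geometry(self):
        pts = np.array([[0.0, 0], [2, 0], [0, 2], [10, 10], [14, 10], [10, 14]])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"s{i}" for i in range(6)])
        res = permdisp(euclid_dm(pts), groups, n_perm=49, seed=0)
        dist = res.extras["sample_distances"]
        for lab, sub in zip(["a", "b"], [pts[:3], pts[3:]]):
            centroid = sub.mean(axis=0)
            expected = np.linalg.norm(sub - centroid, axis=1)
            got = dist[groups[groups == lab].index].to_numpy()
            np.testing.assert_allclose(got, expected, atol=1e-9)


class TestEnvfit:
    @staticmethod
    def _ordination(scores):
        df = pd.DataFrame(scores, columns=["A1", "A2"],
                          index=[f"s{i}" for i in range(len(scores))])
        return OrdinationResult(method="test", scores=df)

    def test_variable_equal_to_axis_one(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(12, 2))
        ordi = self._ordination(scores)
        env = pd.DataFrame({"v": scores[:, 0]}, index=ordi.scores.index)
        res = envfit(ordi, env, n_perm=99, seed=0)
        assert res.loc[0, "r2"] == pytest.approx(1.0)
        arrow = res.loc[0, ["arrow_A1", "arrow_A2"]].to_numpy(dtype=float)
        np.testing.assert_allclose(np.abs(arrow), [1.0, 0.0], atol=1e-8)

    def test_diagonal_variable_points_at_45_degrees(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(12, 2))
        scores -= scores.mean(axis=0)
        # orthogonalize and equalize the axes so the projection is exact
        q, _ = np.linalg.qr(scores)
        scores = q
        ordi = self._ordination(scores)
        env = pd.DataFrame({"v": scores[:, 0] + scores[:, 1]},
                           index=ordi.scores.index)
        res = envfit(ordi, env, n_perm=9, seed=0)
        arrow = res.loc[0, ["arrow_A1", "arrow_A2"]].to_numpy(dtype=float)
        np.testing.assert_allclose(np.abs(arrow), [2**-0.5, 2**-0.5], atol=1e-8)

    def test_constant_variable_is_flagged(self):
        rng = np.random.default_rng(3)
        ordi = self._ordination(rng.normal(size=(8, 2)))
        env = pd.DataFrame({"flat": np.ones(8)}, index=ordi.scores.index)
        res = envfit(ordi, env, n_perm=9, seed=0)
        assert bool(res.loc[0, "skipped"])


class TestBioenv:
    def test_monotone_transform_recovers_single_variable(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=10)
        d = euclid_dm(v[:, None])
        env = pd.DataFrame(
            {"v": v, "noise": rng.normal(size=10)}, index=d.ids
        )
        res = bioenv(d, env)
        assert res.best_subset == ("v",)
        assert res.best_rho == pytest.approx(1.0)

    def test_best_subset_dominates_singletons(self):
        rng = np.random.default_rng(6)
        d = euclid_dm(rng.normal(size=(10, 3)))
        env = pd.DataFrame(rng.normal(size=(10, 4)),
                           columns=list("abcd"), index=d.ids)
        res = bioenv(d, env)
        singles = res.ranking[res.ranking["size"] == 1]["rho"]
        assert res.best_rho >= singles.max() - 1e-12

    def test_matches_independent_exhaustive_search(self):
        rng = np.random.default_rng(7)
        d = euclid_dm(rng.normal(size=(9, 3)))
        env = pd.DataFrame(rng.normal(size=(9, 4)),
                           columns=list("wxyz"), index=d.ids)
        res = bioenv(d, env)
        # independent re-search with its own standardization and looping
        z = (env - env.mean()) / env.std(ddof=1)
        target = d.condensed()
        expected = {}
        for r in range(1, 5):
            for subset in itertools.combinations(env.columns, r):
                ed = pdist(z[list(subset)].to_numpy())
                expected[subset] = spearmanr(ed, target).statistic
        ours = {tuple(s): r for s, r in zip(res.ranking["subset"], res.ranking["rho"])}
        for subset, rho in expected.items():
            assert ours[subset] == pytest.approx(rho, abs=1e-12)
        assert res.best_subset == max(expected, key=expected.get)

    def test_combinatorial_guard(self):
        rng = np.random.default_rng(8)
        d = euclid_dm(rng.normal(size=(6, 2)))
        env = pd.DataFrame(rng.normal(size=(6, 4)), index=d.ids)
        with pytest.raises(ValidationError, match="guard"):
            bioenv(d, env, max_vars=3)


class TestPCA:
    def test_eigenvalue_sum_equals_variable_count(self):
        rng = np.random.default_rng(9)
        env = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        res = pca_axes(env)
        assert res.eigenvalues.sum() == pytest.approx(5.0)

    def test_perfectly_correlated_pair_gives_eigenvalue_two(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=15)
        env = pd.DataFrame({"x": x, "y": 3 * x + 1})
        res = pca_axes(env)
        assert res.eigenvalues[0] == pytest.approx(2.0)

    def test_eigenvalues_match_analytic_decomposition(self):
        rng = np.random.default_rng(11)
        env = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        res = pca_axes(env)
        corr = np.corrcoef((env - env.mean()).T / env.std(ddof=1).to_numpy()[:, None])
        expected = np.sort(np.linalg.eigvalsh(np.corrcoef(env.T)))[::-1]
        np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-10)

    def test_constant_column_named_in_error(self):
        env = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValidationError, match="flat"):
            pca_axes(env)


class TestDbmem:
    def test_eigenvectors_orthogonal_and_centered(self):
        dates = pd.Series(pd.date_range("2015-01-01", periods=12, freq="30D"))
        mem = dbmem(dates)
        m = mem.to_numpy()
        np.testing.assert_allclose(m.mean(axis=0), 0.0, atol=1e-10)
        gram = m.T @ m
        np.testing.assert_allclose(gram, np.eye(m.shape[1]), atol=1e-9)
        assert (mem.attrs["eigenvalues"] > 0).all()

    def test_regular_transect_gives_sinusoidal_eigenvectors(self):
        times = pd.Series(np.arange(24) * 30.0)
        mem = dbmem(times)
        t = np.arange(24)
        for j in (0, 1):
            vec = mem.iloc[:, j].to_numpy()
            best = max(
                abs(np.corrcoef(vec, np.sin(np.pi * (k + 1) * (t + 0.5) / 24))[0, 1])
                for k in range(4)
            )
            assert best > 0.95

    def test_two_time_blocks_split_on_first_eigenvector(self):
        times = pd.Series([0.0, 1, 2, 3, 1000, 1001, 1002, 1003])
        mem = dbmem(times)
        v1 = mem.iloc[:, 0].to_numpy()
        assert len(set(np.sign(v1[:4]))) == 1
        assert len(set(np.sign(v1[4:]))) == 1
        assert np.sign(v1[0]) != np.sign(v1[-1])

    def test_needs_three_distinct_times(self):
        with pytest.raises(ValidationError):
            dbmem(pd.Series([1.0, 1.0, 2.0]))


class TestForwardDbrda:
    @staticmethod
    def _response_from_axis(axis_values, noise, rng):
        vals = axis_values + noise * rng.normal(size=len(axis_values))
        d = np.abs(vals[:, None] - vals[None, :])
        d = d / d.max()
        ids = [f"s{i}" for i in range(len(vals))]
        return DissimilarityMatrix(d, ids)

    def test_generating_axis_selected_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            predictors = pd.DataFrame(
                rng.normal(size=(20, 4)), columns=["A", "B", "C", "D"],
                index=[f"s{i}" for i in range(20)],
            )
            response = self._response_from_axis(
                predictors["A"].to_numpy(), 0.3, rng
            )
            rep = forward_select_dbrda(response, predictors, 0.05, 199, seed)
            if len(rep.selected) and rep.selected.iloc[0]["axis"] == "A":
                hits += 1
        assert hits >= 18

    def test_selection_halts_at_full_model_adjusted_r2(self):
        # double stopping: every selected step except possibly the last
        # stays below the full-model adjusted R2, and selection never
        # continues after crossing it
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            predictors = pd.DataFrame(
                rng.normal(size=(15, 5)),
                index=[f"s{i}" for i in range(15)],
                columns=list("abcde"),
            )
            response = self._response_from_axis(
                predictors["a"].to_numpy() + predictors["b"].to_numpy(), 0.5, rng
            )
            rep = forward_select_dbrda(response, predictors, 0.2, 99, seed)
            crossed = rep.selected["adj_r2_cum"] >= rep.full_model_adj_r2 - 1e-12
            if crossed.any():
                assert crossed.idxmax() == len(rep.selected) - 1

    def test_unnormalized_response_rejected(self):
        rng = np.random.default_rng(0)
        d = np.abs(rng.normal(size=(6, 6)))
        d = (d + d.T) * 2.0
        np.fill_diagonal(d, 0.0)
        dm = DissimilarityMatrix(d, [f"s{i}" for i in range(6)])
        predictors = pd.DataFrame(rng.normal(size=(6, 2)), index=dm.ids)
        with pytest.raises(ValidationError, match="normalized"):
            forward_select_dbrda(dm, predictors)

    def test_measured_flag_uses_loadings(self):
        rng = np.random.default_rng(3)
        predictors = pd.DataFrame(
            rng.normal(size=(18, 2)), columns=["PC1", "PC2"],
            index=[f"s{i}" for i in range(18)],
        )
        response = self._response_from_axis(predictors["PC1"].to_numpy(), 0.2, rng)
        loadings = pd.DataFrame(
            {"PC1": [0.9, 0.1], "PC2": [0.1, 0.2]}, index=["temp", "pH"]
        )
        rep = forward_select_dbrda(
            response, predictors, 0.05, 99, 0, loadings=loadings
        )
        sel = rep.selected.set_index("axis")["interpretation"]
        if "PC1" in sel.index:
            assert sel["PC1"] == "measured"
        if "PC2" in sel.index:
            assert sel["PC2"] == "unmeasured"


class TestNormalizeAndPcoa:
    def test_normalize_unit_interval(self):
        d = np.array([[0, 2.0, -1.0], [2.0, 0, 5.0], [-1.0, 5.0, 0]])
        dm = DissimilarityMatrix(d, list("abc"), check_hollow=False)
        norm = normalize_unit_interval(dm)
        vals = norm.condensed()
        assert vals.min() == pytest.approx(0.0)
        assert vals.max() == pytest.approx(1.0)

    def test_pcoa_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(7, 3))
        vals, vecs = principal_coordinates(squareform(pdist(pts)))
        keep = vals > 1e-9
        coords = vecs[:, keep] * np.sqrt(vals[keep])
        d_rec = squareform(pdist(coords))
        np.testing.assert_allclose(d_rec, squareform(pdist(pts)), atol=1e-8)

    def test_p_values_reproducible_and_bounded(self):
        rng = np.random.default_rng(13)
        d = euclid_dm(rng.normal(size=(8, 3)))
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=d.ids)
        r1 = anosim(d, groups, n_perm=49, seed=5)
        r2 = anosim(d, groups, n_perm=49, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 50
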