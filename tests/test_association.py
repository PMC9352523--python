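import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pneumobiome import association as assoc
from pneumobiome.diversity import DistanceMatrix, gower_center
from pneumobiome.dmm import ClusterAssignment
from pneumobiome.io_formats import (CountTable, ResponsePanel, SampleMetadata,
                                    ValidationError)


def _euclid_dm(points, ids=None):
    points = np.atleast_2d(points)
    if points.shape[0] == 1:
        points = points.T
    ids = ids or [f"s{i}" for i in range(points.shape[0])]
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    return DistanceMatrix(ids, d)


def _panel(values: np.ndarray, ids=None):
    values = np.asarray(values, dtype=float)
    if np.nanmin(values) < 0:  # assay values are non-negative; shift preserves
        values = values - np.nanmin(values)  # distances, ranks and R^2
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    cols = [f"a{j}" for j in range(values.shape[1])]
    analytes = pd.DataFrame({"stimulus": "LPS", "cell_type": "monocyte"},
                            index=cols)
    return ResponsePanel(pd.DataFrame(values, index=ids, columns=cols), analytes)


class TestPermanova:
    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.0
        d = _euclid_dm(pts)
        meta = pd.DataFrame({"grp": ["x"] * 3 + ["y"] * 3}, index=d.sample_ids)
        res = assoc.permanova(d, meta, ["grp"], exhaustive=True)

        g = gower_center(d.d)
        ones = np.ones((6, 6)) / 6

        def pseudo_f(indicator):
            x = np.column_stack([np.ones(6), indicator])
            q, _ = np.linalg.qr(x)
            h = q @ q.T
            ss = np.trace((h - ones) @ g)
            ss_res = np.trace((np.eye(6) - h) @ g)
            return ss / (ss_res / 4)

        f_obs = pseudo_f(np.array([0, 0, 0, 1, 1, 1.0]))
        f_all = [pseudo_f(np.isin(np.arange(6), c).astype(float))
                 for c in itertools.combinations(range(6), 3)]
        exact_p = np.mean([f >= f_obs - 1e-12 for f in f_all])
        assert res.p_value("grp") == pytest.approx(exact_p, abs=1e-12)

    def test_separated_centroids_high_r2_min_p(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 2))
        pts = np.vstack([base, base + 50.0])
        d = _euclid_dm(pts)
        meta = pd.DataFrame({"grp": ["x"] * 10 + ["y"] * 10}, index=d.sample_ids)
        res = assoc.permanova(d, meta, ["grp"], n_perm=199, seed=1)
        assert res.r_squared("grp") > 0.5
        assert res.p_value("grp") == pytest.approx(1 / 200)

    def test_sequential_r2_sums_to_one(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 3))
        d = _euclid_dm(pts)
        meta = pd.DataFrame({
            "grp": rng.choice(["x", "y"], 30),
            "age": rng.normal(70, 10, 30),
            "sex": rng.choice(["male", "female"], 30),
        }, index=d.sample_ids)
        res = assoc.permanova(d, meta, ["grp", "age", "sex"], n_perm=49, seed=0)
        assert res.table["r2"].drop("Total").sum() == pytest.approx(1.0,
                                                                    abs=1e-10)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            pts = rng.normal(size=(20, 2))
            d = _euclid_dm(pts)
            meta = pd.DataFrame({"grp": rng.permutation(["x"] * 10 + ["y"] * 10)},
                                index=d.sample_ids)
            res = assoc.permanova(d, meta, ["grp"], n_perm=199,
                                  seed=int(rng.integers(2**31 - 1)))
            rejections += res.p_value("grp") <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_constant_term_rejected(self):
        d = _euclid_dm(np.arange(5.0))
        meta = pd.DataFrame({"grp": ["x"] * 5}, index=d.sample_ids)
        with pytest.raises(ValidationError, match="grp"):
            assoc.permanova(d, meta, ["grp"], n_perm=19)

    def test_marginal_mode_runs(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(24, 2))
        pts[:12] += 2.0
        d = _euclid_dm(pts)
        meta = pd.DataFrame({"grp": ["x"] * 12 + ["y"] * 12,
                             "age": rng.normal(70, 10, 24)}, index=d.sample_ids)
        res = assoc.permanova(d, meta, ["grp", "age"], n_perm=99, seed=0,
                              mode="marginal")
        assert res.p_value("grp") < 0.05


class TestVariancePartition:
    def test_construction_signal_ranks_first(self, default_cohort):
        from pneumobiome.diversity import unifrac
        table = default_cohort.counts["admission"]
        dmat = unifrac(table, default_cohort.tree)
        meta = default_cohort.metadata.data.loc[table.sample_ids].copy()
        meta["component"] = default_cohort.ground_truth.components[
            table.sample_ids]
        part = assoc.variance_partition(dmat, meta,
                                        ["component", "age", "sex"],
                                        n_perm=99, seed=0)
        assert part.iloc[0]["covariate"] == "component"
        assert part.iloc[0]["p"] == pytest.approx(1 / 100)

    def test_null_covariate_r2_near_expectation(self):
        rng = np.random.default_rng(1)
        r2s = []
        for _ in range(50):
            pts = rng.normal(size=(30, 3))
            d = _euclid_dm(pts)
            meta = pd.DataFrame({"x": rng.normal(size=30)}, index=d.sample_ids)
            part = assoc.variance_partition(d, meta, ["x"], n_perm=19,
                                            seed=int(rng.integers(2**31)))
            r2s.append(part["r2"].iloc[0])
        assert np.mean(r2s) == pytest.approx(1 / 29, rel=0.4)


class TestCytokineVarianceExplained:
    def test_constant_analyte_flagged_zero(self):
        rng = np.random.default_rng(0)
        d = _euclid_dm(rng.normal(size=(20, 4)))
        values = np.column_stack([np.full(20, 7.0), rng.normal(5, 1, 20)])
        res = assoc.cytokine_variance_explained(d, _panel(values), n_perm=99,
                                                seed=0)
        assert res.table.loc["a0", "explained_pct"] == 0.0
        assert bool(res.table.loc["a0", "flagged"])

    def test_exact_affine_analyte_fully_explained(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 4))
        d = _euclid_dm(pts)
        from pneumobiome.diversity import pcoa
        axes = pcoa(d, 4).coordinates
        values = (3.0 + 2.0 * axes[:, 0])[:, None]
        res = assoc.cytokine_variance_explained(d, _panel(values), n_perm=199,
                                                seed=0)
        assert res.table["explained_pct"].iloc[0] >= 99.0

    def test_alpha_one_gives_full_r2_sum_and_monotonicity(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 4))
        d = _euclid_dm(pts)
        values = rng.normal(10, 2, size=(30, 3))
        full = assoc.cytokine_variance_explained(d, _panel(values), alpha=1.0,
                                                 n_perm=99, seed=3)
        strict = assoc.cytokine_variance_explained(d, _panel(values), alpha=0.2,
                                                   n_perm=99, seed=3)
        by_analyte = full.axis_detail.groupby("analyte")["r2"].sum() * 100
        for analyte in full.table.index:
            assert full.table.loc[analyte, "explained_pct"] == pytest.approx(
                by_analyte[analyte])
            assert strict.table.loc[analyte, "explained_pct"] <= \
                full.table.loc[analyte, "explained_pct"] + 1e-12

    def test_permanova_r2_equals_ols_r2_for_1d_response(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(25, 4))
        d = _euclid_dm(pts)
        y = pts[:, 0] + rng.normal(0, 1, 25)
        res = assoc.cytokine_variance_explained(d, _panel(y[:, None]),
                                                alpha=1.0, n_perm=49, seed=0)
        from pneumobiome.diversity import pcoa
        axes = pcoa(d, 4).coordinates
        x = np.column_stack([np.ones(25), axes])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        ols_r2 = 1 - ((y - x @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert res.table["explained_pct"].iloc[0] / 100 == pytest.approx(
            ols_r2, abs=1e-8)


class TestCompareExplained:
    def _result(self, values):
        table = pd.DataFrame({"explained_pct": values,
                              "flagged": False},
                             index=[f"a{i}" for i in range(len(values))])
        return assoc.VarianceExplainedResult(table, pd.DataFrame(), 4, 0.2, 99)

    def test_identical_distributions_p_one(self):
        a = self._result([0.0, 1.0, 2.0, 5.0])
        assert assoc.compare_explained(a, a)["p"] == 1.0

    def test_shifted_alternative_detected(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 5, 30)
        a = self._result(base)
        b = self._result(base + 10)
        out = assoc.compare_explained(a, b)
        assert out["p"] < 0.01
        assert out["median_b"] == pytest.approx(np.median(base + 10))

    def test_medians_and_iqr_definition(self):
        vals = [1.0, 2.0, 3.0, 10.0]
        a = self._result(vals)
        out = assoc.compare_explained(a, self._result([0, 0, 1, 1.0]))
        assert out["median_a"] == np.median(vals)
        assert out["iqr_a"] == (np.quantile(vals, 0.25), np.quantile(vals, 0.75))


class TestGroupComparisons:
    def _assignment(self, ids, labels):
        return ClusterAssignment(list(ids), np.asarray(labels),
                                 np.ones(len(labels)))

    def test_exact_small_sample_p(self):
        # (1,2,3) vs (10,20,30): fully separated ranks, two-sided exact
        # rank-sum p = 2/C(6,3) = 0.1
        panel = _panel(np.array([1, 2, 3, 10, 20, 30.0])[:, None])
        assign = self._assignment(panel.sample_ids, [1, 1, 1, 2, 2, 2])
        res = assoc.wilcoxon_group_compare(panel, assign)
        assert res.table["p"].iloc[0] == pytest.approx(0.1)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(1, 5, 30)
        assign = self._assignment([f"s{i}" for i in range(30)],
                                  rng.integers(1, 3, 30))
        p1 = assoc.wilcoxon_group_compare(_panel(y[:, None]), assign)
        p2 = assoc.wilcoxon_group_compare(_panel(np.exp(y)[:, None]), assign)
        assert p1.table["p"].iloc[0] == pytest.approx(p2.table["p"].iloc[0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 500
        labels = np.array([1] * 15 + [2] * 15)
        ids = [f"s{i}" for i in range(30)]
        for _ in range(n_rep):
            panel = _panel(rng.normal(size=(30, 1)), ids=ids)
            res = assoc.wilcoxon_group_compare(
                panel, self._assignment(ids, rng.permutation(labels)))
            rejections += res.table["p"].iloc[0] <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_adjusted_collapses_to_anova_when_covariates_constant(
            self, small_metadata):
        rng = np.random.default_rng(3)
        n = 20
        ids = [f"s{i}" for i in range(n)]
        meta = pd.concat([small_metadata.data.iloc[[0]]] * n)
        meta.index = ids
        meta["age"] = 70.0
        panel = _panel(rng.normal(10, 2, size=(n, 1)), ids=ids)
        assign = self._assignment(ids, [1] * 10 + [2] * 10)
        res = assoc.adjusted_group_compare(panel, assign, SampleMetadata(meta),
                                           covariates=("age",), transform=None)
        y = panel.values.iloc[:, 0].to_numpy()
        f, p = stats.f_oneway(y[:10], y[10:])
        assert res.table["p_adjusted"].iloc[0] == pytest.approx(p)

    def test_cluster_effect_detected_with_age_confounder(self):
        rng = np.random.default_rng(4)
        detected = 0
        n_rep = 50
        for _ in range(n_rep):
            n = 100
            ids = [f"s{i}" for i in range(n)]
            labels = np.array([1] * 50 + [2] * 50)
            age = rng.normal(70, 8, n)
            y = 2.0 * (labels == 2) + 0.1 * age + rng.normal(0, 1, n)
            meta = pd.DataFrame({
                "group": "CAP", "timepoint": "admission", "age": age,
                "sex": rng.choice(["male", "female"], n),
                **{c: False for c in ("copd", "cardiovascular", "diabetes",
                                      "malignancy", "immunosuppressed",
                                      "gastrointestinal", "renal")},
                "prior_antibiotics": False}, index=ids)
            res = assoc.adjusted_group_compare(
                _panel(y[:, None] + 20, ids=ids),
                self._assignment(ids, labels), SampleMetadata(meta),
                covariates=("age", "sex"), transform=None)
            detected += res.table["p_adjusted"].iloc[0] < 0.01
        assert detected >= 0.9 * n_rep


class TestButyrateScore:
    def test_pure_reference_sample_scores_one(self):
        table = CountTable(["s1"], ["Roseburia", "Faecalibacterium"],
                           np.array([[60, 40]]))
        score = assoc.butyrate_score(table, ["Roseburia", "Faecalibacterium"])
        assert score.scores.iloc[0] == pytest.approx(1.0)

    def test_no_reference_genus_scores_zero(self):
        table = CountTable(["s1"], ["Finegoldia", "Anaerococcus"],
                           np.array([[60, 40]]))
        score = assoc.butyrate_score(table, ["Roseburia"])
        assert score.scores.iloc[0] == 0.0

    def test_twenty_eighty_split(self):
        table = CountTable(["s1"], ["Roseburia", "Finegoldia"],
                           np.array([[20, 80]]))
        score = assoc.butyrate_score(table, ["Roseburia"])
        assert score.scores.iloc[0] == pytest.approx(0.2)

    def test_depth_invariance(self):
        t1 = CountTable(["s1"], ["Roseburia", "Finegoldia"], np.array([[3, 7]]))
        t2 = CountTable(["s1"], ["Roseburia", "Finegoldia"],
                        np.array([[300, 700]]))
        ref = ["Roseburia"]
        assert assoc.butyrate_score(t1, ref).scores.iloc[0] == \
            assoc.butyrate_score(t2, ref).scores.iloc[0]

    def test_empty_reference_rejected(self):
        table = CountTable(["s1"], ["a", "b"], np.array([[1, 1]]))
        with pytest.raises(ValidationError):
            assoc.butyrate_score(table, [])


class TestSpearman:
    def _score(self, values):
        return pd.Series(values, index=[f"s{i}" for i in range(len(values))])

    @pytest.mark.parametrize("y,rho", [
        ([1, 2, 3, 4, 5], 1.0),
        ([5, 4, 3, 2, 1], -1.0),
        ([1, 3, 2, 5, 4], 0.8),  # sum d^2 = 2 -> 1 - 12/120
    ])
    def test_hand_rank_values(self, y, rho):
        score = self._score([1, 2, 3, 4, 5.0])
        res = assoc.spearman_association(score, _panel(np.array(y, float)[:, None]))
        assert res["rho"].iloc[0] == pytest.approx(rho)

    def test_exact_p_matches_enumeration_for_monotone_pair(self):
        # perfectly increasing n=5: only 2 of 120 orderings reach |rho| = 1
        score = self._score([1, 2, 3, 4, 5.0])
        res = assoc.spearman_association(score,
                                         _panel(np.arange(5.0)[:, None]))
        assert res["p"].iloc[0] == pytest.approx(2 / 120)

    def test_constant_vector_flagged(self):
        score = self._score([1, 2, 3, 4, 5.0])
        res = assoc.spearman_association(score, _panel(np.full((5, 1), 3.0)))
        assert np.isnan(res["rho"].iloc[0]) and bool(res["flagged"].iloc[0])

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 1, 40)
        res = assoc.spearman_association(self._score(x), _panel(y[:, None]))
        ref = stats.spearmanr(x, y)
        assert res["rho"].iloc[0] == pytest.approx(ref.statistic)
        assert res["p"].iloc[0] == pytest.approx(ref.pvalue)
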