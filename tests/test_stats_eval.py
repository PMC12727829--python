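import itertools

import numpy as np
import pandas as pd
import pytest

from silis import stats_eval as se
from silis import normalize_qc as nq
from silis import simulate


class TestKendallTrend:
    def test_perfect_concordance_and_reversal(self):
        tau, p = se.kendall_trend([1, 2, 3, 4], [1, 2, 3, 4])
        assert tau == pytest.approx(1.0)
        tau, _ = se.kendall_trend([4, 3, 2, 1], [1, 2, 3, 4])
        assert tau == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_tau_b_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        v = rng.integers(1, 4, n).astype(float)
        g = rng.integers(1, 3, n).astype(float)
        if np.unique(v).size < 2 or np.unique(g).size < 2:
            return
        conc = disc = tx = ty = 0
        for i, j in itertools.combinations(range(n), 2):
            dv, dg = v[i] - v[j], g[i] - g[j]
            if dv * dg > 0:
                conc += 1
            elif dv * dg < 0:
                disc += 1
            elif dg == 0 and dv != 0:
                tx += 1
            elif dv == 0 and dg != 0:
                ty += 1
        n0 = n * (n - 1) / 2
        denom = np.sqrt((n0 - tx - _tie_pairs(g)) * (n0 - ty - _tie_pairs(v)))
        tau, _ = se.kendall_trend(v, g)
        expected = (conc - disc) / np.sqrt(
            (n0 - _tie_pairs(g)) * (n0 - _tie_pairs(v)))
        assert tau == pytest.approx(expected)

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError):
            se.kendall_trend([1, 2], [1, 2])


def _tie_pairs(x):
    _, counts = np.unique(x, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert se.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_step_up_with_cumulative_minimum(self):
        np.testing.assert_allclose(
            se.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            se.bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_step_up_and_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.001, 1, size=int(rng.integers(1, 7)))
        m = len(p)
        order = np.argsort(p)
        # brute-force step-up: adjusted = min over j >= i of p_(j) * m / j
        expected = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            running = min(running, p[order[rank_idx]] * m / (rank_idx + 1))
            expected[order[rank_idx]] = running
        np.testing.assert_allclose(se.bh_adjust(p), expected)
        assert (se.bh_adjust(p) >= p - 1e-15).all()
        perm = rng.permutation(m)
        np.testing.assert_allclose(se.bh_adjust(p[perm]), expected[perm])


class TestPairedWilcoxon:
    def test_identical_samples_undefined(self):
        assert np.isnan(se.paired_wilcoxon([1, 2, 3], [1, 2, 3]))

    def test_six_positive_differences_exact_p(self):
        a = [2, 3, 4, 5, 6, 7]
        b = [1, 1, 1, 1, 1, 1]
        assert se.paired_wilcoxon(a, b) == pytest.approx(2 / 2**6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sign_assignment_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        d = rng.uniform(0.1, 5, n) * rng.choice([-1, 1], n)
        # oracle: exact two-sided p by enumerating all sign assignments
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        stat_obs = min(w_obs, total - w_obs)
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            w = sum(r for s, r in zip(signs, ranks) if s)
            if min(w, total - w) <= stat_obs:
                count += 1
        expected = min(count / 2**n, 1.0)
        assert se.paired_wilcoxon(d, np.zeros(n)) == pytest.approx(expected)


class TestIcc:
    def test_identical_columns_give_one(self):
        m = np.column_stack([np.arange(5.0)] * 3)
        assert se.icc(m, "ICC3k") == pytest.approx(1.0)
        assert se.icc(m, "ICC21") == pytest.approx(1.0)

    def test_toy_matrix_matches_anova_mean_squares(self):
        m = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 2.0], [6.0, 7.0]])
        n, k = m.shape
        grand = m.mean()
        ms_rows = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        ms_cols = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        ss_err = (((m - m.mean(1, keepdims=True)
                    - m.mean(0, keepdims=True) + grand)) ** 2).sum()
        ms_err = ss_err / ((n - 1) * (k - 1))
        assert se.icc(m, "ICC3k") == pytest.approx((ms_rows - ms_err) / ms_rows)
        expected21 = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
        assert se.icc(m, "ICC21") == pytest.approx(expected21)

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        m = rng.normal(size=(8, 3)) + np.arange(8)[:, None]
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(8), 3),
            "raters": np.tile(np.arange(3), 8),
            "scores": m.ravel(),
        })
        tab = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="scores").set_index("Type")
        # ICC(C,k): two-way mixed, consistency, average of k raters
        assert se.icc(m, "ICC3k") == pytest.approx(tab.loc["ICC(C,k)", "ICC"])
        # ICC(A,1): two-way random, absolute agreement, single rater
        assert se.icc(m, "ICC21") == pytest.approx(tab.loc["ICC(A,1)", "ICC"])

    def test_independent_noise_columns_near_zero(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(600, 3))
        assert abs(se.icc(m, "ICC3k")) < 0.25
        assert abs(se.icc(m, "ICC21")) < 0.1

    def test_rows_with_missing_removed_listwise(self):
        m = np.array([[1.0, 2.0], [np.nan, 5.0], [2.0, 2.0], [6.0, 7.0]])
        complete = m[[0, 2, 3]]
        assert se.icc(m, "ICC3k") == pytest.approx(se.icc(complete, "ICC3k"))


class TestKnnImpute:
    def test_complete_matrix_unchanged(self):
        m = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        pd.testing.assert_frame_equal(se.knn_impute(m, k=2), m)

    def test_missing_among_identical_samples_gets_shared_value(self):
        # samples (columns) are the observations: identical samples make
        # the imputed entry the shared per-peptide constant
        m = pd.DataFrame(np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 4)))
        m.iloc[2, 1] = np.nan
        out = se.knn_impute(m, k=3)
        assert out.iloc[2, 1] == pytest.approx(3.0)

    def test_small_case_matches_neighbor_averaging(self):
        # samples (columns) 0/1 identical, 2/3 identical but far away
        m = pd.DataFrame({
            "s0": [1.0, 1.0, 1.0], "s1": [1.0, 1.0, np.nan],
            "s2": [10.0, 10.0, 10.0], "s3": [10.0, 10.0, 10.0],
        })
        out = se.knn_impute(m, k=1)
        assert out["s1"].iloc[2] == pytest.approx(1.0)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            se.knn_impute(pd.DataFrame([[1.0]]), k=0)


class TestVariancePartition:
    def _design(self, platforms, severities):
        cols = pd.MultiIndex.from_product([platforms, severities],
                                          names=["platform", "severity"])
        design = pd.DataFrame(
            [{"platform": p, "severity": s} for p, s in cols], index=cols)
        return cols, design

    def test_pure_platform_offsets_attributed_to_platform(self):
        cols, design = self._design(list("ABC"), ["h", "m", "s", "c"])
        offsets = {"A": 0.0, "B": 5.0, "C": 10.0}
        rng = np.random.default_rng(0)
        vals = [offsets[p] + rng.normal(0, 0.01) for p, _ in cols]
        mat = pd.DataFrame([vals], index=["pep1"], columns=cols)
        out = se.variance_partition(mat, design)
        assert out.loc["pep1", "frac_platform"] > 0.9

    def test_pure_noise_attributed_to_residual(self):
        cols, design = self._design(list("AB"), [f"g{i}" for i in range(10)])
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(3, len(cols))),
                           index=["p1", "p2", "p3"], columns=cols)
        out = se.variance_partition(mat, design)
        assert (out["frac_residual"] > 0.5).all()

    def test_fractions_sum_to_one(self):
        cols, design = self._design(list("AB"), ["h", "m"])
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(4, len(cols))), columns=cols)
        out = se.variance_partition(mat, design)
        sums = out[["frac_platform", "frac_severity", "frac_residual"]].sum(1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestBlandAltman:
    def test_self_agreement_is_exactly_zero_bias(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = se.bland_altman(x, x)
        assert res.bias == 0.0 and res.sd_diff == 0.0

    def test_constant_shift(self):
        x = np.array([1.0, 2.0, 3.0])
        res = se.bland_altman(x, x - 0.5)
        assert res.bias == pytest.approx(0.5)
        assert res.sd_diff == 0.0
        assert res.loa_low == res.loa_high == pytest.approx(0.5)

    def test_loa_width_identity(self):
        rng = np.random.default_rng(4)
        res = se.bland_altman(rng.normal(size=20), rng.normal(size=20))
        assert res.loa_high - res.loa_low == pytest.approx(
            2 * 1.96 * res.sd_diff)

    def test_ci_bounds_match_t_formula_oracle(self):
        from scipy import stats
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=10), rng.normal(size=10)
        d = x - y
        n = 10
        bias, sd = d.mean(), d.std(ddof=1)
        t = stats.t.ppf(0.975, n - 1)
        res = se.bland_altman(x, y)
        assert res.ci_bias == pytest.approx(
            (bias - t * sd / np.sqrt(n), bias + t * sd / np.sqrt(n)))
        se_loa = sd * np.sqrt(3 / n)
        assert res.ci_loa_low == pytest.approx(
            (bias - 1.96 * sd - t * se_loa, bias - 1.96 * sd + t * se_loa))


class TestCompositeDataset:
    def _tables(self, platforms, n=8):
        tabs = {}
        for k, p in enumerate(platforms):
            tabs[p] = pd.DataFrame({
                "sample_id": [f"s{i}" for i in range(n)],
                "group": [("healthy", "mild")[i % 2] for i in range(n)],
                "modified_seq": "PEPK",
                "ratio": np.arange(n, dtype=float) + 100 * k,
            })
        return tabs

    def test_single_donor_platform_reproduces_it(self):
        tabs = self._tables(["A", "B"])
        comp = se.composite_dataset(tabs, holdout="B", seed=0)
        pd.testing.assert_frame_equal(
            comp.drop(columns="source_platform"), tabs["A"])

    def test_severity_histogram_preserved_exactly(self):
        tabs = self._tables(["A", "B", "C"])
        comp = se.composite_dataset(tabs, holdout="C", seed=3)
        expected = tabs["A"]["group"].value_counts()
        pd.testing.assert_series_equal(
            comp["group"].value_counts(), expected)

    def test_seed_determinism(self):
        tabs = self._tables(["A", "B", "C"], n=30)
        c1 = se.composite_dataset(tabs, "C", seed=7)
        c2 = se.composite_dataset(tabs, "C", seed=7)
        pd.testing.assert_frame_equal(c1, c2)
        c3 = se.composite_dataset(tabs, "C", seed=8)
        assert not c1["source_platform"].equals(c3["source_platform"])

    def test_missing_sample_everywhere_errors(self):
        tabs = self._tables(["A", "B"])
        tabs["A"] = tabs["A"][tabs["A"]["sample_id"] != "s3"]
        with pytest.raises(ValueError, match="s3"):
            se.composite_dataset(tabs, holdout="B", seed=0)


class TestGroupRegression:
    def _merged(self, y_fn, n=6):
        x = np.linspace(1, 10, n)
        return pd.DataFrame({
            "modified_seq": "PEPK", "group": "healthy",
            "x": x, "y": y_fn(x),
        })

    def test_identity_line(self):
        out = se.group_regression(self._merged(lambda x: x), "x", "y")
        assert out["slope"].iloc[0] == pytest.approx(1.0)
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_slope_two_with_vanishing_noise(self):
        rng = np.random.default_rng(0)
        out = se.group_regression(
            self._merged(lambda x: 2 * x + rng.normal(0, 1e-9, x.size)),
            "x", "y")
        assert out["slope"].iloc[0] == pytest.approx(2.0)

    def test_matches_normal_equations_on_five_points(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 5)
        y = rng.uniform(0, 10, 5)
        merged = pd.DataFrame({"modified_seq": "PEPK", "group": "g",
                               "x": x, "y": y})
        out = se.group_regression(merged, "x", "y")
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        r2 = sxy**2 / (sxx * ((y - y.mean()) ** 2).sum())
        assert out["slope"].iloc[0] == pytest.approx(slope)
        assert out["r2"].iloc[0] == pytest.approx(r2)

    def test_zero_x_variance_undefined(self):
        merged = pd.DataFrame({"modified_seq": "P", "group": "g",
                               "x": [1.0] * 4, "y": [1, 2, 3, 4.0]})
        out = se.group_regression(merged, "x", "y")
        assert np.isnan(out["slope"].iloc[0])


class TestPcaScores:
    def test_rank_one_data_explained_by_pc1(self):
        m = pd.DataFrame(np.outer([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0]))
        scores, explained = se.pca_scores(m)
        assert explained[0] == pytest.approx(1.0)

    def test_explained_fractions_non_increasing_and_sum_le_one(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(10, 5)))
        _, explained = se.pca_scores(m)
        assert (np.diff(explained) <= 1e-12).all()
        assert explained.sum() <= 1 + 1e-9

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(4, 3)))
        scores, _ = se.pca_scores(m)
        x = m.to_numpy() - m.to_numpy().mean(0)
        evals, evecs = np.linalg.eigh(x.T @ x)
        order = np.argsort(evals)[::-1]
        projected = x @ evecs[:, order]
        np.testing.assert_allclose(np.abs(scores.to_numpy()),
                                   np.abs(projected), atol=1e-10)


class TestCohortLevelProperties:
    def test_ratio_normalization_shrinks_platform_variance_fraction(self, cohort_sim):
        table, design, _ = cohort_sim
        pools = {
            p: sorted(table[(table["platform_id"] == p)
                            & (table["group"] == "pool")]["run_id"].unique())
            for p in table["platform_id"].unique()
        }
        norm = nq.median_normalize(table, pools)
        ratio = nq.ratio_normalize(table)
        design_idx = design.set_index("sample_id")

        def varpart_median(df, col):
            df = df[df["group"] != "pool"]
            mat = df.pivot_table(index="modified_seq",
                                 columns=["platform_id", "sample_id"],
                                 values=col, aggfunc="mean")
            mat = mat.iloc[:20]
            dsg = pd.DataFrame(
                [{"platform": p,
                  "severity": design_idx.loc[s, "severity"]}
                 for p, s in mat.columns], index=mat.columns)
            mat = se.knn_impute(mat)
            out = se.variance_partition(mat, dsg)
            return out["frac_platform"].median()

        assert varpart_median(ratio, "ratio") < varpart_median(norm, "norm_light")

    def test_composite_trend_recovers_planted_severity_peptides(self, cohort_sim):
        """Completeness gate -> composite -> trend test recovers the sign
        of every planted severity effect among quantifiable peptides."""
        table, design, truth = cohort_sim
        ratio = nq.ratio_normalize(table)
        ratio = ratio[ratio["group"] != "pool"]
        platforms = sorted(ratio["platform_id"].unique())
        tables = {p: ratio[ratio["platform_id"] == p] for p in platforms}
        comp = se.composite_dataset(tables, holdout=platforms[-1], seed=5)
        # the workflow's completeness rule: detected in > 2/3 of samples
        n_samples = comp["sample_id"].nunique()
        det = (comp.dropna(subset=["ratio"])
               .groupby("modified_seq")["sample_id"].nunique() / n_samples)
        quantifiable = set(det[det > 2 / 3].index)
        eligible = [p for p in truth.severity_effect if p in quantifiable]
        assert len(eligible) / len(truth.severity_effect) >= 0.6
        res = se.trend_table(
            comp, severity_order=["healthy", "mild", "severe", "critical"],
            value_col="ratio").set_index("modified_seq")
        hits = sum(
            np.sign(res.loc[p, "tau"])
            == np.sign(np.log(truth.severity_effect[p]))
            for p in eligible)
        assert hits / len(eligible) >= 0.95
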