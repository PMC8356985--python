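"""Group statistics: ANOVA, LSD, BH-FDR, chi-square, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dfncstates as d


class TestSubjectStateConnectivity:
    def _toy(self):
        from dfncstates.windows import TaperSpec, WindowedFNC

        values = np.zeros((1, 4, 3))
        values[0] = [[0.2, 1.0, -1.0], [0.4, 2.0, -2.0], [0.6, 3.0, -3.0], [0.8, 4.0, -4.0]]
        ids = ("c1", "c2", "c3")
        part = d.NetworkPartition(ids, {"c1": "A", "c2": "A", "c3": "B"})
        fnc = WindowedFNC(values, ["s1"], d.pair_index(part), part, TaperSpec(), np.array([0.1]))
        return fnc

    def test_mean_over_state_windows(self):
        fnc = self._toy()
        model = d.StateModel(2, np.zeros((2, 3)), np.array([[1, 1, 2, 2]]), None, 0.0)
        prof = d.subject_state_connectivity(fnc, model)
        np.testing.assert_allclose(prof[0, 0], [0.3, 1.5, -1.5])
        np.testing.assert_allclose(prof[0, 1], [0.7, 3.5, -3.5])

    def test_unvisited_state_missing(self):
        fnc = self._toy()
        model = d.StateModel(2, np.zeros((2, 3)), np.array([[1, 1, 1, 1]]), None, 0.0)
        prof = d.subject_state_connectivity(fnc, model)
        assert np.isnan(prof[0, 1]).all()
        assert np.isfinite(prof[0, 0]).all()

    def test_window_permutation_invariance(self):
        fnc = self._toy()
        labels = np.array([[1, 2, 1, 2]])
        model = d.StateModel(2, np.zeros((2, 3)), labels, None, 0.0)
        a = d.subject_state_connectivity(fnc, model)
        perm = [3, 1, 2, 0]
        fnc.values = fnc.values[:, perm]
        model2 = d.StateModel(2, np.zeros((2, 3)), labels[:, perm], None, 0.0)
        b = d.subject_state_connectivity(fnc, model2)
        np.testing.assert_allclose(a, b)


class TestOnewayAnova:
    def test_identical_groups_zero_f(self):
        g = np.array([1.0, 2.0, 3.0])
        F, p, _ = d.oneway_anova([g, g, g])
        assert F == 0.0
        assert p == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        a = np.zeros(4) + rng.normal(0, 1e-6, 4)
        b = np.ones(4) + rng.normal(0, 1e-6, 4)
        F, p, _ = d.oneway_anova([a, b])
        assert p < 1e-6

    def test_hand_computed_example(self):
        # groups (2,4),(6,8),(10,12): SSB = 64, SSW = 6, F = (64/2)/(6/3) = 16
        F, p, (df1, df2) = d.oneway_anova(
            [np.array([2.0, 4.0]), np.array([6.0, 8.0]), np.array([10.0, 12.0])]
        )
        assert F == pytest.approx(16.0)
        assert (df1, df2) == (2, 3)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        groups = [rng.standard_normal(n) for n in (8, 12, 10)]
        F, p, _ = d.oneway_anova(groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_vectorized_outcomes(self):
        rng = np.random.default_rng(2)
        groups = [rng.standard_normal((6, 5)) for _ in range(3)]
        F, p, _ = d.oneway_anova(groups)
        assert F.shape == (5,)
        for j in range(5):
            ref = stats.f_oneway(*[g[:, j] for g in groups])
            assert F[j] == pytest.approx(ref.statistic)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            d.oneway_anova([np.ones(3), np.ones(3)])


class TestAnovaFromSummary:
    def test_matches_full_anova_on_constructed_data(self):
        rng = np.random.default_rng(3)
        means, sds, ns = [1.0, 2.0, 1.5], [0.5, 1.0, 0.8], [10, 14, 12]
        groups = []
        for m, s, n in zip(means, sds, ns):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1) * s + m  # exact sample moments
            groups.append(x)
        F_full, p_full, _ = d.oneway_anova(groups)
        F_sum, p_sum = d.anova_from_summary(means, sds, ns)
        assert F_sum == pytest.approx(F_full)
        assert p_sum == pytest.approx(p_full)

    def test_equal_means_zero_f(self):
        F, p = d.anova_from_summary([5.0, 5.0], [1.0, 2.0], [10, 10])
        assert F == 0.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            d.anova_from_summary([1.0, 1.0], [0.0, 0.0], [5, 5])


class TestLsdPosthoc:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        out = d.lsd_posthoc([g, g.copy()])
        t, p = out[("g1", "g2")]
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_group_t_squared_equals_f(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(8), rng.standard_normal(10) + 0.5
        F, _, _ = d.oneway_anova([a, b])
        t, _ = d.lsd_posthoc([a, b])[("g1", "g2")]
        assert t**2 == pytest.approx(F)

    def test_three_group_hand_formula(self):
        groups = [np.array([2.0, 4.0]), np.array([6.0, 8.0]), np.array([10.0, 12.0])]
        out = d.lsd_posthoc(groups, ["a", "b", "c"])
        msw = 2.0  # each group variance 2, pooled over df = 3
        se = np.sqrt(msw * (0.5 + 0.5))
        t_ab = (3.0 - 7.0) / se
        assert out[("a", "b")][0] == pytest.approx(t_ab)
        assert out[("a", "c")][0] == pytest.approx((3.0 - 11.0) / se)


def brute_force_bh(pvals, q):
    """Literal step-up definition, independent of the implementation."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    k = below.max() + 1 if below.size else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, sorted_p[i] * m / (i + 1))
        adj[order[i]] = running
    return adj, reject


class TestBhFdr:
    def test_step_up_example(self):
        p_adj, reject = d.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()

    def test_all_ones(self):
        p_adj, reject = d.bh_fdr(np.ones(5))
        assert not reject.any()
        np.testing.assert_allclose(p_adj, 1.0)

    def test_single_test_unchanged(self):
        p_adj, _ = d.bh_fdr(np.array([0.03]))
        assert p_adj[0] == pytest.approx(0.03)

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            adj, rej = d.bh_fdr(p, q=0.05)
            adj_bf, rej_bf = brute_force_bh(p, 0.05)
            np.testing.assert_allclose(adj, adj_bf, atol=1e-12)
            np.testing.assert_array_equal(rej, rej_bf)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            d.bh_fdr(np.array([0.1, 1.5]))


class TestChiSquare:
    def test_proportional_rows_zero(self):
        chi2, p, _ = d.chi_square(np.array([[10, 20], [5, 10], [20, 40]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table(self):
        chi2, p, dof = d.chi_square(np.array([[10, 0], [0, 10]]))
        assert chi2 == pytest.approx(20.0)
        assert dof == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            d.chi_square(np.array([[0, 0], [1, 2]]))


class TestPartialCorrelation:
    def test_no_covariates_is_pearson(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        r, p = d.partial_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_covariate_determined_outcome_zero(self):
        rng = np.random.default_rng(7)
        c = rng.standard_normal((60, 2))
        y = 2.0 * c[:, 0] - c[:, 1] + 3.0
        x = rng.standard_normal(60)
        r, _ = d.partial_correlation(x, y, c)
        assert abs(r) < 1e-10

    def test_shared_covariate_construction(self):
        # x = c + e1, y = c + e2: partial r given c approximates corr(e1, e2)
        rng = np.random.default_rng(8)
        n = 2000
        c = rng.standard_normal(n) * 2
        e = rng.multivariate_normal([0, 0], [[1.0, 0.4], [0.4, 1.0]], size=n)
        x, y = c + e[:, 0], c + e[:, 1]
        r, _ = d.partial_correlation(x, y, c)
        assert r == pytest.approx(0.4, abs=0.06)
        # zero-order correlation is inflated by the shared covariate
        assert stats.pearsonr(x, y).statistic > r

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("xyab"))
        out = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
        r, p = d.partial_correlation(
            df["x"].to_numpy(), df["y"].to_numpy(), df[["a", "b"]].to_numpy()
        )
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-10)

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(10)
        c = rng.standard_normal(30)
        cov = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError):
            d.partial_correlation(rng.standard_normal(30), rng.standard_normal(30), cov)


def _synthetic_metrics_manifest(n_per_group, seed, fw_shift=0.0):
    rng = np.random.default_rng(seed)
    groups = ["OCD"] * n_per_group + ["UFDR"] * n_per_group + ["HC"] * n_per_group
    n = len(groups)
    shift = np.array([0.0] * n_per_group + [fw_shift / 2] * n_per_group + [fw_shift] * n_per_group)
    fw1 = np.clip(rng.normal(0.3 + shift, 0.1), 0.01, 0.99)
    metrics = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "fw_state1": fw1,
            "fw_state2": 1 - fw1,
            "dt_state1": rng.gamma(4, 5, n),
            "dt_state2": rng.gamma(6, 5, n),
            "n_transitions": rng.poisson(6, n),
        }
    )
    manifest = pd.DataFrame(
        {
            "subject_id": metrics["subject_id"],
            "group": groups,
            "ybocs_total": rng.normal(10, 5, n),
            "ocir": rng.normal(15, 8, n),
            "bdi": rng.normal(10, 5, n),
            "stai_state": rng.normal(40, 10, n),
            "stai_trait": rng.normal(40, 10, n),
            "education_years": rng.normal(13, 3, n),
        }
    )
    return metrics, manifest


class TestRunGroupAnalysis:
    def test_smoke_and_structure(self):
        metrics, manifest = _synthetic_metrics_manifest(12, seed=0, fw_shift=0.15)
        profiles = np.random.default_rng(0).normal(0.3, 0.1, size=(36, 2, 10))
        res = d.run_group_analysis(metrics, profiles, manifest)
        assert set(res.temporal["outcome"]) == {
            "fw_state1", "fw_state2", "dt_state1", "dt_state2", "n_transitions"
        }
        assert set(res.connectivity) == {1, 2}
        assert len(res.clinical) == 10  # 5 metrics x 2 scales
        assert (res.clinical["p_fdr"] >= res.clinical["p"] - 1e-12).all()
        fw_row = res.temporal[res.temporal["outcome"] == "fw_state1"].iloc[0]
        assert fw_row["p"] < 0.01  # built-in group shift detected

    def test_missing_state_family_skipped(self):
        metrics, manifest = _synthetic_metrics_manifest(5, seed=1)
        profiles = np.random.default_rng(1).normal(0.3, 0.1, size=(15, 2, 6))
        # state 2 missing for all but one OCD subject
        profiles[:4, 1, :] = np.nan
        with pytest.warns(UserWarning):
            res = d.run_group_analysis(metrics, profiles, manifest)
        assert 2 not in res.connectivity
        assert res.exclusions[2] == 4
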