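"""Statistical battery: winsorization, partial correlations, Holm,
elastic net, cross-sample prediction, overlap, ICC, split-half, LQ."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fconn import (
    CovariateDesign,
    cross_sample_predict,
    elastic_net_select,
    holm_adjust,
    icc_3_1,
    lateralization_quotient,
    partial_correlation_test,
    predictor_overlap,
    residualize,
    significant_effect_summary,
    spearman_brown,
    split_half_reliability,
    winsorize,
)


def make_cohort_table(n, rng):
    lq = rng.uniform(-100, 100, n)
    return pd.DataFrame(
        {
            "id": [f"sub-{i}" for i in range(n)],
            "g": rng.standard_normal(n),
            "age": rng.uniform(18, 40, n),
            "sex": rng.integers(0, 2, n),
            "LQ": lq,
            "handedness": (lq >= 60).astype(int),
            "total_brain_volume": rng.normal(1200, 100, n),
            "head_motion": rng.uniform(0.05, 0.3, n),
        }
    )


class TestWinsorize:
    def test_outlier_pulled_to_exact_bound(self, rng):
        x = rng.standard_normal(200)
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        x[0] = x.mean() + 10 * iqr
        out = winsorize(x)
        # bound computed on the contaminated vector, as applied
        assert out[0] == pytest.approx(x.mean() + 3 * (np.percentile(x, 75) - np.percentile(x, 25)))

    def test_in_bounds_vector_unchanged(self, rng):
        x = rng.uniform(-1, 1, 50)
        assert np.array_equal(winsorize(x), x)

    def test_identical_values_unchanged(self):
        x = np.full(10, 3.7)
        assert np.array_equal(winsorize(x), x)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_replaced_count_matches_out_of_bounds_count(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(100) * rng.uniform(0.5, 5)
        x[rng.integers(0, 100, 5)] *= 20
        q1, q3 = np.percentile(x, [25, 75])
        lo, hi = x.mean() - 3 * (q3 - q1), x.mean() + 3 * (q3 - q1)
        out = winsorize(x)
        assert np.sum(out != x) == np.sum((x < lo) | (x > hi))


class TestResidualize:
    def test_orthogonal_outcome_returned_centered(self, rng):
        design = CovariateDesign(matrix=rng.standard_normal((100, 3)), names=("a", "b", "c"))
        y = rng.standard_normal(100)
        resid = residualize(y, design)
        assert np.allclose(resid.mean(), 0.0, atol=1e-12)

    def test_outcome_linear_in_design_gives_zero_residuals(self, rng):
        x = rng.standard_normal((50, 2))
        design = CovariateDesign(matrix=x, names=("a", "b"))
        y = 2.0 * x[:, 0] - 1.5 * x[:, 1] + 3.0
        assert np.allclose(residualize(y, design), 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_every_column(self, rng):
        design = CovariateDesign(matrix=rng.standard_normal((200, 5)), names=tuple("abcde"))
        resid = residualize(rng.standard_normal(200), design)
        for j in range(5):
            assert abs(resid @ design.matrix[:, j]) < 1e-10

    def test_rank_deficient_design_names_dependent_columns(self, rng):
        x = rng.standard_normal((40, 2))
        mat = np.column_stack([x[:, 0], x[:, 1], x[:, 0] + x[:, 1]])
        design = CovariateDesign(matrix=mat, names=("a", "b", "a_plus_b"))
        with pytest.raises(ValueError, match="a_plus_b"):
            residualize(rng.standard_normal(40), design)

    def test_cohort_design_has_documented_columns(self, rng):
        table = make_cohort_table(80, rng)
        design = CovariateDesign.from_cohort(table)
        assert design.n_controls == 8
        assert design.names[0] == "age" and design.names[-1] == "head_motion"
        assert np.isfinite(design.condition_number)


class TestPartialCorrelationTest:
    def test_metric_identical_to_g_gives_unit_correlation(self, rng):
        design = CovariateDesign(matrix=rng.standard_normal((50, 2)), names=("a", "b"))
        g = rng.standard_normal(50)
        r, p = partial_correlation_test(g, g.copy(), design)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_planted_partial_correlation_recovered(self, rng):
        n = 500
        design = CovariateDesign(matrix=rng.standard_normal((n, 4)), names=tuple("abcd"))
        latent = rng.standard_normal(n)
        g = 0.3 * latent + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        r, p = partial_correlation_test(g, latent, design)
        assert r == pytest.approx(0.3, abs=3.0 / np.sqrt(n))
        assert p < 0.001

    def test_df_guard(self, rng):
        design = CovariateDesign(matrix=rng.standard_normal((5, 4)), names=tuple("abcd"))
        with pytest.raises(ValueError):
            partial_correlation_test(rng.standard_normal(5), rng.standard_normal(5), design)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_down_with_monotonicity_hand_case(self):
        # sorted: 0.01*3=0.03, 0.03*2=0.06, 0.04*1=0.04 -> running max 0.06
        adj = holm_adjust(np.array([0.01, 0.04, 0.03]))
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_matches_statsmodels_and_dominates_raw(self, ps):
        from statsmodels.stats.multitest import multipletests

        p = np.array(ps)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        expected = multipletests(p, method="holm")[1]
        assert np.allclose(adj, expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust(np.array([0.5, 1.2]))


class TestSignificantEffectSummary:
    def test_mean_and_sd_of_significant_entries(self):
        pairs = [(0.07, 0.023), (0.11, 0.030), (0.11, 0.049), (0.02, 0.5), (-0.01, 0.85)]
        mean, sd, n = significant_effect_summary(pairs, alpha=0.05)
        assert n == 3
        assert mean == pytest.approx(np.mean([0.07, 0.11, 0.11]))
        assert sd == pytest.approx(np.std([0.07, 0.11, 0.11], ddof=1))

    def test_no_significant_entries(self):
        mean, sd, n = significant_effect_summary([(0.2, 0.6)])
        assert n == 0 and np.isnan(mean)


class TestElasticNet:
    def test_strong_single_predictor_recovered(self, rng):
        n, p = 300, 50
        X = rng.standard_normal((n, p))
        y = 0.8 * X[:, 5] + rng.standard_normal(n)
        model = elastic_net_select(X, y, seed=0)
        assert 5 in model.selected
        assert model.alpha == 0.5 and model.cv_folds == 10
        assert np.array_equal(model.selected, np.flatnonzero(model.beta != 0))

    def test_seeded_reproducibility(self, rng):
        X = rng.standard_normal((100, 20))
        y = rng.standard_normal(100)
        a = elastic_net_select(X, y, seed=3)
        b = elastic_net_select(X, y, seed=3)
        assert np.array_equal(a.beta, b.beta)
        assert a.lambda_selected == b.lambda_selected

    def test_huge_penalty_zeroes_all_coefficients(self, rng):
        from sklearn.linear_model import ElasticNet

        X = rng.standard_normal((80, 10))
        y = rng.standard_normal(80)
        fit = ElasticNet(alpha=1e6, l1_ratio=0.5).fit(X, y)
        assert np.all(fit.coef_ == 0.0)

    def test_one_se_rule_selects_larger_lambda(self, rng):
        n, p = 200, 30
        X = rng.standard_normal((n, p))
        y = 0.5 * X[:, 2] + rng.standard_normal(n)
        m_min = elastic_net_select(X, y, seed=1, lambda_rule="min")
        m_1se = elastic_net_select(X, y, seed=1, lambda_rule="1se")
        assert m_1se.lambda_selected >= m_min.lambda_selected

    def test_nonfinite_rejected(self, rng):
        X = rng.standard_normal((50, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            elastic_net_select(X, rng.standard_normal(50), seed=0)

    def test_design_residualization_path(self, rng):
        table = make_cohort_table(120, rng)
        design = CovariateDesign.from_cohort(table)
        X = rng.standard_normal((120, 15))
        y = 0.8 * X[:, 3] + rng.standard_normal(120)
        model = elastic_net_select(X, y, design=design, seed=2)
        assert 3 in model.selected


class TestCrossSamplePredict:
    def test_single_perfect_predictor_explains_everything(self, rng):
        table = make_cohort_table(100, rng)
        design = CovariateDesign.from_cohort(table)
        g = rng.standard_normal(100)
        X = np.column_stack([g, rng.standard_normal(100)])
        res = cross_sample_predict(np.array([0]), "A", "B", g, X, design)
        assert res.r_squared == pytest.approx(1.0)
        assert res.significant_bonferroni

    def test_empty_predictor_set_flagged(self, rng):
        table = make_cohort_table(50, rng)
        design = CovariateDesign.from_cohort(table)
        res = cross_sample_predict(np.array([], dtype=int), "A", "B", rng.standard_normal(50), rng.standard_normal((50, 3)), design)
        assert res.note == "no predictors"
        assert res.r_squared is None and not res.significant_bonferroni

    def test_null_predictors_rarely_significant_at_bonferroni(self, rng):
        hits = 0
        for _ in range(30):
            table = make_cohort_table(120, rng)
            design = CovariateDesign.from_cohort(table)
            g = rng.standard_normal(120)
            X = rng.standard_normal((120, 5))
            res = cross_sample_predict(np.arange(5), "A", "B", g, X, design, bonferroni_m=16)
            hits += res.significant_bonferroni
        assert hits <= 2


class TestPredictorOverlap:
    def test_identical_supports_full_overlap(self):
        rep = predictor_overlap({"A": {1, 2}, "B": {1, 2}})
        assert rep["overlap_pct"] == 100.0
        assert rep["all_way"] == [1, 2]

    def test_disjoint_supports_empty_intersection(self):
        rep = predictor_overlap({"A": {1}, "B": {2}})
        assert rep["all_way"] == [] and rep["overlap_pct"] == 0.0

    def test_partial_overlap_with_averaged_effects(self):
        rep = predictor_overlap(
            {"A": {1, 2, 3}, "B": {2, 3, 4}},
            effects={"A": {1: 0.5, 2: 0.2, 3: 0.4}, "B": {2: 0.4, 3: 0.0, 4: 0.1}},
        )
        assert rep["pairwise"]["A&B"] == [2, 3]
        assert rep["averaged_effects"][2] == pytest.approx(0.3)
        assert rep["averaged_effects"][1] == pytest.approx(0.5)


class TestICC:
    def test_identical_sessions_give_one(self, rng):
        col = rng.standard_normal(20)
        assert icc_3_1(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_pure_noise_sessions_near_zero(self, rng):
        m = rng.standard_normal((500, 2))
        assert abs(icc_3_1(m)) <= 0.05

    def test_matches_pingouin_on_small_fixture(self):
        pg = pytest.importorskip("pingouin")
        m = np.array([[9.0, 10.0], [6.0, 5.0], [8.0, 8.5], [7.0, 7.5], [10.0, 9.0]])
        ours = icc_3_1(m)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(5), 2),
                "session": np.tile([0, 1], 5),
                "score": m.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="subject", raters="session", ratings="score")
        # consistency, single measure: pingouin's ICC(C,1) == ICC(3,1)
        expected = float(res.loc[res["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert ours == pytest.approx(expected, abs=1e-10)

    def test_variance_component_recovery(self, rng):
        # true ICC = sigma_s^2 / (sigma_s^2 + sigma_e^2) = 0.5
        n = 1000
        subj = rng.standard_normal(n)[:, None]
        m = subj + rng.standard_normal((n, 2))
        assert icc_3_1(m) == pytest.approx(0.5, abs=0.05)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 1.0], [0.5, 0.2]])
        with pytest.raises(ValueError):
            icc_3_1(m)


class TestSplitHalfAndSB:
    def test_spearman_brown_fixed_points(self):
        assert spearman_brown(1.0) == pytest.approx(1.0)
        assert spearman_brown(0.5) == pytest.approx(2 / 3)

    def test_split_half_runs_through_full_chain(self):
        from fconn import EffectSpec, GroundTruthSpec, generate_cohort, simulate_bold

        gspec = GroundTruthSpec(n_nodes=16, n_modules=2, seed=1)
        table, nets = generate_cohort(6, gspec, EffectSpec(scale_sd=0.3), seed=2)
        bundles = [
            simulate_bold(net, n_volumes=400, n_confounds=2, seed=10 + i)
            for i, net in enumerate(nets)
        ]
        out = split_half_reliability(bundles)
        assert set(out["metric"]) == {"global_efficiency", "global_clustering"}
        for _, row in out.iterrows():
            assert row["sb"] <= 1.0 + 1e-12

    def test_short_series_rejected(self, rng):
        from fconn import TimeSeriesBundle

        bundles = [
            TimeSeriesBundle(rng.standard_normal((4, 15)), np.empty((0, 15)), 1.0)
            for _ in range(3)
        ]
        with pytest.raises(ValueError):
            split_half_reliability(bundles)


class TestLateralizationQuotient:
    @pytest.mark.parametrize(
        "r, l, lq, code",
        [(10, 0, 100.0, 1), (5, 5, 0.0, 0), (8, 2, 60.0, 1), (0, 10, -100.0, 0)],
    )
    def test_formula_and_cutoff(self, r, l, lq, code):
        got_lq, got_code = lateralization_quotient(r, l)
        assert got_lq == pytest.approx(lq)
        assert got_code == code

    def test_zero_responses_rejected(self):
        with pytest.raises(ValueError):
            lateralization_quotient(0, 0)
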