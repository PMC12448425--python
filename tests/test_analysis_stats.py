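import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from gliomashape.analysis_stats import (
    ModelSpec,
    battery_frame,
    huber_fit,
    huber_regression,
    kruskal_wallis,
    logistic_fit,
    logistic_regression,
    mann_whitney,
    run_multivariable_models,
    run_univariable_battery,
    shapiro_screen,
    spearman,
)
from gliomashape.errors import (
    GliomaShapeError,
    RankDeficiencyError,
    SchemaError,
    SeparationError,
)
from gliomashape.synthetic_data import CohortSpec, simulate_cohort

from _oracles import kruskal_h_no_ties, mann_whitney_exact_p, ols, spearman_no_ties


class TestShapiroScreen:
    def test_lognormal_flagged(self):
        rng = np.random.default_rng(0)
        r = shapiro_screen(rng.lognormal(0, 1, 5000))
        assert r.significant

    def test_constant_rejected(self):
        with pytest.raises(GliomaShapeError):
            shapiro_screen([2.0] * 10)

    def test_too_few_rejected(self):
        with pytest.raises(GliomaShapeError):
            shapiro_screen([1.0, 2.0])

    def test_level_on_normal_draws(self):
        flagged = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            if shapiro_screen(rng.normal(size=50)).significant:
                flagged += 1
        assert flagged <= 10  # ~5% expected at alpha = 0.05


class TestSpearman:
    def test_identity(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman(x, x).statistic == pytest.approx(1.0)

    def test_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_worked_five_point_example(self):
        x = [1, 2, 3, 4, 5]
        y = [3, 1, 2, 4, 5]
        r = spearman(x, y)
        assert r.statistic == pytest.approx(0.7, abs=1e-12)
        assert r.statistic == pytest.approx(spearman_no_ties(x, y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(GliomaShapeError):
            spearman([1, 2, 3], [1, 2])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from(["exp", "cube", "logit"]))
    def test_monotone_transform_invariance(self, seed, transform):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        fn = {"exp": np.exp, "cube": lambda v: v**3,
              "logit": lambda v: 1 / (1 + np.exp(-v))}[transform]
        base = spearman(x, y)
        trans = spearman(fn(x), fn(y))
        assert trans.statistic == pytest.approx(base.statistic, abs=1e-9)
        assert trans.p_value == pytest.approx(base.p_value, abs=1e-9)


class TestMannWhitney:
    def test_fully_separated_exact(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        u_oracle, p_oracle = mann_whitney_exact_p([1, 2, 3], [4, 5, 6])
        assert r.statistic == u_oracle == 0.0
        assert r.p_value == pytest.approx(0.1, abs=1e-12)
        assert r.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.permutation(14)[:6].astype(float)
        b = np.setdiff1d(np.arange(14), a)[:5].astype(float) + 0.5
        r = mann_whitney(a, b)
        u_oracle, p_oracle = mann_whitney_exact_p(a, b)
        assert r.statistic == pytest.approx(u_oracle)
        assert r.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_identical_multisets_u_half(self):
        a = [1.0, 2.0, 3.0, 4.0]
        r = mann_whitney(a, a)
        assert r.statistic == pytest.approx(8.0)  # n^2 / 2

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_complement_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 12))
        b = rng.normal(size=rng.integers(2, 12))
        u_ab = mann_whitney(a, b).statistic
        u_ba = mann_whitney(b, a).statistic
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_exact_vs_asymptotic_agreement_n8(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=8)
        b = rng.normal(size=8) + 0.5
        from scipy.stats import mannwhitneyu

        exact = mannwhitneyu(a, b, method="exact").pvalue
        asym = mannwhitneyu(a, b, method="asymptotic").pvalue
        assert abs(exact - asym) <= 0.02
        # package picks the exact branch here (n <= 8, no ties)
        assert mann_whitney(a, b).p_value == pytest.approx(exact)

    def test_empty_group_rejected(self):
        with pytest.raises(GliomaShapeError):
            mann_whitney([], [1.0])

    def test_group_summaries(self):
        r = mann_whitney([1, 2, 3, 4], [10, 20])
        assert r.groups["a"].median == 2.5
        assert r.groups["b"].n == 2


class TestKruskalWallis:
    def test_identical_values_h_zero(self):
        r = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0], [5.0]])
        assert r.statistic == 0.0

    def test_three_pair_groups_direct_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        r = kruskal_wallis(groups)
        h_oracle = kruskal_h_no_ties(groups)
        assert h_oracle == pytest.approx(32.0 / 7.0)  # 4.571...
        assert r.statistic == pytest.approx(h_oracle, abs=1e-12)

    def test_permutation_invariance(self):
        groups = [[1.0, 5.0], [2.0, 7.0, 4.0], [9.0, 3.0]]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis(groups[::-1]).statistic
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(GliomaShapeError):
            kruskal_wallis([[1.0, 2.0]])


def _design(rng, n=300, p=3):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = np.array([1.0, 0.5, -0.25])[:p]
    return X, beta


class TestHuberRegression:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        X, beta = _design(rng)
        fit = huber_regression(X, X @ beta)
        np.testing.assert_allclose(fit.coef, beta, atol=1e-8)

    def test_matches_ols_on_clean_gaussian(self):
        # low-noise Gaussian data: downweighting beyond the Huber threshold
        # perturbs coefficients by well under 1e-3
        rng = np.random.default_rng(1)
        X, beta = _design(rng)
        y = X @ beta + rng.normal(0, 0.02, len(X))
        fit = huber_regression(X, y)
        np.testing.assert_allclose(fit.coef, ols(X, y), atol=1e-3)

    def test_beats_ols_under_gross_outlier(self):
        rng = np.random.default_rng(2)
        X, beta = _design(rng)
        y = X @ beta + rng.normal(0, 0.3, len(X))
        y[10] += 100 * 0.3  # +100 sigma
        huber_err = np.abs(huber_regression(X, y).coef - beta).max()
        ols_err = np.abs(ols(X, y) - beta).max()
        assert huber_err < ols_err

    def test_equals_ols_in_large_tuning_limit(self):
        rng = np.random.default_rng(3)
        X, beta = _design(rng)
        y = X @ beta + rng.standard_t(3, len(X))
        fit = huber_regression(X, y, tuning=1e12)
        np.testing.assert_allclose(fit.coef, ols(X, y), atol=1e-10)

    def test_matches_statsmodels_rlm(self):
        rng = np.random.default_rng(4)
        X, beta = _design(rng)
        y = X @ beta + rng.normal(0, 0.5, len(X))
        y[:5] += 20
        fit = huber_regression(X, y)
        rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            scale_est="mad", conv="coefs", tol=1e-10, maxiter=300
        )
        np.testing.assert_allclose(fit.coef, rlm.params, atol=1e-7)
        np.testing.assert_allclose(fit.se, rlm.bse, rtol=1e-5)

    def test_rank_deficiency_names_aliased(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x, 2 * x])
        with pytest.raises(RankDeficiencyError) as exc:
            huber_regression(X, rng.normal(size=100), names=["intercept", "a", "a_twice"])
        assert "a" in exc.value.aliased or "a_twice" in exc.value.aliased

    def test_ci_brackets_coef(self):
        rng = np.random.default_rng(6)
        X, beta = _design(rng)
        y = X @ beta + rng.normal(0, 1, len(X))
        fit = huber_regression(X, y)
        assert np.all(fit.ci_low <= fit.coef) and np.all(fit.coef <= fit.ci_high)


class TestLogisticRegression:
    def test_intercept_only_balanced(self):
        X = np.ones((40, 1))
        y = np.array([0.0, 1.0] * 20)
        fit = logistic_regression(X, y)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-10)

    def test_two_by_two_log_odds_ratio(self):
        # table (a, b, c, d) = (20, 10, 10, 20)
        x = np.array([1.0] * 30 + [0.0] * 30)
        y = np.array([1.0] * 20 + [0.0] * 10 + [1.0] * 10 + [0.0] * 20)
        X = np.column_stack([np.ones(60), x])
        fit = logistic_regression(X, y)
        assert fit.coef[1] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_perfect_separation_raises(self):
        x = np.linspace(-2, 2, 50)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            logistic_regression(np.column_stack([np.ones(50), x]), y)

    def test_single_class_rejected(self):
        with pytest.raises(GliomaShapeError):
            logistic_regression(np.ones((10, 1)), np.ones(10))

    def test_matches_statsmodels_logit(self):
        rng = np.random.default_rng(7)
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        p = 1.0 / (1.0 + np.exp(-(0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2])))
        y = (rng.random(n) < p).astype(float)
        fit = logistic_regression(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-8)

    def test_loglik_not_below_null(self):
        rng = np.random.default_rng(8)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.4).astype(float)
        fit = logistic_regression(X, y)

        def ll(beta):
            eta = X @ beta
            return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

        assert ll(fit.coef) >= ll(np.zeros(2))


class TestBattery:
    def test_injected_negative_csa_effect_detected(self):
        cohort = simulate_cohort(CohortSpec(n_patients=500, seed=21))
        results = run_univariable_battery(cohort)
        cell = next(
            r for r in results if r.variable == "eor" and r.shape_metric == "csa"
        )
        assert cell.statistic < 0
        assert cell.significant

    def test_biopsy_rows_excluded_from_outcome_tests(self):
        cohort = simulate_cohort(CohortSpec(n_patients=400, seed=22))
        n_resection = int((cohort["biopsy_only"] == 0).sum())
        results = run_univariable_battery(cohort)
        eor_cell = next(
            r for r in results if r.variable == "eor" and r.shape_metric == "csa"
        )
        assert eor_cell.n == n_resection
        deficit_cell = next(
            r for r in results if r.variable == "focal_deficits" and r.shape_metric == "csa"
        )
        assert deficit_cell.n == n_resection

    def test_type_one_error_under_null(self):
        null_spec = dict(
            eor_beta_age=0.0, eor_beta_volume=0.0, eor_beta_csa=0.0,
            eor_beta_si=0.0, eor_beta_eloquent=0.0, eor_intercept=0.6,
            gtr_fraction=0.0, eor_noise_sd=0.1,
        )
        false_positives = 0
        n_sims = 200
        for seed in range(n_sims):
            cohort = simulate_cohort(CohortSpec(n_patients=200, seed=seed, **null_spec))
            r = cohort[cohort["biopsy_only"] == 0]
            if spearman(r["eor"], r["csa_cm2"]).significant:
                false_positives += 1
        # binomial(200, 0.05): 95% band roughly [4, 17]
        assert false_positives <= 20

    def test_missing_column_raises_schema_error(self):
        cohort = simulate_cohort(CohortSpec(n_patients=100, seed=1)).drop(columns=["si"])
        with pytest.raises(SchemaError):
            run_univariable_battery(cohort)

    def test_battery_frame_tidy(self):
        cohort = simulate_cohort(CohortSpec(n_patients=300, seed=2))
        frame = battery_frame(run_univariable_battery(cohort))
        assert {"variable", "shape_metric", "test", "p_value"} <= set(frame.columns)
        assert (frame["p_value"] <= 1).all()


class TestMultivariableModels:
    def test_four_fits_converge(self):
        cohort = simulate_cohort(CohortSpec(n_patients=1000, seed=30))
        fits = run_multivariable_models(cohort)
        assert set(fits) == {
            ("eor", "csa"), ("eor", "si"),
            ("focal_deficit", "csa"), ("focal_deficit", "si"),
        }
        for fit in fits.values():
            assert fit.converged

    def test_eor_model_includes_location_dummies(self):
        cohort = simulate_cohort(CohortSpec(n_patients=1000, seed=31))
        fit = huber_fit(ModelSpec("eor", "csa"), cohort)
        assert any(t.startswith("location[") for t in fit.terms)
        assert "location[central_deep]" not in fit.terms  # reference level
        deficit = logistic_fit(ModelSpec("focal_deficit", "csa"), cohort)
        assert not any(t.startswith("location[") for t in deficit.terms)

    def test_missing_location_column_raises(self):
        cohort = simulate_cohort(CohortSpec(n_patients=500, seed=32)).drop(columns=["location"])
        with pytest.raises(SchemaError, match="location"):
            huber_fit(ModelSpec("eor", "csa"), cohort)

    def test_sign_recovery_both_models(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = CohortSpec(
                n_patients=5000, seed=seed,
                csa_median=60.9, csa_q1=45.0, csa_q3=80.0,
                eor_intercept=0.65, eor_beta_age=-0.0005, eor_beta_volume=0.0004,
                eor_beta_csa=-0.0012, eor_beta_si=0.0, eor_beta_eloquent=-0.05,
                eor_noise_sd=0.08, gtr_fraction=0.0,
                deficit_beta_si=0.8, deficit_beta_csa=0.0,
            )
            cohort = simulate_cohort(spec)
            h = huber_fit(ModelSpec("eor", "csa"), cohort)["csa"]
            g = logistic_fit(ModelSpec("focal_deficit", "si"), cohort)["si"]
            hits += (h["coef"] < 0 and h["p_value"] < 0.05
                     and g["coef"] > 0 and g["p_value"] < 0.05)
        assert hits >= 19  # >= 0.95 recovery probability

    def test_biopsy_rows_excluded(self):
        cohort = simulate_cohort(CohortSpec(n_patients=800, seed=33))
        fit = huber_fit(ModelSpec("eor", "csa"), cohort)
        assert fit.n_used == int((cohort["biopsy_only"] == 0).sum())
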