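"""Best-subset regression, BIC/Bayes-factor conventions, LOO skill, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pupilmath import modelsel as ms


class TestNullBic:
    def test_fixed_value_for_any_zscored_70_vector(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = ms.zscore(rng.standard_normal(70))
            assert ms.null_bic(y) == pytest.approx(206.14, abs=0.01)
        # scale-family invariance: lognormal content gives the same BIC
        y = ms.zscore(rng.lognormal(size=70))
        assert ms.null_bic(y) == pytest.approx(206.14, abs=0.01)

    def test_matches_direct_likelihood_oracle_at_n4(self):
        y = ms.zscore(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_allclose(
            y, [-1.161895, -0.387298, 0.387298, 1.161895], atol=1e-5
        )
        # brute-force: evaluate the Gaussian likelihood at the MLE directly
        n = 4
        sigma2 = np.sum((y - y.mean()) ** 2) / n
        ll = np.sum(stats.norm.logpdf(y, loc=y.mean(), scale=np.sqrt(sigma2)))
        assert ms.null_bic(y) == pytest.approx(-2 * ll + 2 * np.log(n), abs=1e-9)

    def test_not_additive_under_data_duplication(self):
        rng = np.random.default_rng(1)
        y = ms.zscore(rng.standard_normal(35))
        doubled = ms.zscore(np.concatenate([y, y]))
        assert ms.null_bic(doubled) != pytest.approx(2 * ms.null_bic(y), abs=0.5)

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            ms.null_bic(np.array([0.5, -0.5]))


class TestBayesFactor:
    @pytest.mark.parametrize(
        "bic_a,bic_b,expected",
        [
            (200.72, 206.14, 15.04),   # accuracy-only vs null
            (189.33, 206.14, 4469.0),  # accuracy+latency vs null
            (189.33, 200.72, 297.4),   # accuracy+latency vs accuracy
            (196.70, 206.14, 112.3),   # latency-only vs null
            (206.72, 206.14, 0.75),    # a model worse than the null
            (199.25, 206.72, 41.89),
        ],
    )
    def test_reproduces_reported_evidence_ratios(self, bic_a, bic_b, expected):
        assert ms.bayes_factor(bic_a, bic_b) == pytest.approx(expected, rel=0.01)

    def test_identity_antisymmetry_transitivity(self):
        assert ms.bayes_factor(123.4, 123.4) == 1.0
        a, b, c = 190.0, 197.3, 204.8
        assert ms.bayes_factor(a, b) * ms.bayes_factor(b, a) == pytest.approx(1.0)
        assert ms.bayes_factor(a, c) == pytest.approx(
            ms.bayes_factor(a, b) * ms.bayes_factor(b, c)
        )


class TestBestSubset:
    def test_all_32_subsets_of_five_predictors(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("ABCDE"))
        fits = ms.best_subset(X, ms.zscore(rng.standard_normal(40)), tuple("ABCDE"))
        assert len(fits) == 32
        assert fits == sorted(fits, key=lambda f: f.bic)

    def test_planted_two_predictor_model_recovered(self):
        # high SNR; 3 candidates so the BIC spurious-inclusion rate
        # (~2 Phi(-sqrt(ln n)) per extra predictor) leaves > 95% exact recovery
        rng = np.random.default_rng(3)
        hits = 0
        reps = 1000
        for _ in range(reps):
            X = pd.DataFrame(rng.standard_normal((70, 3)), columns=list("ABC"))
            y = ms.zscore(
                X["A"].to_numpy() + X["C"].to_numpy() + 0.3 * rng.standard_normal(70)
            )
            best = ms.best_subset(X, y, tuple("ABC"))[0]
            hits += set(best.predictors) == {"A", "C"}
        assert hits / reps >= 0.95

    def test_planted_predictors_always_included_among_five(self):
        rng = np.random.default_rng(4)
        included = 0
        reps = 200
        for _ in range(reps):
            X = pd.DataFrame(rng.standard_normal((70, 5)), columns=list("ABCDE"))
            y = ms.zscore(
                X["A"].to_numpy() + X["C"].to_numpy() + 0.3 * rng.standard_normal(70)
            )
            best = ms.best_subset(X, y, tuple("ABCDE"))[0]
            included += {"A", "C"} <= set(best.predictors)
        assert included / reps >= 0.99

    def test_pure_noise_prefers_null_model(self):
        rng = np.random.default_rng(5)
        nullbest = 0
        reps = 100
        for _ in range(reps):
            X = pd.DataFrame(rng.standard_normal((70, 5)), columns=list("ABCDE"))
            y = ms.zscore(rng.standard_normal(70))
            nullbest += ms.best_subset(X, y, tuple("ABCDE"))[0].predictors == ()
        assert nullbest / reps >= 0.80


class TestLooCv:
    def test_noiseless_linear_outcome_gives_unit_skill(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        y = 1.5 * X["a"].to_numpy() - 2.0 * X["b"].to_numpy() + 0.3
        cv, raw = ms.loo_cv(X, y, ("a", "b"))
        assert cv == pytest.approx(1.0, abs=1e-9)
        assert raw == pytest.approx(1.0, abs=1e-9)

    def test_unrelated_outcome_floors_at_zero(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
        cv, raw = ms.loo_cv(X, rng.standard_normal(40), ("a", "b"))
        assert cv == 0.0
        assert raw < 0.0

    def test_cohort_level_skill_in_plausible_band(self, feature_table_70):
        # accuracy + peak latency predicting the math-anxiety score: typical
        # out-of-sample skill across cohorts brackets the high-teens/twenties
        from pupilmath import synthgen as sg

        vals = []
        for s in range(8):
            tab = sg.cohort_table(
                sg.simulate_cohort(sg.CohortConfig(n_participants=70, seed=300 + s))
            )
            X = pd.DataFrame(
                {
                    "accuracy": tab["accuracy_trait"],
                    "peak_latency": (tab["easy_latency_s"] + tab["hard_latency_s"]) / 2,
                }
            )
            cv, _ = ms.loo_cv(
                X, ms.zscore(tab["amas"].to_numpy(float)), ("accuracy", "peak_latency")
            )
            vals.append(cv)
        assert 0.10 <= np.mean(vals) <= 0.35


class TestAdjR2FromF:
    @pytest.mark.parametrize(
        "f,u,v,expected",
        [(14.59, 2, 67, 0.28), (14.69, 1, 68, 0.17)],
    )
    def test_reported_model_fits(self, f, u, v, expected):
        _, adj = ms.adj_r2_from_f(f, u, v)
        assert adj == pytest.approx(expected, abs=0.005)

    def test_zero_f_algebra(self):
        r2, adj = ms.adj_r2_from_f(0.0, 1, 68)
        assert r2 == 0.0
        assert adj == pytest.approx(-1.0 / 68)


class TestPowerCurve:
    def test_monotone_in_n_and_consistent(self):
        grid = np.arange(10, 400, 10)
        curve = ms.power_curve(grid, 0.2, u=1)
        p = curve["power"].to_numpy()
        assert np.all(np.diff(p) >= -1e-12)
        assert p[-1] > 0.999

    def test_matches_monte_carlo_power(self):
        # fixed orthonormalized design, coefficients set for f^2 = 0.25
        n, u = 40, 2
        v = n - u - 1
        f2 = 0.25
        rng = np.random.default_rng(8)
        X = rng.standard_normal((n, u))
        X -= X.mean(0)
        Q, _ = np.linalg.qr(X)
        Xo = Q * np.sqrt(n)
        b = np.full(u, np.sqrt(f2 / u))
        reps = 20000
        Y = rng.standard_normal((reps, n)) + Xo @ b
        Xc = np.column_stack([np.ones(n), Xo])
        H = Xc @ np.linalg.inv(Xc.T @ Xc) @ Xc.T
        M = np.eye(n) - np.ones((n, n)) / n
        sse_full = np.einsum("rn,rn->r", Y @ (np.eye(n) - H), Y)
        sse_null = np.einsum("rn,rn->r", Y @ M, Y)
        F = ((sse_null - sse_full) / u) / (sse_full / v)
        mc = float(np.mean(F > stats.f.isf(0.05, u, v)))
        curve = ms.power_curve(np.array([n]), f2 / (1 + f2), u=u)
        assert curve["power"].iloc[0] == pytest.approx(mc, abs=0.01)

    def test_required_n_reaches_target(self):
        n80 = ms.required_n(0.2, u=1)
        curve = ms.power_curve(np.array([n80 - 1, n80]), 0.2, u=1)
        assert curve["power"].iloc[1] >= 0.80 > curve["power"].iloc[0]


def test_rank_models_table_mirrors_fits(feature_table_70):
    rep = ms.rank_models(
        feature_table_70, "amas",
        predictors=("accuracy", "pmp", "baseline_ps", "max_dilation", "peak_latency"),
    )
    assert len(rep.fits) == 32
    assert rep.table["bic"].is_monotonic_increasing
    assert rep.best.bic == rep.table["bic"].iloc[0]
    bf = rep.bf_matrix(top=5)
    np.testing.assert_allclose(bf.to_numpy() * bf.to_numpy().T, 1.0, atol=1e-9)


def test_outcome_zscoring_uses_sample_sd(feature_table_70):
    y = ms.zscore(feature_table_70["amas"].to_numpy(float))
    assert y.mean() == pytest.approx(0.0, abs=1e-12)
    assert y.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
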