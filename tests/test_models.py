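import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskstrat import (
    CohortTable,
    EffectSet,
    GAConfig,
    GlmFit,
    anova_deviance,
    build_design,
    default_candidate_effects,
    exhaustive_oracle,
    fit_logistic_glm,
    ga_search,
    pearson_correlation,
)


def intercept_only_fit(n_events, n_total):
    y = np.r_[np.ones(n_events), np.zeros(n_total - n_events)]
    X = pd.DataFrame({"Intercept": np.ones(n_total)})
    return fit_logistic_glm(X, y)


def small_cohort(n=250, seed=0, betas=(-1.5, 0.9, 0.0)):
    """Logistic cohort: outcome depends on ln eNAPRT, not on CRP."""
    rng = np.random.default_rng(seed)
    x1 = rng.lognormal(np.log(27.1), 1.0, n)
    x2 = rng.lognormal(np.log(185), 0.6, n)
    eta = betas[0] + betas[1] * (np.log(x1) - np.log(27.1)) \
        + betas[2] * (np.log(x2) - np.log(185))
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "outcome": y,
            "eNAPRT": x1,
            "CRP": x2,
        }
    )
    return CohortTable(df, ["eNAPRT", "CRP"])


class TestEffectSet:
    def test_marginality_enforced_at_construction(self):
        cands = ("A", "B", "A:B")
        with pytest.raises(ValueError, match="marginality"):
            EffectSet(cands, (1, 0, 1))
        EffectSet(cands, (1, 1, 1))  # valid

    def test_repair_drops_orphan_interactions(self):
        es = EffectSet.repair(("A", "B", "A:B"), (0, 1, 1))
        assert es.effects == ("B",)


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        # 34 events / 66 non-events: beta0 = ln(34/66), BIC = -2 llf + ln 100
        fit = intercept_only_fit(34, 100)
        assert fit.params["Intercept"] == pytest.approx(np.log(34 / 66), abs=1e-6)
        assert fit.loglik == pytest.approx(
            34 * np.log(0.34) + 66 * np.log(0.66), abs=1e-6
        )
        assert fit.bic == pytest.approx(132.81, abs=0.01)
        assert fit.k == 1 and fit.converged

    def test_balanced_outcomes_give_zero_intercept(self):
        fit = intercept_only_fit(50, 100)
        assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_bic_rederivable_from_parts(self):
        cohort = small_cohort()
        X, y = build_design(cohort, ("eNAPRT", "CRP"))
        fit = fit_logistic_glm(X, y)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.k * np.log(fit.n), rel=1e-12
        )

    def test_score_equations_hold_at_convergence(self):
        cohort = small_cohort()
        X, y = build_design(cohort, ("eNAPRT", "CRP"))
        fit = fit_logistic_glm(X, y)
        eta = X.to_numpy() @ fit.params.to_numpy()
        fitted = 1 / (1 + np.exp(-eta))
        score = X.to_numpy().T @ (y.to_numpy() - fitted)
        assert np.max(np.abs(score)) < 1e-6

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(99)
        n = 5000
        x = rng.standard_normal(n)
        eta = -2.0 + 1.0 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x})
        fit = fit_logistic_glm(X, y)
        for name, truth in (("Intercept", -2.0), ("x", 1.0)):
            assert abs(fit.params[name] - truth) < 3 * fit.bse[name]

    def test_rank_deficient_design_names_columns(self):
        n = 50
        x = np.arange(n, dtype=float)
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2"):
            fit_logistic_glm(X, np.r_[np.ones(25), np.zeros(25)])

    def test_separation_flagged(self):
        n = 60
        x = np.r_[np.linspace(-3, -1, 30), np.linspace(1, 3, 30)]
        y = np.r_[np.zeros(30), np.ones(30)]
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x})
        fit = fit_logistic_glm(X, y)
        assert fit.separation


class TestAnovaDeviance:
    def _fit_pair(self):
        cohort = small_cohort(seed=1)
        X1, y = build_design(cohort, ("eNAPRT",))
        X2, _ = build_design(cohort, ("eNAPRT", "CRP"))
        return fit_logistic_glm(X1, y), fit_logistic_glm(X2, y)

    def test_identical_models_give_p_one(self):
        nested, _ = self._fit_pair()
        assert anova_deviance(nested, nested) == 1.0

    def test_chi2_upper_tail_closed_forms(self):
        # delta-deviance 10.83 on 1 df ~ 0.001; 3.84 on 1 df ~ 0.05
        assert stats.chi2.sf(10.83, 1) == pytest.approx(0.001, abs=5e-5)
        nested, full = self._fit_pair()
        p = anova_deviance(nested, full)
        assert p == pytest.approx(
            stats.chi2.sf(nested.deviance - full.deviance, 1), rel=1e-12
        )
        assert nested.deviance - full.deviance >= -1e-6

    def test_non_nested_pair_rejected(self):
        cohort = small_cohort(seed=2)
        Xa, y = build_design(cohort, ("eNAPRT",))
        Xb, _ = build_design(cohort, ("CRP",))
        fa, fb = fit_logistic_glm(Xa, y), fit_logistic_glm(Xb, y)
        with pytest.raises(ValueError, match="nested"):
            anova_deviance(fa, fb)


class TestExhaustiveOracle:
    def test_two_mains_give_four_models(self):
        cohort = small_cohort(seed=3)
        res = exhaustive_oracle(cohort, ("eNAPRT", "CRP"))
        assert len(res.ranked) == 4

    def test_marginality_prunes_subsets(self):
        cohort = small_cohort(seed=3)
        res = exhaustive_oracle(
            cohort, ("eNAPRT", "CRP", "eNAPRT:CRP"), top_k=10
        )
        # 8 raw subsets minus the 3 with an orphan interaction
        assert len(res.ranked) == 5

    def test_zero_candidates_fit_intercept_only(self):
        cohort = small_cohort(seed=3)
        res = exhaustive_oracle(cohort, ())
        assert len(res.ranked) == 1
        assert res.best[0].effects == ()

    def test_ranking_strictly_ordered_by_bic(self):
        cohort = small_cohort(seed=4)
        res = exhaustive_oracle(cohort, ("eNAPRT", "CRP", "eNAPRT:CRP"))
        bics = [fit.bic for _, fit in res.ranked]
        assert bics == sorted(bics)


class TestGASearch:
    candidates = default_candidate_effects("eNAPRT", ("CRP",))  # 3 effects

    def test_determinism_contract(self):
        cohort = small_cohort(seed=5)
        r1 = ga_search(cohort, self.candidates, seed=7)
        r2 = ga_search(cohort, self.candidates, seed=7)
        assert [es.inclusion for es, _ in r1.ranked] == [
            es.inclusion for es, _ in r2.ranked
        ]
        assert r1.trace == r2.trace

    def test_empty_candidates_return_intercept_only(self):
        cohort = small_cohort(seed=5)
        res = ga_search(cohort, (), seed=0)
        assert res.best[0].effects == ()

    def test_matches_exhaustive_oracle(self):
        cohort = small_cohort(seed=6)
        oracle = exhaustive_oracle(cohort, self.candidates)
        ga = ga_search(cohort, self.candidates, seed=11)
        assert ga.best[1].bic == pytest.approx(oracle.best[1].bic, rel=1e-12)

    def test_best_never_worse_than_seeded_extremes(self):
        cohort = small_cohort(seed=8)
        res = ga_search(cohort, self.candidates, seed=3)
        bics = {es.inclusion: fit.bic for es, fit in res.ranked}
        full = EffectSet.repair(tuple(self.candidates),
                                [1] * len(self.candidates))
        best_bic = res.best[1].bic
        intercept = exhaustive_oracle(cohort, ()).best[1].bic
        assert best_bic <= intercept + 1e-9
        if full.inclusion in bics:
            assert best_bic <= bics[full.inclusion] + 1e-9

    def test_trace_monotone_non_increasing(self):
        cohort = small_cohort(seed=9)
        res = ga_search(cohort, self.candidates, seed=5,
                        config=GAConfig(generations=20))
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_p_from_t_transform(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        res = pearson_correlation(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), res.n - 2),
                                      rel=1e-9)

    def test_copula_pairs_near_target_at_cohort_scale(self):
        from riskstrat import generate_cohort, sepsis_default_config

        cohort = generate_cohort(sepsis_default_config(n=92), seed=13)
        res = pearson_correlation(cohort.data["CRP"], cohort.data["eNAPRT"])
        assert res.r == pytest.approx(0.31, abs=0.15)
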