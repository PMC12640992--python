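import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from panfuse.io import ExpressionMatrix, SurvivalTable
from panfuse.survival import (
    PrognosticModel,
    RiskModel,
    cindex,
    cox_screen,
    km_curve,
    km_stratify,
    logrank_statistic,
    maxstat_cutoff,
    risk_score,
    rsf_fit,
)
from panfuse.synth import SimulationConfig, simulate_expression, simulate_survival


def cohort_with_signal(seed=0, n=200, p=10, coef=np.log(2), censor=0.2):
    cfg = SimulationConfig(
        n_samples=n, n_genes=p, n_informative=0, effect_size=0.0, seed=seed
    )
    X, _, _ = simulate_expression(cfg)
    surv = simulate_survival(
        X, ["G0001"], [coef], baseline_rate=0.1, censor_rate=censor, seed=seed + 1
    )
    return X, surv


class TestCoxScreen:
    def test_coefficient_recovery_small(self):
        # single run sanity; the multi-replicate recovery lives in acceptance
        X, surv = cohort_with_signal(seed=3, n=500)
        screen = cox_screen(X, surv)
        row = screen[screen["gene"] == "G0001"].iloc[0]
        assert abs(row["coef"] - np.log(2)) < 0.2
        assert row["significant"]
        np.testing.assert_allclose(row["hr"], np.exp(row["coef"]), rtol=1e-9)

    def test_constant_gene_gets_na_row(self):
        X, surv = cohort_with_signal(seed=4, n=80)
        values = X.values.copy()
        values[2, :] = 1.0
        Xc = ExpressionMatrix(X.gene_ids, X.sample_ids, values)
        screen = cox_screen(Xc, surv)
        row = screen[screen["gene"] == "G0003"].iloc[0]
        assert row["na"] and not row["significant"]

    def test_too_few_events_rejected(self):
        X, surv = cohort_with_signal(seed=5, n=30)
        few = SurvivalTable(surv.sample_ids, surv.time, np.zeros(surv.n, int))
        few.event[:5] = 1
        with pytest.raises(ValueError):
            cox_screen(X, few)

    def test_disjoint_samples_rejected(self):
        X, surv = cohort_with_signal(seed=6, n=50)
        other = SurvivalTable(["zz1", "zz2"], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            cox_screen(X, other)


class TestRiskScore:
    def _model(self, genes, coefs):
        return RiskModel(
            genes=genes, coefs=np.asarray(coefs, float),
            baseline_times=np.array([1.0]), baseline_cumhaz=np.array([0.1]),
        )

    def test_zero_coefficients_score_one(self):
        X, _ = cohort_with_signal(seed=7, n=20)
        model = self._model(["G0001", "G0002"], [0.0, 0.0])
        np.testing.assert_array_equal(risk_score(model, X), np.ones(20))

    def test_single_gene_doubling(self):
        X = ExpressionMatrix(["g"], ["a", "b"], np.array([[1.0, 0.0]]))
        model = self._model(["g"], [np.log(2)])
        s = risk_score(model, X)
        assert s[0] / s[1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(8)
        X, _ = cohort_with_signal(seed=8, n=30)
        coefs = rng.standard_normal(3)
        model = self._model(["G0001", "G0005", "G0009"], coefs)
        scores = risk_score(model, X)
        sub = X.subset_genes(["G0001", "G0005", "G0009"]).values
        expected = np.exp(np.array([coefs @ sub[:, j] for j in range(30)]))
        np.testing.assert_allclose(scores, expected, rtol=1e-9)

    def test_missing_gene_named(self):
        X, _ = cohort_with_signal(seed=9, n=10)
        model = self._model(["NOPE"], [1.0])
        with pytest.raises(KeyError, match="NOPE"):
            risk_score(model, X)


class TestMaxstat:
    def test_matches_exhaustive_enumeration_via_lifelines(self):
        X, surv = cohort_with_signal(seed=10, n=60)
        scores = np.exp(0.7 * X.values[0])
        result = maxstat_cutoff(scores, surv, min_prop=0.1)
        # independent oracle: lifelines chi2 -> standardized stat per candidate
        uniq = np.unique(scores)
        best_stat, best_cut = -1.0, None
        n = len(scores)
        for c in (uniq[:-1] + uniq[1:]) / 2:
            high = scores > c
            if high.sum() < 6 or (~high).sum() < 6:
                continue
            lr = logrank_test(
                surv.time[high], surv.time[~high], surv.event[high], surv.event[~high]
            )
            stat = np.sqrt(lr.test_statistic)
            if stat > best_stat + 1e-12:
                best_stat, best_cut = stat, c
        assert result.cutoff == pytest.approx(best_cut)
        assert result.statistic == pytest.approx(best_stat, abs=1e-9)

    def test_planted_threshold_recovered(self):
        rng = np.random.default_rng(11)
        n = 200
        scores = np.concatenate([rng.uniform(0, 9.5, n // 2), rng.uniform(10.5, 20, n // 2)])
        group = (scores > 10).astype(int)
        lam = np.where(group == 1, 0.4, 0.1)
        time = rng.exponential(1 / lam)
        surv = SurvivalTable([f"s{i}" for i in range(n)], time, np.ones(n, int))
        result = maxstat_cutoff(scores, surv)
        uniq = np.sort(np.unique(scores))
        grid = np.diff(uniq).max()
        assert abs(result.cutoff - 10.0) <= max(grid, 1.0)

    def test_constant_scores_rejected(self, simple_survival):
        with pytest.raises(ValueError):
            maxstat_cutoff(np.ones(4), simple_survival)

    def test_min_prop_admissibility(self, simple_survival):
        # only cutoffs keeping >= 40% of 4 samples (2 per side) are admissible
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        result = maxstat_cutoff(scores, simple_survival, min_prop=0.4)
        assert (result.candidates["cutoff"] == [2.5]).all()


class TestKaplanMeier:
    def test_four_event_product_limit_steps(self, simple_survival):
        curve = km_curve(simple_survival)
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == pytest.approx(0.75)
        assert lookup[2.0] == pytest.approx(0.50)
        assert lookup[3.0] == pytest.approx(0.25)
        assert lookup[4.0] == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        surv = SurvivalTable(["a", "b", "c"], [1.0, 2.0, 3.0], [0, 0, 0])
        curve = km_curve(surv)
        assert (curve["survival"] == 1.0).all()

    def test_censored_fixture_matches_hand_product_limit(self):
        # 10 samples, censoring interleaved; hand product-limit oracle
        time = np.array([1, 2, 2, 3, 4, 4, 5, 6, 7, 8], dtype=float)
        event = np.array([1, 1, 0, 1, 0, 1, 1, 0, 1, 0])
        surv = SurvivalTable([f"s{i}" for i in range(10)], time, event)
        curve = km_curve(surv)
        lookup = dict(zip(curve["time"], curve["survival"]))

        def hand_km(t_eval):
            s = 1.0
            for t in sorted(set(time[event == 1])):
                if t > t_eval:
                    break
                at_risk = (time >= t).sum()
                deaths = ((time == t) & (event == 1)).sum()
                s *= 1 - deaths / at_risk
            return s

        for t in sorted(set(time)):
            assert lookup[t] == pytest.approx(hand_km(t), abs=1e-12)

    def test_km_curve_monotone_from_one(self):
        X, surv = cohort_with_signal(seed=12, n=100)
        curve = km_curve(surv)
        s = curve["survival"].to_numpy()
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()

    def test_stratify_groups_and_logrank(self):
        X, surv = cohort_with_signal(seed=13, n=100)
        scores = np.exp(0.7 * X.values[0])
        strat = km_stratify(scores, float(np.median(scores)), surv)
        assert set(strat.group) == {"high", "low"}
        assert ((strat.group == "high") == (scores > np.median(scores))).all()
        assert 0 <= strat.logrank_p <= 1

    def test_empty_group_rejected(self, simple_survival):
        with pytest.raises(ValueError):
            km_stratify(np.array([1, 2, 3, 4.0]), 10.0, simple_survival)

    def test_logrank_statistic_matches_lifelines(self):
        X, surv = cohort_with_signal(seed=14, n=80)
        group = (X.values[0] > 0).astype(int)
        stat = logrank_statistic(surv.time, surv.event, group)
        lr = logrank_test(
            surv.time[group == 1], surv.time[group == 0],
            surv.event[group == 1], surv.event[group == 0],
        )
        assert stat**2 == pytest.approx(lr.test_statistic, rel=1e-9)


class TestCindex:
    def test_perfect_ordering_gives_one(self):
        time = np.array([4.0, 3.0, 2.0, 1.0])
        surv = SurvivalTable(list("abcd"), time, np.ones(4, int))
        assert cindex(np.array([1.0, 2.0, 3.0, 4.0]), surv) == 1.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(15)
        n = 200
        time = rng.exponential(5, n)
        event = (rng.random(n) < 0.7).astype(int)
        scores = rng.standard_normal(n)
        scores[:20] = scores[20:40]  # inject ties
        surv = SurvivalTable([f"s{i}" for i in range(n)], time, event)

        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                usable = (time[i] < time[j] and event[i] == 1) or (
                    time[i] == time[j] and event[i] == 1 and event[j] == 0
                )
                if not usable:
                    continue
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
        assert cindex(scores, surv) == pytest.approx(num / den, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(16)
        n = 2000
        surv = SurvivalTable(
            [f"s{i}" for i in range(n)], rng.exponential(5, n),
            (rng.random(n) < 0.8).astype(int),
        )
        assert abs(cindex(rng.standard_normal(n), surv) - 0.5) <= 0.05

    def test_invariant_under_monotone_transform(self):
        X, surv = cohort_with_signal(seed=17, n=120)
        scores = np.exp(0.5 * X.values[0])
        assert cindex(scores, surv) == cindex(np.log(scores) * 3 + 7, surv)

    def test_no_comparable_pairs_rejected(self):
        surv = SurvivalTable(["a", "b"], [1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            cindex(np.array([1.0, 2.0]), surv)


@pytest.fixture(scope="module")
def prognostic_cohort():
    cfg = SimulationConfig(
        n_samples=150, n_genes=20, n_informative=0, effect_size=0.0, seed=20
    )
    X, _, _ = simulate_expression(cfg)
    surv = simulate_survival(
        X, ["G0001", "G0002", "G0003"], [0.9, -0.9, 0.9],
        baseline_rate=0.1, censor_rate=0.2, seed=21,
    )
    return X, surv


@pytest.fixture(scope="module")
def fitted_prognosis():
    cfg = SimulationConfig(
        n_samples=200, n_genes=25, n_informative=0, effect_size=0.0, seed=30
    )
    X, _, _ = simulate_expression(cfg)
    surv = simulate_survival(
        X, ["G0001", "G0002", "G0003"], [0.8, -0.8, 0.8],
        baseline_rate=0.1, censor_rate=0.2, seed=31,
    )
    res = PrognosticModel(X, surv, top_m=5, n_trees=150, seed=0).fit()
    return X, surv, res


class TestRSF:

    def test_planted_genes_rank_high(self, prognostic_cohort):
        X, surv = prognostic_cohort
        fit = rsf_fit(X, surv, n_trees=200, seed=0)
        assert {"G0001", "G0002", "G0003"} <= set(fit.ranking[:10])

    def test_oob_error_improves_with_trees(self, prognostic_cohort):
        X, surv = prognostic_cohort
        fit = rsf_fit(X, surv, n_trees=200, seed=0)
        traj = fit.oob_trajectory
        assert traj["oob_error"].iloc[-1] <= traj["oob_error"].iloc[0] + 0.02

    def test_seed_determinism(self, prognostic_cohort):
        X, surv = prognostic_cohort
        f1 = rsf_fit(X, surv, n_trees=100, seed=5)
        f2 = rsf_fit(X, surv, n_trees=100, seed=5)
        assert f1.ranking == f2.ranking

    def test_all_censored_rejected(self, prognostic_cohort):
        X, surv = prognostic_cohort
        dead = SurvivalTable(surv.sample_ids, surv.time, np.zeros(surv.n, int))
        with pytest.raises(ValueError):
            rsf_fit(X, dead, n_trees=100, seed=0)


class TestPrognosticModel:
    def test_chain_uses_only_screened_genes(self, fitted_prognosis):
        _, _, res = fitted_prognosis
        sig = set(res.screen.loc[res.screen["significant"], "gene"])
        assert set(res.risk_model.genes) <= sig

    def test_high_risk_group_has_more_events(self, fitted_prognosis):
        _, surv, res = fitted_prognosis
        high = res.stratification.group == "high"
        assert surv.event[high].mean() > surv.event[~high].mean()

    def test_cindex_reasonable_on_planted_signal(self, fitted_prognosis):
        _, _, res = fitted_prognosis
        assert res.cindex > 0.6

    def test_summary_renders(self, fitted_prognosis):
        _, _, res = fitted_prognosis
        text = res.summary()
        assert "concordance index" in text and "maxstat cutoff" in text

    def test_cutoff_within_score_range(self, fitted_prognosis):
        _, _, res = fitted_prognosis
        assert res.scores.min() < res.risk_model.cutoff < res.scores.max()

    def test_baseline_hazard_monotone(self, fitted_prognosis):
        _, _, res = fitted_prognosis
        H = res.risk_model.baseline_cumhaz
        assert (np.diff(H) >= -1e-12).all()


class TestRiskFunctionComposition:
    def test_cumulative_hazard_matches_cox_prediction(self, fitted_prognosis):
        # H(t|x) = H0(t) * exp(coef . x) must reproduce the proportional-
        # hazards prediction of an identical multivariable Cox fit
        X, surv, res = fitted_prognosis
        rm = res.risk_model
        from lifelines import CoxPHFitter

        df = pd.DataFrame(X.subset_genes(rm.genes).values.T, columns=rm.genes)
        df["time"] = surv.time
        df["event"] = surv.event
        cph = CoxPHFitter().fit(df, "time", "event")
        tm = float(rm.baseline_times[len(rm.baseline_times) // 2])
        expected = cph.predict_cumulative_hazard(
            df[rm.genes].iloc[:5], times=[tm]
        ).to_numpy()[0]
        got = rm.cumulative_hazard(tm, X.subset_samples(X.sample_ids[:5]))[0]
        np.testing.assert_allclose(got, expected, rtol=1e-6)
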