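import numpy as np
import pytest

from _oracles import cox_grid_search, km_product_limit, logrank_observed_expected
from episyn.core_data import CARRIER_MINOR, GenotypeCombination
from episyn.survival_followup import (
    classify_carriers,
    cox_hr,
    kaplan_meier,
    logrank_test,
    survival_screen,
)
from episyn.synthetic_data import (
    SimConfig,
    SurvivalEffect,
    simulate_study,
    survival_combination,
)


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        km = kaplan_meier([5, 10, 15], [0, 0, 0])
        assert np.all(km["survival"] == 1.0)

    def test_three_deaths_closed_form(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1])
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_mixed_censoring_matches_product_limit_oracle(self):
        times = [3, 5, 5, 8, 12, 16]
        events = [1, 1, 0, 1, 0, 1]
        km = kaplan_meier(times, events)
        t_o, s_o = km_product_limit(times, events)
        got = dict(zip(km["time"], km["survival"]))
        for t, s in zip(t_o, s_o):
            assert got[t] == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(30, size=50).round() + 1
        km = kaplan_meier(times, np.ones(50))
        for t, s in zip(km["time"], km["survival"]):
            if t > 0:
                assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [2, 4, 6, 8]
        e = [1, 1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_observed_minus_expected_oracle(self):
        ta, ea = [1, 3, 5, 7], [1, 1, 1, 0]
        tb, eb = [2, 4, 6, 8], [1, 0, 1, 1]
        chi2, _ = logrank_test(ta, ea, tb, eb)
        assert chi2 == pytest.approx(
            logrank_observed_expected(ta, ea, tb, eb), abs=1e-9
        )

    def test_power_against_hazard_ratio_two(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(20, 200)
            tb = rng.exponential(40, 200)
            c = rng.uniform(10, 80, 400)
            ea = (ta <= c[:200]).astype(int)
            eb = (tb <= c[200:]).astype(int)
            _, p = logrank_test(
                np.minimum(ta, c[:200]), ea, np.minimum(tb, c[200:]), eb
            )
            rejections += p < 0.05
        assert rejections > 90

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestCoxHr:
    def test_matches_grid_search_oracle_on_toy_data(self):
        times = [2, 3, 5, 7, 8, 11, 13, 17, 19, 23]
        events = [1, 1, 0, 1, 1, 1, 0, 1, 1, 1]
        x = [1, 0, 1, 1, 0, 0, 1, 0, 1, 0]
        hr, _ = cox_hr(times, events, x)
        assert hr == pytest.approx(cox_grid_search(times, events, x), abs=1e-4)

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(4)
        n = 120
        x = rng.integers(0, 2, n)
        t = rng.exponential(np.where(x, 20, 35))
        t += rng.uniform(0, 1e-6, n)  # enforce no ties so Efron == Breslow
        c = rng.uniform(5, 90, n)
        e = (t <= c).astype(int)
        obs = np.minimum(t, c)
        hr, (lo, hi) = cox_hr(obs, e, x)
        df = pd.DataFrame({"t": obs, "e": e, "x": x})
        fit = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert hr == pytest.approx(float(np.exp(fit.params_["x"])), rel=1e-4)

    def test_null_coverage_of_wald_interval(self):
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 150
            x = rng.integers(0, 2, n)
            t = rng.exponential(30, n)
            c = rng.uniform(10, 90, n)
            e = (t <= c).astype(int)
            _, (lo, hi) = cox_hr(np.minimum(t, c), e, x)
            covered += lo <= 1.0 <= hi
        assert 89 <= covered <= 99

    def test_complete_separation_raises(self):
        # all events in the carrier group -> monotone likelihood
        times = [1, 2, 3, 10, 11, 12]
        events = [1, 1, 1, 0, 0, 0]
        x = [1, 1, 1, 0, 0, 0]
        with pytest.raises(ValueError, match="separation|monotone"):
            cox_hr(times, events, x)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="event"):
            cox_hr([1, 2], [0, 0], [0, 1])


class TestClassifyCarriers:
    def test_manual_classification_on_tiny_study(self, tiny_study):
        comb = GenotypeCombination(
            loci=(("rs1", CARRIER_MINOR),), label="rs1 carriers"
        )
        match, decidable = classify_carriers(tiny_study, comb)
        # cases: s0 (rs1=0) noncarrier, s1 (rs1=1) carrier, s2 (rs1=2) carrier
        assert list(match) == [False, True, True]
        assert list(decidable) == [True, True, True]

    def test_missing_locus_excluded(self, tiny_study):
        comb = GenotypeCombination(
            loci=(("rs2", frozenset({1})), ("rs3", frozenset({2})))
        )
        match, decidable = classify_carriers(tiny_study, comb)
        assert not decidable[2]  # s2 missing rs2
        assert list(match) == [True, False, False]

    def test_universal_combination_rejected(self, tiny_study):
        comb = GenotypeCombination(loci=(("rs1", frozenset({0, 1, 2})),))
        with pytest.raises(ValueError, match="contrast"):
            classify_carriers(tiny_study, comb)


class TestSurvivalScreen:
    def test_sex_specific_protective_combination_detected(self):
        # protective carrier effect planted; with a strong HR the female
        # stratum (71% of cases) flags it far more often than chance
        cfg = SimConfig(
            n_cases=800,
            n_controls=100,
            panel=(("IIS", 6),),
            survival_effects=(
                SurvivalEffect(
                    loci=(0,), conditions=(frozenset({1, 2}),), hazard_ratio=0.5
                ),
            ),
            censor_window=(24.0, 120.0),
            missing_rate=0.0,
            seed=31,
        )
        study, _, truth = simulate_study(cfg)
        comb = survival_combination(truth.survival[0])
        results = survival_screen(study, [comb])
        by_stratum = {r.stratum: r for r in results}
        assert set(by_stratum) == {"male", "female"}
        f = by_stratum["female"]
        assert f.hr < 1.0
        assert f.significant

    def test_empty_combination_list_gives_empty_result(self, tiny_study):
        assert survival_screen(tiny_study, []) == []

    def test_km_curves_start_at_one_and_decrease(self):
        cfg = SimConfig(
            n_cases=200,
            n_controls=50,
            panel=(("IIS", 4),),
            missing_rate=0.0,
            seed=5,
        )
        study, _, _ = simulate_study(cfg)
        comb = GenotypeCombination(
            loci=((study.snp_ids[0], CARRIER_MINOR),), label="c"
        )
        results = survival_screen(study, [comb], strata=("all",))
        assert len(results) == 1
        for curve in results[0].km_curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert np.all(np.diff(s) <= 1e-12)

    def test_logrank_p_agrees_with_permutation_reference(self):
        # chi-square log-rank p vs a label-permutation reference on toy data
        rng = np.random.default_rng(7)
        t = np.concatenate([rng.exponential(15, 40), rng.exponential(30, 40)])
        c = rng.uniform(5, 60, 80)
        e = (t <= c).astype(int)
        obs = np.minimum(t, c).round() + 1
        groups = np.array([0] * 40 + [1] * 40)
        chi2, p = logrank_test(
            obs[groups == 0], e[groups == 0], obs[groups == 1], e[groups == 1]
        )
        n_perm = 2000
        b = 0
        for _ in range(n_perm):
            gp = rng.permutation(groups)
            stat = logrank_observed_expected(
                obs[gp == 0], e[gp == 0], obs[gp == 1], e[gp == 1]
            )
            b += stat >= chi2 - 1e-12
        p_perm = (b + 1) / (n_perm + 1)
        se = np.sqrt(p * (1 - p) / n_perm)
        assert abs(p_perm - p) < max(4 * se, 0.01)
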