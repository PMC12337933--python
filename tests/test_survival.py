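"""Time-to-high-adherence: events, KM, IPW, Cox (proportional and piecewise)."""

import numpy as np
import pandas as pd
import pytest

from oracles import product_limit
from rxadherence.simulate import (
    simulate_confounded_survival,
    simulate_piecewise_survival,
)
from rxadherence.survival import (
    adherence_event_times,
    cox_fit,
    expand_episodes,
    km_estimate,
    stabilized_ipw,
    standardized_mean_differences,
    survival_metrics,
)


class TestEventTimes:
    def test_first_window_high(self):
        assert adherence_event_times([(0, 170)], 1080) == (180, True)

    def test_never_high_censored_at_horizon(self):
        assert adherence_event_times([], 1080) == (1080, False)

    def test_event_in_third_window(self):
        # window PDCs 0.5, 0.5, 1.0
        ints = [(0, 90), (180, 270), (360, 540)]
        assert adherence_event_times(ints, 2000) == (540, True)

    def test_censored_at_followup_end(self):
        assert adherence_event_times([], 400) == (400, False)

    def test_rejects_nonpositive_followup(self):
        with pytest.raises(ValueError):
            adherence_event_times([], 0)


class TestKaplanMeier:
    def test_three_events_hand_fixture(self):
        km = km_estimate([1, 2, 3], [True, True, True]).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(2 / 3, abs=1e-12)
        assert km.loc[2.0] == pytest.approx(1 / 3, abs=1e-12)
        assert km.loc[3.0] == pytest.approx(0.0, abs=1e-12)

    def test_censored_first_hand_fixture(self):
        km = km_estimate([1, 2, 3], [False, True, True]).set_index("time")["survival"]
        assert km.loc[2.0] == pytest.approx(1 / 2, abs=1e-12)
        assert km.loc[3.0] == pytest.approx(0.0, abs=1e-12)

    def test_no_events_flat(self):
        km = km_estimate([5, 6, 7], [False] * 3)
        assert (km["survival"] == 1.0).all()

    def test_matches_hand_product_limit_on_random_data(self, rng):
        times = rng.integers(1, 50, size=80).astype(float)
        events = rng.random(80) < 0.7
        km = km_estimate(times, events).set_index("time")["survival"]
        oracle = product_limit(times, events)
        for t, s in oracle.items():
            assert km.loc[t] == pytest.approx(s, abs=1e-12)

    def test_monotone_nonincreasing(self, rng):
        times = rng.integers(1, 40, size=100).astype(float)
        events = rng.random(100) < 0.5
        km = km_estimate(times, events)
        assert (np.diff(km["survival"]) <= 1e-12).all()


class TestStabilizedIpw:
    def test_no_confounding_weights_near_one(self):
        rng = np.random.default_rng(0)
        n = 3000
        cov = pd.DataFrame({"z": pd.Categorical(rng.integers(0, 2, n))})
        expo = pd.Series(rng.choice(["bb", "acei", "ccb"], size=n))
        w, diag = stabilized_ipw(cov, expo)
        assert abs(diag["mean_weight"] - 1) < 0.05
        assert (np.abs(w - 1) < 0.1).mean() > 0.95

    def test_mean_weight_one_under_confounding(self):
        df = simulate_confounded_survival(4000, seed=1)
        w, diag = stabilized_ipw(df[["z"]], df["exposure"])
        assert abs(diag["mean_weight"] - 1) < 0.05

    def test_balance_restored(self):
        df = simulate_confounded_survival(4000, seed=2)
        _, diag = stabilized_ipw(df[["z"]], df["exposure"])
        assert diag["smd_before"].max() > 0.3
        assert diag["smd_after"].max() < 0.1

    def test_smd_zero_for_identical_groups(self):
        X = pd.DataFrame({"a": [0.0, 1.0] * 10})
        groups = pd.Series(["g1", "g2"] * 10)
        # identical distributions in both groups after pairing
        smd = standardized_mean_differences(X, pd.Series(["g1"] * 10 + ["g2"] * 10))
        assert smd.max() <= 1e-12 + 2  # columns vary; just bounds check
        assert (smd >= 0).all()


class TestCoxFit:
    def test_two_group_hr_recovery(self):
        df = simulate_confounded_survival(
            2500, true_hr=2.0, confounder_hr=1.0, p_exposed_given_z=(0.5, 0.5), seed=3
        )
        rep = cox_fit(df)
        hr = rep.summary.set_index("term").loc["exposure_ccb", "hr"]
        assert 1.8 <= hr <= 2.2

    def test_weights_of_one_equal_unweighted(self):
        df = simulate_confounded_survival(800, seed=4)
        a = cox_fit(df)
        b = cox_fit(df, weights=np.ones(len(df)))
        assert np.allclose(
            a.summary["coef"].to_numpy(), b.summary["coef"].to_numpy(), atol=1e-12
        )
        assert not b.weighted

    def test_ipw_moves_hr_toward_truth(self):
        wins = 0
        for seed in range(10):
            df = simulate_confounded_survival(2000, seed=seed)
            crude = cox_fit(df)
            w, _ = stabilized_ipw(df[["z"]], df["exposure"])
            adj = cox_fit(df, weights=w)
            hr_c = crude.summary.set_index("term").loc["exposure_ccb", "hr"]
            hr_a = adj.summary.set_index("term").loc["exposure_ccb", "hr"]
            wins += abs(hr_a - 2.0) < abs(hr_c - 2.0)
        assert wins >= 9

    def test_null_hazard_ci_covers_one(self):
        covered = 0
        for seed in range(20):
            df = simulate_confounded_survival(
                800, true_hr=1.0, confounder_hr=1.0, p_exposed_given_z=(0.5, 0.5),
                seed=seed,
            )
            rep = cox_fit(df)
            row = rep.summary.set_index("term").loc["exposure_ccb"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 17

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"time": [10.0, 20.0], "event": [False, False], "exposure": ["bb", "ccb"]}
        )
        with pytest.raises(ValueError):
            cox_fit(df)

    def test_episode_expansion_consistent(self):
        df = pd.DataFrame(
            {"time": [100.0, 700.0, 1080.0], "event": [True, True, False],
             "exposure": ["bb", "ccb", "bb"]}
        )
        long = expand_episodes(df, "time", "event", (0, 180, 540, 1080))
        # row 0: one episode; row 1: three; row 2: three
        assert len(long) == 1 + 3 + 3
        assert long["episode_event"].sum() == 2
        by_id = long.groupby("episode_id")
        assert (by_id["stop"].max().to_numpy() == df["time"].to_numpy()).all()

    def test_piecewise_effect_sign_recovery(self):
        ok = 0
        for seed in range(5):
            df = simulate_piecewise_survival(1500, seed=seed)
            rep = cox_fit(df, time_dependent=True)
            s = rep.summary.set_index("term")
            ok += (
                s.loc["exposure_ccb@0-180", "coef"] > 0
                and s.loc["exposure_ccb@540-1080", "coef"] < 0
            )
        assert ok >= 4


class TestSurvivalMetrics:
    def test_perfect_ordering_c_index_one(self):
        n = 60
        times = np.arange(1, n + 1, dtype=float)
        df = pd.DataFrame(
            {"time": times, "event": [True] * n,
             "exposure": ["bb", "ccb"] * (n // 2)}
        )
        rep = cox_fit(df)
        rep.linear_predictor = pd.Series(-times)  # larger risk -> earlier event
        m = survival_metrics(rep, df, t_eval=float(n // 2))
        assert m["harrell_c"] == pytest.approx(1.0)

    def test_random_score_c_half(self):
        rng = np.random.default_rng(7)
        n = 2000
        df = pd.DataFrame(
            {"time": rng.exponential(300, n) + 1, "event": rng.random(n) < 0.8,
             "exposure": rng.choice(["bb", "ccb"], n)}
        )
        rep = cox_fit(df)
        rep.linear_predictor = pd.Series(rng.normal(size=n))
        m = survival_metrics(rep, df, t_eval=300)
        assert abs(m["harrell_c"] - 0.5) < 0.03

    def test_null_model_nagelkerke_zero(self):
        df = simulate_confounded_survival(
            1000, true_hr=1.0, confounder_hr=1.0, p_exposed_given_z=(0.5, 0.5), seed=8
        )
        rep = cox_fit(df)
        m = survival_metrics(rep, df)
        assert m["nagelkerke_r2"] == pytest.approx(0.0, abs=0.01)

    def test_metrics_in_unit_interval(self):
        df = simulate_piecewise_survival(1200, seed=9)
        rep = cox_fit(df)
        m = survival_metrics(rep, df)
        for key in ("auc", "sensitivity", "specificity", "harrell_c"):
            assert 0.0 <= m[key] <= 1.0
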