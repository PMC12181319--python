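"""Executive-function scorers: d' correction, costs, eligibility, SSRT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import cogbattery as cb
from cogbattery.ef import SstScore, drop_taskswitch_buffers, score_ef_table


class TestCorrectedRate:
    @pytest.mark.parametrize(
        "count, n, expected",
        [(0, 80, 0.00625), (80, 80, 0.99375), (24, 80, 0.3), (1, 80, 1 / 80)],
    )
    def test_examples(self, count, n, expected):
        assert cb.corrected_rate(count, n) == pytest.approx(expected, abs=1e-15)

    def test_errors(self):
        with pytest.raises(ValueError):
            cb.corrected_rate(0, 0)
        with pytest.raises(ValueError):
            cb.corrected_rate(5, 4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(2, 200), c=st.integers(0, 200))
    def test_strictly_monotone_and_interior_exact(self, n, c):
        c = min(c, n)
        r = cb.corrected_rate(c, n)
        assert 0.0 < r < 1.0
        if 0 < c < n:
            assert r == c / n  # correction never fires on interior rates
        if c < n:
            # strict monotonicity (n >= 2: at n = 1 both counts map to 1/2)
            assert cb.corrected_rate(c + 1, n) > r


class TestDprime:
    def test_symmetry_zero(self):
        assert cb.dprime(10, 20, 10, 20).dprime == 0.0

    def test_quantile_oracle(self):
        d = cb.dprime(80, 80, 0, 20).dprime
        assert d == pytest.approx(
            sps.norm.ppf(0.99375) - sps.norm.ppf(0.025), abs=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        h=st.integers(0, 24), f=st.integers(0, 72),
    )
    def test_antisymmetry(self, h, f):
        """Swapping hit and FA structure negates d' (matched category sizes)."""
        a = cb.dprime(h, 24, f, 72).dprime
        b = cb.dprime(f, 72, h, 24).dprime
        assert a == pytest.approx(-b, abs=1e-12)


class TestAlertness:
    def _frame(self, n_resp, n_total, rt=350.0):
        return pd.DataFrame(
            {
                "rt_ms": [rt] * n_resp + [np.nan] * (n_total - n_resp),
                "response": ["press"] * n_resp + ["none"] * (n_total - n_resp),
            }
        )

    def test_full_response(self):
        s = cb.alertness_scores(self._frame(80, 80))
        assert (s.mean_rt_ms, s.accuracy, s.included) == (350.0, 1.0, True)

    def test_below_half_excluded(self):
        assert not cb.alertness_scores(self._frame(39, 80)).included
        assert cb.alertness_scores(self._frame(40, 80)).included  # boundary

    def test_no_responses_errors(self):
        with pytest.raises(ValueError):
            cb.alertness_scores(self._frame(0, 80))

    def test_generator_mean_recovered(self):
        means = [
            cb.alertness_scores(cb.simulate_alertness(
                cb.CohortConfig().alertness_base, seed=s)).mean_rt_ms
            for s in range(40)
        ]
        # ex-Gaussian mean = mu + tau (30 ms floor effects negligible)
        assert np.mean(means) == pytest.approx(300 + 55, abs=5)


class TestNback:
    def test_perfect_responder_ceiling(self):
        t = cb.simulate_nback(cb.NbackParams(hit_p=1.0, fa_p=0.0), seed=0)
        nb = cb.nback_scores(t)
        expected = sps.norm.ppf((24 - 0.5) / 24) - sps.norm.ppf(0.5 / 72)
        assert nb.sd.dprime == pytest.approx(expected, abs=1e-12)

    def test_chance_responder_near_zero(self):
        ds = [
            cb.nback_scores(
                cb.simulate_nback(cb.NbackParams(hit_p=0.3, fa_p=0.3), seed=s)
            ).sd.dprime
            for s in range(60)
        ]
        assert abs(np.mean(ds)) < 0.1

    def test_hit_rate_recovered(self):
        hrs = [
            cb.nback_scores(
                cb.simulate_nback(cb.NbackParams(hit_p=0.78), seed=s)
            ).sd.hit_rate
            for s in range(150)
        ]
        assert np.mean(hrs) == pytest.approx(0.78, abs=0.02)

    def test_single_hit_rt(self):
        t = cb.simulate_nback(cb.NbackParams(hit_p=1.0, fa_p=0.0), seed=0)
        hit_idx = t.index[(t["condition"] == "target")]
        t.loc[hit_idx, "rt_ms"] = 400.0
        t.loc[hit_idx[1:], "response"] = "none"
        t.loc[hit_idx[1:], "rt_ms"] = np.nan
        t.loc[hit_idx[1:], "correct"] = False
        assert cb.nback_scores(t).mean_hit_rt_ms == 400.0

    def test_targets_match_two_back_letter(self):
        t = cb.simulate_nback(cb.NbackParams(), seed=9)
        for b in range(4):
            blk = t[t["block"] == b].reset_index(drop=True)
            for i, row in blk.iterrows():
                if row["condition"] == "target":
                    assert blk.loc[i - 2, "stimulus_id"] == row["stimulus_id"]


class TestTaskSwitch:
    def test_constructed_means(self):
        """Class means 1322/1007/750 give switch cost 315 and mixing cost 257."""
        rows = []
        for cls, rt, block in (("switch", 1322.0, 2), ("repeat", 1007.0, 2),
                               ("homogeneous", 750.0, 0)):
            for i in range(10):
                rows.append({"task": "taskswitch", "block": block,
                             "trial_index": i, "condition": cls,
                             "response": "x", "correct": True, "rt_ms": rt})
        costs = cb.switch_mixing_costs(pd.DataFrame(rows), buffers_dropped=True)
        assert costs.switch_cost_rt_ms == pytest.approx(315.0)
        assert costs.mixing_cost_rt_ms == pytest.approx(257.0)
        assert costs.switch_cost_err == 0.0 and costs.mixing_cost_err == 0.0

    def test_zero_effects_give_zero_costs(self):
        from cogbattery.simulators import TaskSwitchParams

        params = TaskSwitchParams(mixing_effect_ms=0.0, switch_effect_ms=0.0,
                                  error_p={"homogeneous": 0.05, "repeat": 0.05,
                                           "switch": 0.05})
        sc = [cb.switch_mixing_costs(cb.simulate_taskswitch(params, seed=s))
              for s in range(100)]
        assert np.mean([c.switch_cost_rt_ms for c in sc]) == pytest.approx(0, abs=12)
        assert np.mean([c.mixing_cost_rt_ms for c in sc]) == pytest.approx(0, abs=12)
        assert np.mean([c.switch_cost_err for c in sc]) == pytest.approx(0, abs=0.02)

    def test_buffer_removal_counts(self):
        from cogbattery.simulators import TaskSwitchParams

        t = cb.simulate_taskswitch(TaskSwitchParams(), seed=0)
        valid = drop_taskswitch_buffers(t)
        assert len(valid[valid["block"] == 0]) == 24
        assert len(valid[valid["block"] == 1]) == 24
        assert len(valid[valid["block"] == 2]) == 48

    def test_missing_class_errors(self):
        t = pd.DataFrame({"task": ["taskswitch"], "block": [2], "trial_index": [0],
                          "condition": ["switch"], "response": ["x"],
                          "correct": [True], "rt_ms": [800.0]})
        with pytest.raises(ValueError, match="homogeneous"):
            cb.switch_mixing_costs(t, buffers_dropped=True)


class TestGonogo:
    def test_zero_fa_corrected_floor(self):
        from cogbattery.simulators import GonogoParams

        t = cb.simulate_gonogo(GonogoParams(hit_p=(1.0, 1.0), fa_p=(0.0, 0.0)), seed=0)
        g = cb.gonogo_scores(t)
        assert g.phase1.fa_rate_corrected == pytest.approx(0.5 / 20)
        expected = sps.norm.ppf(0.99375) - sps.norm.ppf(0.025)
        assert g.phase1.dprime == pytest.approx(expected, abs=1e-12)

    def test_chance_responder(self):
        from cogbattery.simulators import GonogoParams

        ds = []
        for s in range(60):
            g = cb.gonogo_scores(
                cb.simulate_gonogo(GonogoParams(hit_p=(0.5, 0.5), fa_p=(0.5, 0.5)),
                                   seed=s)
            )
            ds += [g.phase1.dprime, g.phase2.dprime]
        assert abs(np.mean(ds)) < 0.1

    def test_fa_rate_recovered(self):
        from cogbattery.simulators import GonogoParams

        fas = [
            cb.gonogo_scores(
                cb.simulate_gonogo(GonogoParams(fa_p=(0.3, 0.3)), seed=s)
            ).fa_rate
            for s in range(150)
        ]
        assert np.mean(fas) == pytest.approx(0.30, abs=0.015)


def _sst_frame(go_rts, stop_responded, ssds, go_omissions=0):
    rows = []
    i = 0
    for rt in go_rts:
        rows.append({"condition": "go", "response": "f", "rt_ms": float(rt),
                     "ssd_ms": np.nan, "trial_index": i}); i += 1
    for _ in range(go_omissions):
        rows.append({"condition": "go", "response": "none", "rt_ms": np.nan,
                     "ssd_ms": np.nan, "trial_index": i}); i += 1
    for responded, ssd in zip(stop_responded, ssds):
        rows.append({
            "condition": "stop",
            "response": "f" if responded else "none",
            "rt_ms": (np.mean(go_rts) - 50.0) if responded else np.nan,
            "ssd_ms": float(ssd), "trial_index": i,
        }); i += 1
    df = pd.DataFrame(rows)
    df["task"] = "sst"
    return df


class TestSstEligibility:
    def test_high_commission_rate(self):
        t = _sst_frame([600] * 40, [True] * 8 + [False] * 2, [250] * 10)
        ok, reasons = cb.sst_eligibility(t)
        assert not ok and "commission_rate" in reasons

    def test_omission_boundary(self):
        t = _sst_frame([600] * 89, [True] * 5 + [False] * 5, [250] * 10,
                       go_omissions=11)  # 11/100 > 10%
        ok, reasons = cb.sst_eligibility(t)
        assert not ok and "omission_rate" in reasons
        t = _sst_frame([600] * 90, [True] * 5 + [False] * 5, [250] * 10,
                       go_omissions=10)  # exactly 10% passes
        ok, reasons = cb.sst_eligibility(t)
        assert "omission_rate" not in reasons

    def test_slow_stop_rts_ineligible(self):
        t = _sst_frame([600] * 40, [True] * 5 + [False] * 5, [250] * 10)
        t.loc[(t["condition"] == "stop") & (t["response"] != "none"), "rt_ms"] = 900.0
        ok, reasons = cb.sst_eligibility(t)
        assert not ok and reasons == ("stop_rt_not_faster",)

    def test_race_model_simulants_mostly_eligible(self):
        params = cb.RaceModelParams(mu=500, sigma=50, tau=100, true_ssrt_ms=250)
        ok = [cb.sst_eligibility(cb.simulate_sst(params, seed=s))[0]
              for s in range(40)]
        assert np.mean(ok) > 0.9


class TestSsrtIntegration:
    def test_constant_distribution(self):
        t = _sst_frame([600.0] * 20, [True] * 5 + [False] * 5, [250] * 10)
        s = cb.ssrt_integration(t)
        assert s.eligible
        assert s.ssrt_ms == pytest.approx(350.0)

    def test_hand_sorted_oracle(self):
        """RTs 300..1200 by 100, p=.5, mean SSD 200 -> 5th RT 700, SSRT 500."""
        go = list(range(300, 1201, 100))  # 10 RTs
        t = _sst_frame(go, [True] * 5 + [False] * 5, [200] * 10)
        t.loc[(t["condition"] == "stop") & (t["response"] != "none"), "rt_ms"] = 290.0
        s = cb.ssrt_integration(t)
        assert s.n_used == 5 and s.nth_rt_ms == 700.0
        assert s.ssrt_ms == pytest.approx(500.0)

    def test_omissions_get_max_rt(self):
        go = [300.0 + 50 * k for k in range(18)]  # 300..1150
        t = _sst_frame(go, [True] * 9 + [False] * 3, [250] * 12, go_omissions=2)
        s = cb.ssrt_integration(t)
        # 20 go trials incl. 2 omissions replaced by max observed (1150);
        # p = 9/12 = .75 -> n = round(20 * .75) = 15 -> 15th of the augmented
        # list = 1000 (ignoring omissions would give n = 14 -> 950)
        assert s.eligible
        assert s.n_used == 15 and s.nth_rt_ms == 1000.0

    def test_ineligible_returns_nan(self):
        t = _sst_frame([600] * 40, [True] * 9 + [False], [250] * 10)
        s = cb.ssrt_integration(t)
        assert not s.eligible and np.isnan(s.ssrt_ms)

    def test_estimator_consistency_scaled_up(self):
        """At 500+ stop trials per simulant the estimator recovers true SSRT."""
        table = cb.ssrt_recovery_study(
            true_ssrt_ms=250.0, n_participants=30,
            stop_trials_per_participant=(501,), seed=11,
        )
        assert abs(table["bias_ms"].iloc[0]) < 20


def test_score_ef_table_layout(small_cohort):
    _, trials, _ = small_cohort
    tab = score_ef_table(trials)
    for col in ("nback_dprime", "switch_cost_rt_ms", "gonogo_fa_rate",
                "ssrt_ms", "sst_eligible", "alertness_mean_rt_ms"):
        assert col in tab.columns
    assert tab["participant_id"].is_unique
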