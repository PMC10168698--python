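"""Onset detection, triggered averaging, pre-onset inference, comparisons."""

import numpy as np
import pandas as pd
import pytest

from walkmap.events import (OnsetParams, compare_conditions, detect_onsets,
                            lateralization_index, pre_onset_statistic,
                            triggered_average)
from walkmap.events import test_pre_onset as wilcoxon_pre_onset  # noqa: avoid pytest collection

from conftest import behavior_from_labels
from test_regionstats import signed_rank_oracle


def _params(**kw):
    defaults = dict(t_pre=0.5, display_before=2.0, display_after=2.0,
                    min_rest=2.0, min_walk=2.0)
    defaults.update(kw)
    return OnsetParams(**defaults)


class TestDetectOnsets:
    def test_all_walk_has_no_onsets(self):
        b = behavior_from_labels(["walk"] * 10, frame_rate_hz=1.0)
        assert len(detect_onsets(b, _params())) == 0

    def test_worked_example(self):
        labels = ["rest"] * 3 + ["walk"] * 3 + ["rest"] * 2 + ["walk"] * 2
        b = behavior_from_labels(labels, frame_rate_hz=1.0)
        onsets = detect_onsets(b, _params(min_rest=2.0, min_walk=2.0))
        np.testing.assert_array_equal(onsets, [3, 8])

    def test_relaxing_min_rest_only_adds_onsets(self):
        rng = np.random.default_rng(0)
        labels = np.where(rng.random(300) < 0.4, "walk", "rest")
        b = behavior_from_labels(labels, frame_rate_hz=1.0)
        strict = set(detect_onsets(b, _params(min_rest=3.0, min_walk=1.0)))
        loose = set(detect_onsets(b, _params(min_rest=1.0, min_walk=1.0)))
        assert strict <= loose

    def test_groom_before_walk_does_not_qualify(self):
        labels = ["groom"] * 5 + ["walk"] * 5
        b = behavior_from_labels(labels, frame_rate_hz=1.0)
        assert len(detect_onsets(b, _params())) == 0


class TestTriggeredAverage:
    def test_identical_trials_have_zero_sem(self):
        fs = 10.0
        period = 60
        tc = np.tile(np.sin(np.linspace(0, 2 * np.pi, period)), 6)
        onsets = np.array([90, 150, 210, 270])
        res = triggered_average(tc, onsets, _params(), fs)
        assert res.n_trials == 4
        np.testing.assert_allclose(res.sem, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.mean, res.trials[0])

    def test_trial_and_negation_average_to_zero(self):
        fs = 10.0
        tc = np.zeros(300)
        tc[100:120] = 1.0
        tc[200:220] = -1.0
        res = triggered_average(tc, np.array([100, 200]), _params(), fs)
        np.testing.assert_allclose(res.mean, 0.0, atol=1e-12)

    def test_incomplete_windows_are_dropped(self):
        fs = 10.0
        tc = np.arange(100.0)
        res = triggered_average(tc, np.array([5, 50, 99]), _params(), fs)
        assert res.n_trials == 1
        assert res.n_dropped == 2

    def test_no_valid_trials_raises(self):
        with pytest.raises(ValueError, match="trial"):
            triggered_average(np.arange(10.0), np.array([5]), _params(), 10.0)

    def test_planted_step_recovered_within_sem(self, rng):
        fs = 30.0
        T = 40000
        step = 0.5
        onsets = np.arange(200, T - 200, 400)[:50]
        tc = rng.normal(0, 0.05, size=T)
        for o in onsets:
            tc[o:o + 60] += step
        res = triggered_average(tc, onsets, _params(normalize_trials=False), fs)
        post = res.times > 0.1
        pre = res.times < -0.5
        assert np.all(np.abs(res.mean[pre]) <= 3 * np.maximum(res.sem[pre], 1e-9) + 0.01)
        inside = (res.times > 0.2) & (res.times < 1.8)
        assert np.all(np.abs(res.mean[inside] - step) <= 4 * res.sem[inside] + 0.01)


class TestPreOnsetStatistic:
    def test_constant_trace_is_zero(self):
        assert pre_onset_statistic(np.full(20, 3.3), _params(), 10.0) == 0.0

    def test_linear_ramp_analytic_value(self):
        # ramp 0 -> h over the last 0.5 s: integral of (a - a(-0.5)) = h/4
        fs = 1000.0
        h = 2.0
        n = int(0.5 * fs)
        trace = np.concatenate([np.zeros(100), np.linspace(0, h, n + 1)])
        got = pre_onset_statistic(trace, _params(), fs)
        assert got == pytest.approx(0.25 * h, rel=1e-4)

    def test_linearity_in_trace(self, rng):
        trace = rng.normal(size=30)
        s = pre_onset_statistic(trace, _params(), 10.0)
        assert pre_onset_statistic(-trace, _params(), 10.0) == pytest.approx(-s)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError, match="cover"):
            pre_onset_statistic(np.zeros(3), _params(), 30.0)

    def test_convergence_to_analytic_integral(self):
        # trapezoid error O(dt^2) for a smooth trace
        errs = []
        for fs in (20.0, 40.0, 80.0):
            n = int(0.5 * fs)
            t = np.linspace(-0.5, 0.0, n + 1)
            trace = np.sin(2 * np.pi * t)
            exact = -(np.cos(0) - np.cos(-np.pi)) / (2 * np.pi) - np.sin(-np.pi) * 0.5
            got = pre_onset_statistic(trace, _params(), fs)
            errs.append(abs(got - exact))
        assert errs[1] < errs[0] and errs[2] < errs[1]
        assert errs[0] / errs[1] > 3.0  # ~4x per rate doubling


class TestWilcoxonPreOnset:
    def test_worked_exact_value(self):
        p, p_adj = wilcoxon_pre_onset([np.array([1.0, 2, 3, 4, 5])], aggregate="trial")
        assert p[0] == pytest.approx(1 / 32)
        assert p_adj[0] == pytest.approx(1 / 32)

    def test_symmetric_sample_is_uninformative(self):
        p, _ = wilcoxon_pre_onset([np.array([-1.3, 1.3])], aggregate="trial")
        assert p[0] >= 0.5

    def test_negative_sample_large_p(self):
        p, _ = wilcoxon_pre_onset([np.array([-3.0, -2, -1, -0.5])], aggregate="trial")
        assert p[0] > 0.5

    def test_exact_matches_enumeration(self, rng):
        for n in range(2, 7):
            vals = rng.normal(0.3, 1.0, size=n)
            p, _ = wilcoxon_pre_onset([vals], aggregate="trial")
            assert p[0] == pytest.approx(signed_rank_oracle(vals), abs=1e-12)

    def test_fly_aggregation_averages_within_fly(self):
        stats = [np.array([1.0, 2.0, -5.0, 3.0, 4.0, 6.0])]
        flies = [np.array([0, 0, 1, 1, 2, 2])]
        p_fly, _ = wilcoxon_pre_onset(stats, flies, aggregate="fly")
        # fly means: 1.5, -1, 5 -> same as testing those three values
        p_direct, _ = wilcoxon_pre_onset([np.array([1.5, -1.0, 5.0])], aggregate="trial")
        assert p_fly[0] == pytest.approx(p_direct[0])

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_pre_onset([np.zeros(5)], aggregate="trial")


class TestLateralization:
    def test_identical_sides_give_zero_index(self):
        out = lateralization_index({"P": np.array([0.3, 0.4])},
                                   {"P": np.array([0.3, 0.4])})
        assert out.iloc[0]["index"] == 0.0

    def test_swapping_sides_negates_index(self, rng):
        a = rng.normal(0.3, 0.05, size=8)
        b = rng.normal(0.1, 0.05, size=8)
        fwd = lateralization_index({"P": a}, {"P": b}).iloc[0]
        rev = lateralization_index({"P": b}, {"P": a}).iloc[0]
        assert fwd["index"] == pytest.approx(-rev["index"])

    def test_planted_ipsilateral_coupling_detected(self, rng):
        ipsi = rng.normal(0.3, 0.05, size=10)
        contra = rng.normal(0.0, 0.05, size=10)
        out = lateralization_index({"P": ipsi}, {"P": contra}).iloc[0]
        assert out["index"] > 0
        assert out["p_adj"] < 0.05
        assert out["ci_low"] > 0

    def test_unmatched_pair_raises(self):
        with pytest.raises(ValueError, match="unmatched"):
            lateralization_index({"P": np.array([1.0])}, {"Q": np.array([1.0])})


class TestCompareConditions:
    @staticmethod
    def _table(units, r2, coef):
        return pd.DataFrame({"unit": units, "r2": r2, "coefficient": coef,
                             "ci_low": np.asarray(coef) - 0.1,
                             "ci_high": np.asarray(coef) + 0.1})

    def test_identical_conditions(self):
        t = self._table(["a", "b"], [0.5, 0.2], [1.0, -0.5])
        out = compare_conditions(t, t)
        assert out["cosine_r2"] == pytest.approx(1.0)
        assert out["cosine_coefficient"] == pytest.approx(1.0)
        assert out["non_overlapping_ci"] == []

    def test_scale_invariance(self):
        a = self._table(["a", "b", "c"], [0.5, 0.2, 0.1], [1.0, -0.5, 0.2])
        b = self._table(["a", "b", "c"], [1.0, 0.4, 0.2], [2.0, -1.0, 0.4])
        out = compare_conditions(a, b)
        assert out["cosine_r2"] == pytest.approx(1.0)
        assert out["cosine_coefficient"] == pytest.approx(1.0)

    def test_disjoint_units_raise(self):
        a = self._table(["a"], [0.5], [1.0])
        b = self._table(["b"], [0.5], [1.0])
        with pytest.raises(ValueError, match="share"):
            compare_conditions(a, b)

    def test_turn_samples_tested_per_unit(self, rng):
        t = self._table(["a", "b"], [0.5, 0.2], [1.0, -0.5])
        sa = {"a": rng.normal(0.5, 0.1, 12), "b": rng.normal(0.0, 0.1, 12)}
        sb = {"a": rng.normal(-0.5, 0.1, 12), "b": rng.normal(0.0, 0.1, 12)}
        out = compare_conditions(t, t, sa, sb)
        tests = out["turn_tests"].set_index("unit")
        assert tests.loc["a", "p_adj"] < 0.05
        assert tests.loc["b", "p_adj"] > 0.05
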