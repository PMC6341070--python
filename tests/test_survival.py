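import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

import seedscreen as ss
from seedscreen import SurvivalRecord
from seedscreen.errors import DomainError
from seedscreen.io import ExpressionCohort


def records(times, events, prefix="s"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKMCurve:
    def test_all_censored_curve_is_one(self):
        curve = ss.km_curve(records([5, 10, 15], [0, 0, 0]))
        assert curve(0) == 1.0 and curve(20) == 1.0

    def test_three_events_closed_form(self):
        curve = ss.km_curve(records([1, 2, 3], [1, 1, 1]))
        assert curve(1) == pytest.approx(2 / 3)
        assert curve(2) == pytest.approx(1 / 3)
        assert curve(3) == pytest.approx(0.0)
        assert curve(0.5) == 1.0

    def test_duplicated_dataset_identical_curve(self):
        base = records([1, 3, 5, 7], [1, 0, 1, 1])
        doubled = base + records([1, 3, 5, 7], [1, 0, 1, 1], prefix="t")
        c1 = ss.km_curve(base)
        c2 = ss.km_curve(doubled)
        for t in [0.5, 1, 2, 3, 5, 7, 8]:
            assert c1(t) == pytest.approx(c2(t))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        recs = records(rng.exponential(10, 50), rng.random(50) < 0.7)
        curve = ss.km_curve(recs)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival.min() >= 0.0 and curve.survival.max() <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            ss.km_curve([])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        recs = records([1, 2, 3], [1, 1, 1], "a") + records([1, 2, 3], [1, 1, 1], "b")
        groups = {r.sample_id: ("low" if r.sample_id.startswith("a") else "high") for r in recs}
        res = ss.logrank_test(recs, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_three_vs_three_hand_computed_oracle(self):
        # hypergeometric accumulation by hand: O_low=3, E_low=1.15, V=0.6775
        recs = records([1, 2, 3], [1, 1, 1], "a") + records([4, 5, 6], [1, 1, 1], "b")
        groups = {f"a{i}": "low" for i in range(3)} | {f"b{i}": "high" for i in range(3)}
        res = ss.logrank_test(recs, groups)
        assert res.observed_events == (3.0, 3.0)
        assert res.expected_events[0] == pytest.approx(1.15)
        assert res.statistic == pytest.approx(5.051660516605167, rel=1e-12)
        assert res.p_value == pytest.approx(0.024602349953641744, rel=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        recs = records(rng.exponential(10, 40), rng.random(40) < 0.8)
        groups = {r.sample_id: ("low" if i % 2 else "high") for i, r in enumerate(recs)}
        flipped = {k: ("high" if v == "low" else "low") for k, v in groups.items()}
        r1 = ss.logrank_test(recs, groups)
        r2 = ss.logrank_test(recs, flipped)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 30)
        events = rng.random(30) < 0.7
        groups = {f"s{i}": ("low" if i < 15 else "high") for i in range(30)}
        r1 = ss.logrank_test(records(times, events), groups)
        r2 = ss.logrank_test(records(times * 365.0, events), groups)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_event_count_conservation(self):
        rng = np.random.default_rng(4)
        recs = records(rng.exponential(5, 60), rng.random(60) < 0.6)
        groups = {r.sample_id: ("low" if i % 3 else "high") for i, r in enumerate(recs)}
        res = ss.logrank_test(recs, groups)
        assert sum(res.observed_events) == pytest.approx(sum(res.expected_events))

    def test_matches_lifelines_with_ties_and_censoring(self):
        rng = np.random.default_rng(5)
        times = np.round(rng.exponential(10, 80), 0) + 1  # many ties
        events = rng.random(80) < 0.7
        low = rng.random(80) < 0.5
        if low.all() or not low.any():  # pragma: no cover
            low[0] = ~low[0]
        recs = records(times, events)
        groups = {f"s{i}": ("low" if low[i] else "high") for i in range(80)}
        mine = ss.logrank_test(recs, groups)
        ref = lifelines_logrank(times[low], times[~low], events[low], events[~low])
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_one_empty_group_rejected(self):
        recs = records([1, 2], [1, 1])
        with pytest.raises(DomainError):
            ss.logrank_test(recs, {"s0": "low", "s1": "low"})


class TestAntimodeThreshold:
    def test_bimodal_mixture_threshold_between_modes(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(4, 1, 50)])
        res = ss.antimode_threshold(vals)
        assert res.method == "antimode"
        assert 1.0 <= res.threshold <= 3.0
        assert sum(res.group_sizes) == 100

    def test_unimodal_falls_back_to_median(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, 200)
        res = ss.antimode_threshold(vals)
        assert res.method == "median_fallback"
        assert res.threshold == pytest.approx(np.median(vals))

    def test_two_point_masses_with_jitter(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0, 0.01, 50), rng.normal(4, 0.01, 50)])
        res = ss.antimode_threshold(vals)
        assert 0.0 < res.threshold < 4.0

    def test_separation_property(self):
        """Antimode lies between the component means once separation >= 3 sd."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            delta = 3.5
            vals = np.concatenate([rng.normal(0, 1, 60), rng.normal(delta, 1, 60)])
            res = ss.antimode_threshold(vals)
            assert 0.0 < res.threshold < delta

    def test_constant_values_rejected(self):
        with pytest.raises(DomainError):
            ss.antimode_threshold(np.full(30, 2.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(DomainError):
            ss.antimode_threshold(np.arange(10.0))

    def test_min_group_fraction_enforced(self):
        rng = np.random.default_rng(9)
        # tiny second mode: antimode split would isolate 4% of samples
        vals = np.concatenate([rng.normal(0, 0.5, 96), rng.normal(6, 0.1, 4)])
        res = ss.antimode_threshold(vals, min_group_frac=0.1)
        assert res.method == "median_fallback"

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(4, 1, 50)])
        r1 = ss.antimode_threshold(vals)
        r2 = ss.antimode_threshold(vals)
        assert r1.threshold == r2.threshold and r1.method == r2.method


class TestSurvivalScreen:
    def _cohort_and_records(self, hazard_ratio, n=300, rng_seed=11):
        cfg = ss.SyntheticConfig(
            survival_spec=ss.SurvivalSpec(hazard_ratio=hazard_ratio, censoring_rate=0.2),
            rng_seed=rng_seed,
        )
        return ss.generate_survival_cohort(cfg, n_samples=n)

    def test_protective_low_expression_detected(self):
        cohort, recs, truth = self._cohort_and_records(hazard_ratio=2.0)
        frame = ss.survival_screen(cohort, recs, cohort.features)
        row = frame.iloc[0]
        assert row["method"] == "antimode"
        assert row["p_value"] <= 0.05
        assert row["direction_of_benefit"] == "low"

    def test_too_few_linked_samples_rejected(self):
        cohort, recs, _ = self._cohort_and_records(hazard_ratio=1.0, n=30)
        with pytest.raises(DomainError):
            ss.survival_screen(cohort, recs[:10], cohort.features)

    def test_model_results_surface(self):
        cohort, recs, _ = self._cohort_and_records(hazard_ratio=2.0)
        res = ss.SurvivalScreen(cohort, recs).fit()
        assert len(res.frame) == 1
        assert "Survival screen" in res.summary()
        assert len(res.significant(alpha=1.0)) == 1
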