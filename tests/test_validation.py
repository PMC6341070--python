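import itertools

import numpy as np
import pandas as pd
import pytest

import seedscreen as ss
from seedscreen.association import AssociationTable
from seedscreen.errors import ConfigurationError, DomainError
from seedscreen.io import ExpressionCohort
from seedscreen.validation import format_percent

from test_screening import make_result, table_for


def candidate_set(features):
    return ss.CandidateSet(
        tier_name="relaxed", features=frozenset(features), genes=frozenset(features),
        per_feature_evidence={},
    )


class TestRateRendering:
    @pytest.mark.parametrize(
        "num, den, text",
        [
            (212, 214, "99.07%"),
            (206, 214, "96.26%"),
            (106, 214, "49.53%"),
            (2, 206, "0.97%"),
            (0, 188, "0.00%"),
        ],
    )
    def test_percent_formatting_matches_printed_rates(self, num, den, text):
        assert format_percent(num, den) == text


class TestReplicationReport:
    def _group_table(self, n_sig_same, n_sig_opp, n_total, group="val"):
        """Candidates f0..f{n_total-1}; the first n_sig_same replicate with the
        reference (+) direction, the next n_sig_opp flip sign, the rest are null."""
        entries = {}
        for i in range(n_total):
            if i < n_sig_same:
                entries[f"f{i}"] = (0.001, 0.2, 1)
            elif i < n_sig_same + n_sig_opp:
                entries[f"f{i}"] = (0.001, 0.2, -1)
            else:
                entries[f"f{i}"] = (0.5, 0.0, 1)
        return table_for(group, entries)

    def test_counts_and_rendering_212_of_214(self):
        cs = candidate_set([f"f{i}" for i in range(214)])
        ref = {f"f{i}": 1 for i in range(214)}
        rep = ss.replication_report(cs, ref, self._group_table(212, 0, 214))
        assert rep.n_significant_same_direction == 212
        assert rep.consistent_rate_text == "99.07%"

    def test_counts_and_rendering_106_of_214(self):
        cs = candidate_set([f"f{i}" for i in range(214)])
        ref = {f"f{i}": 1 for i in range(214)}
        rep = ss.replication_report(cs, ref, self._group_table(106, 0, 214))
        assert rep.consistent_rate_text == "49.53%"

    def test_opposite_rate_two_of_206(self):
        cs = candidate_set([f"f{i}" for i in range(214)])
        ref = {f"f{i}": 1 for i in range(214)}
        rep = ss.replication_report(cs, ref, self._group_table(204, 2, 214))
        assert rep.n_significant_total == 206
        assert rep.opposite_rate_text == "0.97%"

    def test_perfect_replication(self):
        cs = candidate_set(["a", "b"])
        ref = {"a": 1, "b": 1}
        rep = ss.replication_report(cs, ref, table_for("g", {"a": (0.01, 0.2, 1), "b": (0.01, 0.2, 1)}))
        assert rep.consistent_rate == 1.0 and rep.opposite_rate == 0.0

    def test_unmeasured_candidates_count_in_denominator(self):
        cs = candidate_set(["a", "b", "c", "d"])
        ref = {f: 1 for f in cs.features}
        rep = ss.replication_report(cs, ref, table_for("g", {"a": (0.01, 0.2, 1)}))
        assert rep.n_candidates == 4 and rep.n_significant_same_direction == 1
        assert rep.consistent_rate == 0.25

    def test_empty_candidates_rejected(self):
        with pytest.raises(DomainError):
            ss.replication_report(candidate_set([]), {}, table_for("g", {}))

    def test_duplicating_candidates_leaves_rates_unchanged(self):
        base = {f"f{i}": (0.001 if i < 3 else 0.5, 0.2, 1) for i in range(5)}
        dup = {**base, **{f"g{i}": v for i, v in enumerate(base.values())}}
        cs1 = candidate_set(base)
        cs2 = candidate_set(dup)
        ref1 = {f: 1 for f in cs1.features}
        ref2 = {f: 1 for f in cs2.features}
        r1 = ss.replication_report(cs1, ref1, table_for("g", base))
        r2 = ss.replication_report(cs2, ref2, table_for("g", dup))
        assert r1.consistent_rate == r2.consistent_rate
        assert r1.opposite_rate == r2.opposite_rate

    def test_discovery_cohorts_replicate_themselves(self, eight_cohorts):
        """Relaxed-tier survivors are significant with one direction in every
        discovery cohort, so replicating against any of them gives rate 1.0."""
        cohorts, _ = eight_cohorts
        tables = [ss.associate_all(c, "SEED") for c in cohorts]
        relaxed = ss.apply_tier(tables, ss.relaxed_tier())
        assert relaxed.features
        ref = ss.reference_directions(relaxed, tables)
        for table in tables:
            rep = ss.replication_report(relaxed, ref, table)
            assert rep.consistent_rate == 1.0
            assert rep.opposite_rate == 0.0


class TestSubtypeScreen:
    def _tables(self, per_subtype):
        return {name: table_for(name, entries) for name, entries in per_subtype.items()}

    def test_feature_null_in_one_subtype_excluded(self):
        cs = candidate_set(["a", "b"])
        tabs = self._tables({
            "s1": {"a": (0.001, 0.2, 1), "b": (0.001, 0.2, 1)},
            "s2": {"a": (0.001, 0.2, 1), "b": (0.6, 0.0, 1)},
        })
        survivors, reports = ss.subtype_screen(cs, tabs)
        assert survivors == {"a"}
        assert set(reports) == {"s1", "s2"}

    def test_opposite_sign_in_one_subtype_excluded(self):
        cs = candidate_set(["a"])
        tabs = self._tables({
            "s1": {"a": (0.001, 0.2, 1)},
            "s2": {"a": (0.001, 0.2, -1)},
        })
        survivors, _ = ss.subtype_screen(cs, tabs)
        assert survivors == set()

    def test_needs_two_subtypes(self):
        with pytest.raises(ConfigurationError):
            ss.subtype_screen(candidate_set(["a"]), {"s1": table_for("s1", {"a": (0.01, 0.1, 1)})})

    def test_disjoint_subtype_rejected(self):
        cs = candidate_set(["a"])
        tabs = self._tables({"s1": {"a": (0.01, 0.1, 1)}, "s2": {"zz": (0.01, 0.1, 1)}})
        with pytest.raises(ConfigurationError):
            ss.subtype_screen(cs, tabs)

    def test_recovers_planted_features_across_subtypes(self):
        """Subtype cohorts sharing the discovery structure keep >= 95% of
        planted features (seeded simulation with known ground truth)."""
        cfg = ss.SyntheticConfig(
            n_cohorts=4,
            samples_per_cohort=[150, 150, 150, 150],
            n_features=60,
            n_planted=30,
            rho_range=(0.5, 0.7),
            rng_seed=21,
        )
        cohorts, truth = ss.generate_cohorts(cfg)
        tabs = {c.cohort_id: ss.associate_all(c, "SEED") for c in cohorts}
        cs = candidate_set(truth.planted_features)
        survivors, _ = ss.subtype_screen(cs, tabs)
        assert len(survivors) >= 0.95 * len(truth.planted_features)


class TestClassifySpecificity:
    def test_definitions(self):
        t = make_result("f", "LIHC", 1e-5, direction=1)
        n_null = make_result("f", "LIHC", 0.4, direction=1)
        assert ss.classify_specificity(t, n_null).call == "tumor_specific"
        n_sig_opp = make_result("f", "LIHC", 0.01, direction=-1)
        assert ss.classify_specificity(t, n_sig_opp).call == "opposite"
        t_null = make_result("f", "LIHC", 0.2, direction=1)
        assert ss.classify_specificity(t_null, n_null).call == "neither"
        assert ss.classify_specificity(t_null, n_sig_opp).call == "normal_specific"
        n_sig_same = make_result("f", "LIHC", 0.01, direction=1)
        assert ss.classify_specificity(t, n_sig_same).call == "consistent"

    def test_feature_mismatch_rejected(self):
        with pytest.raises(DomainError):
            ss.classify_specificity(make_result("a", "c", 0.01), make_result("b", "c", 0.01))

    def test_calls_partition_decision_space(self):
        """Exactly one call per (p_tumor, p_normal, direction) grid cell."""
        calls = set()
        for pt, pn, dt, dn in itertools.product(
            [0.001, 0.049, 0.051, 0.9], [0.001, 0.049, 0.051, 0.9], [1, -1], [1, -1]
        ):
            t = make_result("f", "c", pt, direction=dt)
            n = make_result("f", "c", pn, direction=dn)
            call = ss.classify_specificity(t, n).call
            assert call in {"consistent", "tumor_specific", "normal_specific", "opposite", "neither"}
            calls.add(call)
        assert len(calls) == 5


class TestPairedRegulationFrequency:
    def _paired_cohort(self, diffs):
        n = len(diffs)
        normal = np.zeros(n)
        tumor = np.asarray(diffs, float)
        values = pd.DataFrame(
            [np.concatenate([tumor, normal])], index=["f"],
            columns=[f"p{i}_T" for i in range(n)] + [f"p{i}_N" for i in range(n)],
        )
        ann = pd.DataFrame(index=values.columns)
        ann["tissue"] = ["tumor"] * n + ["normal"] * n
        ann["pair_id"] = [f"p{i}" for i in range(n)] * 2
        return ExpressionCohort(cohort_id="pc", values=values, sample_annotations=ann)

    def test_all_equal_pairs(self):
        up, down = ss.paired_regulation_frequency(self._paired_cohort(np.zeros(10)), "f")
        assert (up, down) == (0.0, 0.0)

    def test_uniform_tenfold_up(self):
        up, down = ss.paired_regulation_frequency(self._paired_cohort(np.full(8, 10.0)), "f")
        assert (up, down) == (1.0, 0.0)

    def test_counted_fractions(self):
        diffs = [2.0, 1.5, 1.0, -1.2, -3.0, 0.2, 0.5, -0.5, 0.0, 0.9]
        up, down = ss.paired_regulation_frequency(self._paired_cohort(diffs), "f")
        assert up == pytest.approx(0.3)
        assert down == pytest.approx(0.2)

    def test_no_pairs_rejected(self):
        cohort = self._paired_cohort([1.0])
        cohort.sample_annotations["pair_id"] = [np.nan, np.nan]
        with pytest.raises(DomainError):
            ss.paired_regulation_frequency(cohort, "f")
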