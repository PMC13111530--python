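import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corrshape import (
    ClassificationRecord,
    PeriodAssignment,
    class_fractions,
    classify_leader_follower,
    classify_peak_count,
    classify_peak_times,
    classify_uniformity,
    combined_combo_table,
    transition_probabilities,
)
from corrshape.classify import LF_CLASSES, peak_count_classes, timescale_classes


def record(region, ref="i", cmp="j", uni="uniform", peak="0", lf="weak"):
    return ClassificationRecord(region, ref, cmp, uni, peak, lf, ())


class TestClassifyUniformity:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.5, "uniform"), (0.05, "nonuniform"), (0.0, "nonuniform"),
         (0.050001, "uniform"), (1.0, "uniform")],
    )
    def test_threshold_semantics(self, p, expected):
        assert classify_uniformity(p, 0.05) == expected


class TestClassifyPeakCount:
    @pytest.mark.parametrize(
        "count, m, expected",
        [(3, 4, "3"), (4, 4, "4+"), (12, 10, "10+"), (0, 1, "0")],
    )
    def test_ceiling_class(self, count, m, expected):
        assert classify_peak_count(count, m) == expected

    def test_class_set_size(self):
        assert len(peak_count_classes(10)) == 11


class TestClassifyPeakTimes:
    def test_one_second_range_has_four_timescale_classes(self):
        assert len(timescale_classes(1.0)) == 4

    def test_timescale_lookup(self):
        labels = classify_peak_times([0.0025], "timescale", 1.0)
        assert labels == ("(0.001, 0.01] s",)

    def test_zero_lag_in_smallest_class(self):
        labels = classify_peak_times([0.0], "timescale", 1.0)
        assert labels == ("<= 0.001 s",)

    def test_five_hz_is_theta(self):
        # |t| = 0.2 s -> f = 5 Hz
        assert classify_peak_times([0.2], "frequency") == ("theta",)

    @pytest.mark.parametrize(
        "lag, band",
        [(0.5, "delta"), (0.1, "alpha"), (0.05, "beta"), (0.02, "gamma"),
         (-0.2, "theta")],
    )
    def test_frequency_bands_contiguous(self, lag, band):
        assert classify_peak_times([lag], "frequency") == (band,)

    def test_zero_lag_skipped_in_frequency_mode(self):
        assert classify_peak_times([0.0], "frequency") == ()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            classify_peak_times([0.1], "nonsense")


class TestClassifyLeaderFollower:
    @pytest.mark.parametrize(
        "A, expected",
        [
            (0.5, "weak"), (0.85, "fairly_strong"), (0.15, "fairly_strong"),
            (0.1, "strong"), (0.9, "strong"), (0.0, "strong"), (1.0, "strong"),
            (0.4, "fairly_weak"), (0.6, "fairly_weak"),
            (0.3, "intermediate"), (0.7, "intermediate"),
            (0.2, "fairly_strong"), (0.8, "fairly_strong"),
        ],
    )
    def test_boundary_audit(self, A, expected):
        assert classify_leader_follower(A) == expected

    @given(st.floats(0, 1))
    @settings(max_examples=300, deadline=None)
    def test_partition_and_mirror_consistency(self, A):
        cls = classify_leader_follower(A)
        assert cls in LF_CLASSES
        assert classify_leader_follower(1 - A) == cls

    def test_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_leader_follower(1.2)


class TestClassFractions:
    def test_simple_fraction(self):
        records = [record(1, ref=f"u{k}", uni="uniform" if k == 0 else "nonuniform")
                   for k in range(4)]
        df = class_fractions(records, include_autocorrelograms=False)
        uni = df[(df["scheme"] == "uniformity_class") & (df["class"] == "uniform")]
        assert uni["fraction"].iloc[0] == 0.25

    def test_fractions_sum_to_one_per_scheme(self):
        rng = np.random.default_rng(11)
        records = [
            record(1, ref=f"u{k}", uni=rng.choice(["uniform", "nonuniform"]),
                   peak=str(rng.integers(0, 3)), lf=rng.choice(LF_CLASSES))
            for k in range(30)
        ]
        df = class_fractions(records)
        sums = df.groupby(["region_index", "scheme"])["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_lf_split(self):
        records = [record(1, ref=f"u{k}", lf="weak" if k < 2 else "strong")
                   for k in range(4)]
        df = class_fractions(records)
        lf = df[df["scheme"] == "lf_class"].set_index("class")["fraction"]
        assert lf["weak"] == 0.5 and lf["strong"] == 0.5

    def test_autocorrelograms_excluded_by_default(self):
        records = [record(1, ref="i", cmp="i"), record(1, ref="i", cmp="j")]
        df = class_fractions(records)
        assert df["n"].iloc[0] == 1


class TestTransitionProbabilities:
    def test_constant_classes_identity_rows(self):
        records = [record(r, uni="uniform") for r in range(1, 6)]
        tables = transition_probabilities(records, step="region")
        assert len(tables) == 4
        for tab in tables:
            assert tab.matrix.loc["uniform", "uniform"] == 1.0

    def test_toy_sequence_pooled_probabilities(self):
        seq = ["uniform", "uniform", "nonuniform"]
        records = [record(r + 1, uni=u) for r, u in enumerate(seq)]
        periods = PeriodAssignment({1: "all", 2: "all", 3: "all"})
        (tab,) = transition_probabilities(records, step="period", periods=periods)
        assert tab.matrix.loc["uniform", "uniform"] == pytest.approx(0.5)
        assert tab.matrix.loc["uniform", "nonuniform"] == pytest.approx(0.5)

    def test_rows_sum_to_one_where_supported(self):
        rng = np.random.default_rng(13)
        records = [
            record(r, ref=f"u{k}", uni=rng.choice(["uniform", "nonuniform"]))
            for r in range(1, 5) for k in range(10)
        ]
        for tab in transition_probabilities(records, step="region"):
            for cls in tab.matrix.index:
                if tab.support[cls]:
                    assert tab.matrix.loc[cls].sum() == pytest.approx(1.0, abs=1e-12)

    def test_sparse_endpoints_skipped_and_counted(self):
        # correlogram (i,j) present in regions 1 and 3 only
        records = [record(1), record(3)]
        tables = transition_probabilities(records, step="region")
        assert all(tab.skipped == 1 for tab in tables)

    def test_period_pooling_matches_weighted_region_tables(self):
        rng = np.random.default_rng(17)
        records = [
            record(r, ref=f"u{k}", uni=rng.choice(["uniform", "nonuniform"]))
            for r in range(1, 6) for k in range(8)
        ]
        periods = PeriodAssignment({r: ("early" if r <= 3 else "late") for r in range(1, 6)})
        region_tabs = transition_probabilities(records, step="region")
        period_tabs = {t.grouping: t for t in
                       transition_probabilities(records, step="period", periods=periods)}
        # pool the per-step counts destined for "late" (steps 3->4, 4->5)
        pooled = None
        for tab in region_tabs:
            dst = int(tab.grouping.split("->")[1])
            if periods.period_of(dst) != "late":
                continue
            counts = tab.matrix.mul(tab.support, axis=0)
            pooled = counts if pooled is None else pooled + counts
        late = period_tabs["late"]
        expected = late.matrix.mul(late.support, axis=0)
        np.testing.assert_allclose(pooled.to_numpy(), expected.to_numpy(), atol=1e-9)


class TestCombinedComboTable:
    def test_cell_count_110_at_m10(self):
        table = combined_combo_table([record(1)], max_peak_class=10)
        assert len(table) == 110

    def test_single_record_single_cell(self):
        table = combined_combo_table([record(1, uni="nonuniform", peak="2", lf="strong")],
                                     max_peak_class=4)
        assert table["all"].sum() == pytest.approx(100.0)
        assert table.loc[("nonuniform", "strong", "2"), "all"] == pytest.approx(100.0)

    def test_percentages_sum_to_100_per_group(self):
        rng = np.random.default_rng(19)
        records = [
            record(r, ref=f"u{k}", uni=rng.choice(["uniform", "nonuniform"]),
                   peak=str(rng.integers(0, 4)), lf=rng.choice(LF_CLASSES))
            for r in range(1, 4) for k in range(20)
        ]
        grouping = {1: "before", 2: "after", 3: "after"}
        table = combined_combo_table(records, 4, grouping=grouping)
        for col in table.columns:
            assert table[col].sum() == pytest.approx(100.0, abs=1e-9)

    def test_occupied_cells_bounded_by_record_count(self):
        records = [record(1, ref=f"u{k}") for k in range(5)]
        table = combined_combo_table(records)
        assert (table["all"] > 0).sum() <= 5
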