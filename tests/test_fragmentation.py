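"""Category slicing, per-slice summaries, and the power gate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionomeshift.dataset import Dataset, NON_MINERALS
from ionomeshift.effects import CategorySummary, EffectSize
from ionomeshift.fragmentation import (
    CategoryKey,
    assign_region,
    gate_by_power,
    slice_effects,
    summarize_category,
)

from conftest import make_record


def summary(power, label="s"):
    return CategorySummary(label=label, m=5, n_total=20,
                           mean_pct_change=-8.0, ci_low=-10.0, ci_high=-6.0,
                           ci_method="bootstrap", power=power)


class TestAssignRegion:
    @pytest.mark.parametrize("lat, expected", [
        (20.0, "tropical_subtropical"),
        (-40.0, "temperate"),
        (35.0, "tropical_subtropical"),   # boundary inclusive
        (-35.0, "tropical_subtropical"),
        (35.01, "temperate"),
    ])
    def test_boundary_convention(self, lat, expected):
        assert assign_region(lat) == expected

    def test_missing_latitude_unclassified(self):
        assert assign_region(None) == "unclassified"
        assert assign_region(float("nan")) == "unclassified"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_region(95.0)


class TestSlicing:
    def test_element_slice_counting_oracle(self):
        data = Dataset.from_records(
            [make_record(study_id=f"Z{i}", element="Zn") for i in range(7)]
            + [make_record(study_id=f"F{i}", element="Fe") for i in range(4)]
        )
        assert len(slice_effects(data, CategoryKey("element", "Zn"))) == 7
        assert len(slice_effects(data, CategoryKey("element", "Fe"))) == 4

    def test_ionome_excludes_c_and_n(self):
        data = Dataset.from_records([
            make_record(study_id="S1", element="C"),
            make_record(study_id="S2", element="N"),
            make_record(study_id="S3", element="Zn"),
            make_record(study_id="S4", element="K"),
        ])
        effs = slice_effects(data, CategoryKey("ionome"))
        assert len(effs) == 2
        assert {e.source_id for e in effs} == {"S3", "S4"}

    def test_geographic_slices_keep_only_open_air_facilities(self):
        data = Dataset.from_records([
            make_record(study_id="S1", facility="FACE", latitude=20.0),
            make_record(study_id="S2", facility="OTC", latitude=20.0),
            make_record(study_id="S3", facility="chamber", latitude=20.0),
            make_record(study_id="S4", facility="greenhouse", latitude=20.0),
        ])
        effs = slice_effects(
            data, CategoryKey("region", "tropical_subtropical"))
        assert {e.source_id for e in effs} == {"S1", "S2"}

    def test_c4_records_excluded_from_other_slices(self):
        data = Dataset.from_records([
            make_record(study_id="S1", pathway="C3"),
            make_record(study_id="S2", pathway="C4"),
        ])
        effs = slice_effects(data, CategoryKey("element", "Zn"))
        assert {e.source_id for e in effs} == {"S1"}
        c4 = slice_effects(data, CategoryKey("plant_group", "C4"))
        assert {e.source_id for e in c4} == {"S2"}

    def test_crop_name_groups_cultivars(self):
        data = Dataset.from_records([
            make_record(study_id="S1", species="Oryza sativa",
                        cultivar="Akitakomachi", common_name=None),
            make_record(study_id="S2", species="Oryza sativa",
                        cultivar="IR 72", common_name=None),
            make_record(study_id="S3", species="Triticum aestivum",
                        common_name=None),
        ])
        rice = slice_effects(data, CategoryKey("crop_name", "rice"))
        assert {e.source_id for e in rice} == {"S1", "S2"}

    def test_unknown_dimension_lists_valid_ones(self):
        with pytest.raises(ValueError, match="element"):
            CategoryKey("flavor", "sweet")

    def test_element_slices_partition_dataset(self, synthetic_dataset):
        frame = synthetic_dataset.frame
        frame = frame[frame["pathway"] != "C4"]
        total = 0
        for el in frame["element"].unique():
            total += len(slice_effects(synthetic_dataset,
                                       CategoryKey("element", el)))
        assert total == len(frame)

    def test_ionome_is_union_of_mineral_slices(self, synthetic_dataset):
        ionome = slice_effects(synthetic_dataset, CategoryKey("ionome"))
        frame = synthetic_dataset.frame
        minerals = [el for el in frame["element"].unique()
                    if el not in NON_MINERALS]
        union = sum(len(slice_effects(synthetic_dataset,
                                      CategoryKey("element", el)))
                    for el in minerals)
        assert len(ionome) == union


class TestSummarize:
    def test_constant_slice_degenerate(self):
        effs = [EffectSize(-0.1, 3)] * 6
        s = summarize_category(effs, seed=0, B=400, B_outer=50, B_inner=99)
        assert s.ci_low == s.ci_high == s.mean_pct_change
        assert "degenerate" in s.flags
        assert s.power == 1.0

    def test_insufficient_slice_flagged(self):
        s = summarize_category([EffectSize(-0.1, 3)], seed=0)
        assert "insufficient" in s.flags
        assert s.m == 1

    def test_recovers_known_mean_with_coverage(self, rng):
        """Simulated slices at true mean ln(0.92), m = 140: the 95% CI
        covers -8% in at least 90% of repetitions (coverage oracle at
        reduced repetitions)."""
        truth = 100 * math.expm1(math.log(0.92))
        reps, hits = 30, 0
        for _ in range(reps):
            effs = [EffectSize(float(v), 4) for v in
                    rng.normal(math.log(0.92), 0.21, size=140)]
            s = summarize_category(effs, seed=rng, B=800,
                                   B_outer=30, B_inner=99)
            hits += s.ci_low <= truth <= s.ci_high
        assert hits / reps >= 0.90

    def test_reports_both_interval_routes(self, rng):
        effs = [EffectSize(float(v), 4) for v in
                rng.normal(-0.08, 0.21, size=40)]
        s = summarize_category(effs, seed=1, B=1000, B_outer=50, B_inner=99)
        assert s.ci_method == "bootstrap"
        assert s.t_ci_low is not None and s.t_ci_high is not None
        assert s.t_ci_low < s.mean_pct_change < s.t_ci_high


class TestGate:
    def test_threshold_strictly_exceeded(self):
        report = gate_by_power([summary(0.39), summary(0.41)])
        assert [s.power for s in report.included] == [0.41]
        assert [s.power for s in report.excluded] == [0.39]

    def test_zero_threshold_includes_everything_with_power(self):
        report = gate_by_power([summary(0.01), summary(0.9)], threshold=0.0)
        assert len(report.included) == 2

    def test_missing_power_excluded(self):
        report = gate_by_power([summary(None)])
        assert len(report.excluded) == 1

    @given(powers=st.lists(st.one_of(st.none(), st.floats(0, 1)),
                           min_size=0, max_size=30),
           threshold=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_partition_property(self, powers, threshold):
        summaries = [summary(p, label=str(i)) for i, p in enumerate(powers)]
        report = gate_by_power(summaries, threshold=threshold)
        assert len(report.included) + len(report.excluded) == len(summaries)
        assert {id(s) for s in report.included}.isdisjoint(
            {id(s) for s in report.excluded})
        assert {id(s) for s in report.all_summaries} == \
            {id(s) for s in summaries}
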