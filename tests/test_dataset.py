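"""Schema validation, CSV round-trips, and the data-inclusion rules."""

import numpy as np
import pytest

from ionomeshift.dataset import (
    Dataset,
    SchemaError,
    UnresolvedGroupError,
    apply_inclusion_rules,
    read_dataset,
    validate_against_printed_counts,
    write_dataset,
)

from conftest import make_record


class TestRoundTrip:
    def test_read_well_formed_csv(self, small_dataset, tmp_path):
        p = tmp_path / "d.csv"
        write_dataset(small_dataset, p)
        loaded = read_dataset(p)
        assert len(loaded) == 3
        assert not loaded.diagnostics

    def test_round_trip_identity(self, small_dataset, tmp_path):
        p = tmp_path / "d.csv"
        write_dataset(small_dataset, p)
        assert read_dataset(p).records == small_dataset.records

    def test_synthetic_round_trip_identity(self, synthetic_dataset, tmp_path):
        p = tmp_path / "synth.csv"
        write_dataset(synthetic_dataset, p)
        loaded = read_dataset(p)
        for a, b in zip(loaded.records, synthetic_dataset.records):
            assert a.study_id == b.study_id and a.element == b.element
            assert a.relative_change == pytest.approx(b.relative_change,
                                                      rel=1e-12)

    def test_empty_dataset_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_dataset(Dataset.from_records([]), p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("study_id,")

    def test_record_count_matches_line_count(self, tmp_path):
        data = Dataset.from_records(
            [make_record(study_id=f"S{i}") for i in range(100)])
        p = tmp_path / "hundred.csv"
        write_dataset(data, p)
        assert len(p.read_text().strip().splitlines()) == 101


class TestValidation:
    def test_impossible_decline_rejected(self, tmp_path):
        data = Dataset.from_records([
            make_record(study_id="good"),
            make_record(study_id="bad", relative_change=-1.2),
        ])
        p = tmp_path / "d.csv"
        write_dataset(data, p)
        loaded = read_dataset(p)
        assert len(loaded) == 1
        assert loaded.diagnostics[0].row == 1
        assert "cannot" in loaded.diagnostics[0].message

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("study_id,species\nS1,wheat\n")
        with pytest.raises(SchemaError, match="relative_change"):
            read_dataset(p)

    def test_column_mapping_applied(self, small_dataset, tmp_path):
        p = tmp_path / "d.csv"
        write_dataset(small_dataset, p)
        text = p.read_text().replace("relative_change", "pct_change_frac")
        p.write_text(text)
        loaded = read_dataset(
            p, column_map={"pct_change_frac": "relative_change"})
        assert len(loaded) == 3

    def test_unknown_element_rejected(self, tmp_path):
        data = Dataset.from_records([make_record(element="Zn")])
        data.frame.loc[0, "element"] = "Xx"
        p = tmp_path / "d.csv"
        write_dataset(data, p)
        loaded = read_dataset(p)
        assert len(loaded) == 0
        assert "element" in loaded.diagnostics[0].message

    def test_inconsistent_concentration_pair_rejected(self, tmp_path):
        data = Dataset.from_records([make_record(
            relative_change=-0.08, conc_ambient=100.0, conc_elevated=95.0)])
        p = tmp_path / "d.csv"
        write_dataset(data, p)
        loaded = read_dataset(p)
        assert len(loaded) == 0
        assert "inconsistent" in loaded.diagnostics[0].message

    def test_co2_ordering_enforced(self, tmp_path):
        data = Dataset.from_records([make_record(
            co2_ambient=700.0, co2_elevated=370.0)])
        p = tmp_path / "d.csv"
        write_dataset(data, p)
        assert len(read_dataset(p)) == 0


class TestPrintedCounts:
    def test_synthetic_marked_not_applicable(self, synthetic_dataset):
        report = validate_against_printed_counts(synthetic_dataset)
        assert all(l.status == "not applicable (synthetic)" for l in report)

    def test_deleting_one_foliar_record_shifts_delta_by_one(self):
        records = [make_record(study_id=f"S{i}", tissue="foliar")
                   for i in range(5)]
        full = Dataset.from_records(records)
        fewer = Dataset.from_records(records[:-1])
        line = {l.name: l for l in validate_against_printed_counts(full)}
        line2 = {l.name: l for l in validate_against_printed_counts(fewer)}
        a, b = line["foliar observations"], line2["foliar observations"]
        assert a.status == b.status == "fail"
        assert b.delta == a.delta - 1


def co2_arm(study, amb, ele, **kw):
    return make_record(study_id=study, co2_ambient=amb, co2_elevated=ele,
                       **kw)


class TestInclusionRules:
    def test_extreme_co2_levels_kept(self):
        data = Dataset.from_records([
            co2_arm("S1", 370, 550, relative_change=-0.04),
            co2_arm("S1", 370, 750, relative_change=-0.09),
        ])
        out = apply_inclusion_rules(data, tissue="foliar")
        assert len(out) == 1
        assert out.records[0].co2_elevated == 750

    def test_foliar_cofactor_arm_dropped_edible_retained(self):
        foliar = Dataset.from_records([
            make_record(study_id="S1", tissue="foliar", cofactor=None),
            make_record(study_id="S1", tissue="foliar", cofactor="ozone",
                        relative_change=-0.2),
        ])
        out = apply_inclusion_rules(foliar, tissue="foliar")
        assert len(out) == 1
        assert out.records[0].cofactor is None

        edible = Dataset.from_records([
            make_record(study_id="S1", tissue="edible", cofactor=None),
            make_record(study_id="S1", tissue="edible", cofactor="ozone",
                        relative_change=-0.2),
        ])
        out = apply_inclusion_rules(edible, tissue="edible")
        assert len(out) == 2

    def test_last_time_point_kept(self):
        data = Dataset.from_records([
            make_record(study_id="S1", time_point_index=1,
                        relative_change=-0.02),
            make_record(study_id="S1", time_point_index=2,
                        relative_change=-0.07),
        ])
        out = apply_inclusion_rules(data, tissue="foliar")
        assert len(out) == 1
        assert out.records[0].relative_change == -0.07

    def test_highest_nutrient_regime_kept(self):
        data = Dataset.from_records([
            make_record(study_id="S1", nutrient_regime=1),
            make_record(study_id="S1", nutrient_regime=2,
                        relative_change=-0.05),
        ])
        out = apply_inclusion_rules(data, tissue="foliar")
        assert len(out) == 1
        assert out.records[0].nutrient_regime == 2

    def test_missing_annotation_raises_with_field_name(self):
        data = Dataset.from_records([
            make_record(study_id="S1", time_point_index=1),
            make_record(study_id="S1", time_point_index=None,
                        relative_change=-0.05),
        ])
        with pytest.raises(UnresolvedGroupError, match="time_point_index"):
            apply_inclusion_rules(data, tissue="foliar")

    def test_three_codependent_datasets_averaged(self):
        data = Dataset.from_records([
            make_record(study_id="S1", relative_change=rc, n_replicates=n)
            for rc, n in [(-0.06, 3), (-0.09, 4), (-0.12, 5)]
        ])
        out = apply_inclusion_rules(data, tissue="foliar")
        assert len(out) == 1
        rec = out.records[0]
        assert rec.relative_change == pytest.approx(-0.09)
        assert rec.n_replicates == 4

    def test_two_surviving_records_both_kept(self):
        data = Dataset.from_records([
            make_record(study_id="S1", relative_change=-0.06),
            make_record(study_id="S1", relative_change=-0.12),
        ])
        assert len(apply_inclusion_rules(data, tissue="foliar")) == 2

    def test_idempotent(self, synthetic_dataset):
        once = apply_inclusion_rules(synthetic_dataset, tissue="foliar")
        twice = apply_inclusion_rules(once, tissue="foliar")
        assert once.records == twice.records

    def test_resolved_dataset_unique_per_study_element(self):
        data = Dataset.from_records([
            co2_arm("S1", 370, 550), co2_arm("S1", 370, 750),
            make_record(study_id="S2", element="Fe"),
        ])
        out = apply_inclusion_rules(data, tissue="foliar")
        keys = [(r.study_id, r.element, r.tissue) for r in out.records]
        assert len(keys) == len(set(keys))
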