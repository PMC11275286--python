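"""Manifest parsing, the uncertain-to-positive label policy, pairing and
patient-level splitting."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import write_manifest
from vaefusion.errors import ConfigurationError, DegenerateInputError
from vaefusion.manifest_io import (DROP, Projection, RawLabel, StudyRecord,
                                   View, build_pairs, parse_manifest,
                                   resolve_label, split_dataset,
                                   write_pairs_table)


def record(patient, view, path, raw_label=RawLabel.POSITIVE):
    proj = Projection.PA if view is View.FRONTAL else Projection.LA
    return StudyRecord(patient_id=patient, study_id="study1", view=view,
                       projection=proj, image_path=path, raw_label=raw_label)


class TestParseManifest:
    def test_coding_table(self, tmp_path):
        manifest = write_manifest(tmp_path / "m.csv", [
            ("patient00001/study1/f.png", "Frontal", "PA", "1.0"),
            ("patient00002/study1/f.png", "Frontal", "AP", "0.0"),
            ("patient00003/study1/f.png", "Frontal", "PA", "-1.0"),
            ("patient00004/study1/l.png", "Lateral", "Lateral", ""),
        ])
        records = parse_manifest(manifest, "Pneumonia")
        assert [r.raw_label for r in records] == [
            RawLabel.POSITIVE, RawLabel.NEGATIVE, RawLabel.UNCERTAIN,
            RawLabel.MISSING]
        assert records[3].view is View.LATERAL
        assert records[3].projection is Projection.LA

    def test_missing_column_names_it(self, tmp_path):
        manifest = write_manifest(tmp_path / "m.csv", [
            ("patient00001/study1/f.png", "Frontal", "PA", "1.0")])
        with pytest.raises(ConfigurationError, match="Edema"):
            parse_manifest(manifest, "Edema")

    def test_bad_rows_skipped_with_warning(self, tmp_path, caplog):
        manifest = write_manifest(tmp_path / "m.csv", [
            ("patient00001/study1/f.png", "Frontal", "PA", "1.0"),
            ("nopatient/study1/f.png", "Frontal", "PA", "1.0"),
            ("patient00003/study1/f.png", "Frontal", "", "1.0"),  # bad proj
            ("patient00004/study1/f.png", "Sideways", "PA", "1.0"),
        ])
        with caplog.at_level(logging.WARNING, logger="vaefusion.manifest_io"):
            records = parse_manifest(manifest, "Pneumonia")
        assert len(records) == 1
        assert sum("skipping manifest row" in m for m in caplog.messages) == 3


class TestResolveLabel:
    @pytest.mark.parametrize("raw,expected", [
        (RawLabel.POSITIVE, 1), (RawLabel.UNCERTAIN, 1),
        (RawLabel.NEGATIVE, 0), (RawLabel.MISSING, DROP)])
    def test_policy_total_mapping(self, raw, expected):
        assert resolve_label(raw) is expected or resolve_label(raw) == expected

    def test_image_is_binary_or_drop(self):
        outputs = {resolve_label(r) for r in RawLabel}
        assert outputs == {0, 1, DROP}


class TestBuildPairs:
    def test_one_of_each_view_pairs(self):
        pairs = build_pairs([record("p1", View.FRONTAL, "a.png"),
                             record("p1", View.LATERAL, "b.png")])
        assert len(pairs) == 1
        assert pairs[0].label == 1

    def test_single_view_patient_excluded(self):
        assert build_pairs([record("p1", View.FRONTAL, "a.png")]) == []

    def test_multiple_frontals_pick_lexicographic_first(self):
        pairs = build_pairs([record("p1", View.FRONTAL, "z_late.png"),
                             record("p1", View.FRONTAL, "a_first.png"),
                             record("p1", View.LATERAL, "lat.png")])
        assert len(pairs) == 1
        assert pairs[0].frontal.image_path == "a_first.png"

    def test_missing_label_drops_record_before_pairing(self):
        pairs = build_pairs([
            record("p1", View.FRONTAL, "a.png", RawLabel.MISSING),
            record("p1", View.LATERAL, "b.png")])
        assert pairs == []

    def test_label_disagreement_uses_frontal_and_warns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="vaefusion.manifest_io"):
            pairs = build_pairs([
                record("p1", View.FRONTAL, "a.png", RawLabel.NEGATIVE),
                record("p1", View.LATERAL, "b.png", RawLabel.POSITIVE)])
        assert pairs[0].label == 0
        assert any("disagrees" in m for m in caplog.messages)

    def test_empty_input_is_empty_output(self):
        assert build_pairs([]) == []

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 10), st.booleans()), max_size=40))
    def test_pair_count_bounded_by_distinct_patients(self, spec):
        records = [record(f"p{pid}", View.FRONTAL if front else View.LATERAL,
                          f"img{i}.png")
                   for i, (pid, front) in enumerate(spec)]
        pairs = build_pairs(records)
        assert len(pairs) <= len({r.patient_id for r in records})


class TestSplitDataset:
    def _pairs(self, n):
        return [build_pairs([record(f"p{i:03d}", View.FRONTAL, f"f{i}.png"),
                             record(f"p{i:03d}", View.LATERAL, f"l{i}.png")])[0]
                for i in range(n)]

    def test_ten_patients_eight_two(self):
        split = split_dataset(self._pairs(10), 0.8, seed=7)
        assert len(split.train) == 8 and len(split.test) == 2

    def test_deterministic_for_fixed_seed(self):
        pairs = self._pairs(20)
        a = split_dataset(pairs, 0.8, seed=3)
        b = split_dataset(pairs, 0.8, seed=3)
        assert [p.patient_id for p in a.train] == [p.patient_id for p in b.train]
        assert [p.patient_id for p in a.test] == [p.patient_id for p in b.test]

    def test_no_patient_leaks_across_sides(self):
        split = split_dataset(self._pairs(100), 0.8, seed=11)
        train_ids = {p.patient_id for p in split.train}
        test_ids = {p.patient_id for p in split.test}
        assert not train_ids & test_ids

    def test_partition_preserves_all_pairs(self):
        pairs = self._pairs(17)
        split = split_dataset(pairs, 0.8, seed=5)
        combined = sorted(p.patient_id for p in split.train + split.test)
        assert combined == sorted(p.patient_id for p in pairs)

    def test_fewer_than_two_patients_rejected(self):
        with pytest.raises(DegenerateInputError):
            split_dataset(self._pairs(1), 0.8, seed=0)

    def test_bad_ratio_rejected(self):
        with pytest.raises(ConfigurationError):
            split_dataset(self._pairs(5), 1.5, seed=0)


def test_parse_resolve_pair_split_rerun_is_byte_identical(tmp_path, tiny_dataset):
    def run(out):
        records = parse_manifest(tiny_dataset["manifest"], "Pneumonia")
        split = split_dataset(build_pairs(records), 0.8, seed=9)
        write_pairs_table(split, out)
        return out.read_bytes()

    assert run(tmp_path / "a.csv") == run(tmp_path / "b.csv")
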