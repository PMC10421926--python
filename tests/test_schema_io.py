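"""Schema parsing, cohort table IO, outlier filtering and padding."""

import numpy as np
import pytest
import yaml

from synthehr.data import (derive_masks, filter_outliers, read_cohort, train_test_split,
                           truncate_pad, validate_cohort, write_cohort)
from synthehr.schema import FeatureSchema, SchemaError, load_schema, save_schema
from synthehr.toygen import generate_cohort

from conftest import tiny_config


def write_yaml(tmp_path, cfg):
    p = tmp_path / "schema.yaml"
    p.write_text(yaml.safe_dump(cfg))
    return p


class TestLoadSchema:
    def test_inpatient_cohort_layout(self, tmp_path):
        """3 static numeric + 3 static categorical + 75 temporal numeric +
        8 temporal categorical, T_max=30 (critical-care cohort shape)."""
        cfg = {
            "static_numeric": ["age", "weight", "mortality"],
            "static_categorical": [{"gender": ["F", "M"]},
                                   {"marital": ["m", "s", "w"]},
                                   {"religion": ["a", "b", "c"]}],
            "temporal_numeric": [f"lab_{i}" for i in range(75)],
            "temporal_categorical": [{f"obs_{i}": ["x", "y", "z"]} for i in range(8)],
            "time_name": "time",
            "max_seq_len": 30,
        }
        schema = load_schema(write_yaml(tmp_path, cfg))
        assert len(schema.static_numeric) == 3
        assert len(schema.static_categorical) == 3
        assert len(schema.temporal_numeric) == 75
        assert len(schema.temporal_categorical) == 8
        assert schema.max_seq_len == 30

    def test_minimal_schema(self, tmp_path):
        cfg = {"temporal_numeric": ["hr"], "max_seq_len": 1}
        schema = load_schema(write_yaml(tmp_path, cfg))
        assert schema.temporal_numeric == ("hr",)
        assert schema.max_seq_len == 1

    def test_duplicate_feature_name_rejected(self, tmp_path):
        cfg = {"static_numeric": ["age"], "temporal_numeric": ["age"]}
        with pytest.raises(SchemaError, match="age"):
            load_schema(write_yaml(tmp_path, cfg))

    def test_empty_vocabulary_rejected(self, tmp_path):
        cfg = {"static_categorical": [{"gender": []}], "temporal_numeric": ["hr"]}
        with pytest.raises(SchemaError, match="vocabulary"):
            load_schema(write_yaml(tmp_path, cfg))

    def test_vocabulary_deduplicated_preserving_order(self, tmp_path):
        cfg = {"static_categorical": [{"g": ["b", "a", "b", "c"]}]}
        schema = load_schema(write_yaml(tmp_path, cfg))
        assert schema.static_categorical[0][1] == ("b", "a", "c")

    def test_save_load_round_trip(self, tmp_path, tiny_cohort):
        schema = tiny_cohort[2]["schema"]
        save_schema(schema, tmp_path / "s.yaml")
        assert load_schema(tmp_path / "s.yaml") == schema


class TestReadWrite:
    def test_round_trip_is_identity(self, tmp_path, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        schema = gt["schema"]
        paths = write_cohort(dataset, masks, schema, tmp_path)
        back, back_masks = read_cohort(paths["static"], paths["temporal"], schema)
        back, back_masks = truncate_pad(back, back_masks, dataset.n_steps)
        assert np.array_equal(back.ids, dataset.ids)
        assert np.array_equal(back.lengths, dataset.lengths)
        assert np.array_equal(back.static_num, dataset.static_num, equal_nan=True)
        assert np.array_equal(back.static_cat, dataset.static_cat)
        assert np.array_equal(back.times, dataset.times)
        assert np.array_equal(back.temp_num, dataset.temp_num, equal_nan=True)
        assert np.array_equal(back.temp_cat, dataset.temp_cat)
        for f in ("static_num", "static_cat", "temp_num", "temp_cat", "step_present"):
            assert np.array_equal(getattr(back_masks, f), getattr(masks, f))

    def test_missing_entry_gets_mask_zero(self, tmp_path):
        schema = FeatureSchema((), (), ("hr", "bp"), (), max_seq_len=4)
        (tmp_path / "static.csv").write_text("patient_id\np1\n")
        (tmp_path / "temporal.csv").write_text(
            "patient_id,time,feature,value\n"
            "p1,1.0,hr,80\np1,1.0,bp,120\np1,2.0,hr,82\n")
        ds, ms = read_cohort(tmp_path / "static.csv", tmp_path / "temporal.csv", schema)
        assert ds.lengths[0] == 2
        assert ms.temp_num[0, 1, 1] == 0 and np.isnan(ds.temp_num[0, 1, 1])
        assert ms.temp_num[0, 0, 1] == 1

    def test_unknown_temporal_feature_listed_in_error(self, tmp_path):
        schema = FeatureSchema((), (), ("hr",), (), max_seq_len=4)
        (tmp_path / "static.csv").write_text("patient_id\np1\n")
        (tmp_path / "temporal.csv").write_text(
            "patient_id,time,feature,value\np1,1.0,oxygen,5\n")
        with pytest.raises(SchemaError, match="oxygen"):
            read_cohort(tmp_path / "static.csv", tmp_path / "temporal.csv", schema)

    def test_patient_without_temporal_rows_rejected(self, tmp_path):
        schema = FeatureSchema((), (), ("hr",), (), max_seq_len=4)
        (tmp_path / "static.csv").write_text("patient_id\np1\np2\n")
        (tmp_path / "temporal.csv").write_text(
            "patient_id,time,feature,value\np1,1.0,hr,80\n")
        with pytest.raises(SchemaError, match="p2"):
            read_cohort(tmp_path / "static.csv", tmp_path / "temporal.csv", schema)

    def test_all_observed_row_count_formula(self, tmp_path):
        """Fully observed cohort: rows = sum(T(i)) * (n_features + 1 time row)."""
        config = tiny_config(seed=3, n=40,
                             missing_rates={}, static_missing_rates={})
        dataset, masks, gt = generate_cohort(config)
        paths = write_cohort(dataset, masks, gt["schema"], tmp_path)
        n_rows = sum(1 for _ in open(paths["temporal"])) - 1  # header
        n_feat = len(gt["schema"].temporal_numeric) + len(gt["schema"].temporal_categorical)
        assert n_rows == dataset.lengths.sum() * (n_feat + 1)

    def test_empty_cohort_round_trip(self, tmp_path):
        schema = FeatureSchema((), (), ("hr",), (), max_seq_len=2)
        from synthehr.data import EHRDataset

        empty = EHRDataset(np.array([], dtype=object), np.zeros((0, 0)),
                           np.zeros((0, 0), dtype=np.int64), np.zeros((0, 2)),
                           np.zeros((0, 2, 1)), np.zeros((0, 2, 0), dtype=np.int64),
                           np.zeros(0, dtype=np.int64))
        masks = derive_masks(empty)
        paths = write_cohort(empty, masks, schema, tmp_path)
        back, _ = read_cohort(paths["static"], paths["temporal"], schema)
        assert back.n_patients == 0


class TestFilterOutliers:
    def make(self, values):
        config = tiny_config(seed=0, n=len(values), missing_rates={}, static_missing_rates={})
        dataset, masks, gt = generate_cohort(config)
        dataset.static_num[:, 0] = values
        return dataset, derive_masks(dataset), gt["schema"]

    def test_default_percentiles_remove_two_extremes(self):
        dataset, masks, schema = self.make(np.arange(1.0, 1001.0))
        out, out_masks = filter_outliers(dataset, masks, schema)
        removed = masks.static_num[:, 0].sum() - out_masks.static_num[:, 0].sum()
        assert removed == 2  # values 1 and 1000
        assert np.isnan(out.static_num[0, 0]) and np.isnan(out.static_num[-1, 0])

    def test_constant_feature_untouched(self):
        dataset, masks, schema = self.make(np.full(100, 7.0))
        out, out_masks = filter_outliers(dataset, masks, schema)
        assert out_masks.static_num[:, 0].sum() == 100

    def test_identity_bounds_change_nothing(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        out, out_masks = filter_outliers(dataset, masks, gt["schema"], 0.0, 1.0)
        assert np.array_equal(out.temp_num, dataset.temp_num, equal_nan=True)
        assert np.array_equal(out_masks.temp_num, masks.temp_num)

    def test_tightening_never_unmasks(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        loose, lm = filter_outliers(dataset, masks, gt["schema"], 0.01, 0.99)
        tight, tm = filter_outliers(dataset, masks, gt["schema"], 0.05, 0.95)
        assert np.all(tm.temp_num <= lm.temp_num)
        assert np.all(tm.static_num <= lm.static_num)

    def test_drop_patient_mode_removes_whole_records(self):
        dataset, masks, schema = self.make(np.arange(1.0, 201.0))
        out, _ = filter_outliers(dataset, masks, schema, mode="drop_patient")
        assert out.n_patients < dataset.n_patients

    def test_invalid_bounds_rejected(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        with pytest.raises(ValueError):
            filter_outliers(dataset, masks, gt["schema"], 0.9, 0.1)


class TestTruncatePad:
    def test_long_sequences_keep_last_steps(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        out, om = truncate_pad(dataset, masks, 3)
        i = int(np.argmax(dataset.lengths >= 5))
        L = dataset.lengths[i]
        assert np.array_equal(out.times[i, :3], dataset.times[i, L - 3: L])
        assert out.lengths[i] == 3

    def test_short_sequences_padded_with_absent_steps(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        out, om = truncate_pad(dataset, masks, 50)
        i = int(np.argmin(dataset.lengths))
        L = out.lengths[i]
        assert om.step_present[i, L:].sum() == 0
        assert np.all(np.isnan(out.temp_num[i, L:]))
        assert np.all(out.times[i, L:] == 0)

    def test_tmax_one_keeps_final_visit(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        out, om = truncate_pad(dataset, masks, 1)
        assert np.all(out.lengths == 1)
        i = 0
        assert out.times[i, 0] == dataset.times[i, dataset.lengths[i] - 1]

    def test_truncation_is_idempotent(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        once = truncate_pad(dataset, masks, 5)
        twice = truncate_pad(*once, 5)
        assert np.array_equal(once[0].temp_num, twice[0].temp_num, equal_nan=True)
        assert np.array_equal(once[1].step_present, twice[1].step_present)

    def test_mask_value_consistency_preserved(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        out, om = truncate_pad(dataset, masks, 5)
        validate_cohort(out, om, gt["schema"])


class TestSplit:
    def test_split_is_disjoint_and_80_20(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        (tr, _), (te, _) = train_test_split(dataset, masks, seed=0)
        assert tr.n_patients + te.n_patients == dataset.n_patients
        assert te.n_patients == round(0.2 * dataset.n_patients)
        assert not set(tr.ids) & set(te.ids)
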