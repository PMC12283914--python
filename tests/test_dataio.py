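"""Tests of feature-table I/O, temporal preprocessing, and subject splits."""

import numpy as np
import pandas as pd
import pytest

from conformalbp import dataio, synth
from conformalbp.schema import COLUMNS, DAYTIME, NIGHTTIME
from conftest import make_records


class TestReadWrite:
    def test_cohort_csv_roundtrip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        dataio.write_feature_table(small_cohort, path)
        back = dataio.read_feature_table(path)
        ref = small_cohort.sort_values(["subject_id", "timestamp"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(back, ref, check_exact=False, rtol=0, atol=1e-9)

    def test_row_with_missing_reference_flagged_invalid(self, tmp_path):
        df = make_records([("A", "2024-01-01 08:00", DAYTIME, True),
                           ("A", "2024-01-01 09:00", DAYTIME, True)])
        df.loc[1, "sbp_ref"] = np.nan
        path = tmp_path / "t.csv"
        dataio.write_feature_table(df, path)
        back = dataio.read_feature_table(path)
        assert len(back) == 2  # flagged, not dropped
        assert back["valid"].tolist() == [True, False]

    def test_empty_file_with_header_ok(self, tmp_path):
        path = tmp_path / "empty.csv"
        pd.DataFrame(columns=list(COLUMNS)).to_csv(path, index=False)
        back = dataio.read_feature_table(path)
        assert len(back) == 0 and tuple(back.columns) == COLUMNS

    def test_missing_column_raises(self, tmp_path):
        df = make_records([("A", "2024-01-01 08:00", DAYTIME, True)])
        path = tmp_path / "bad.csv"
        df.drop(columns=["rpat"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="rpat"):
            dataio.read_feature_table(path)

    def test_unparseable_timestamp_raises(self, tmp_path):
        df = make_records([("A", "2024-01-01 08:00", DAYTIME, True)])
        df["timestamp"] = "not-a-time"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="timestamp"):
            dataio.read_feature_table(path)


class TestDownsampleDaytime:
    def test_first_valid_measurement_represents_the_hour(self):
        df = make_records([("A", "2024-01-01 09:00", DAYTIME, True),
                           ("A", "2024-01-01 09:30", DAYTIME, True)])
        out = dataio.downsample_daytime(df)
        assert len(out) == 1
        assert out.iloc[0]["timestamp"] == pd.Timestamp("2024-01-01 09:00")

    def test_second_measurement_used_when_first_invalid(self):
        df = make_records([("A", "2024-01-01 09:00", DAYTIME, False),
                           ("A", "2024-01-01 09:30", DAYTIME, True)])
        out = dataio.downsample_daytime(df)
        assert len(out) == 1
        assert out.iloc[0]["timestamp"] == pd.Timestamp("2024-01-01 09:30")

    def test_nighttime_records_pass_through(self):
        df = make_records([("A", "2024-01-01 22:00", NIGHTTIME, True),
                           ("A", "2024-01-01 23:00", NIGHTTIME, False)])
        out = dataio.downsample_daytime(df)
        pd.testing.assert_frame_equal(out, df)

    def test_hour_with_no_valid_measurement_left_blank(self):
        df = make_records([("A", "2024-01-01 09:00", DAYTIME, False),
                           ("A", "2024-01-01 09:30", DAYTIME, False),
                           ("A", "2024-01-01 10:00", DAYTIME, True)])
        out = dataio.downsample_daytime(df)
        assert out["timestamp"].tolist() == [pd.Timestamp("2024-01-01 10:00")]


class TestForwardFill:
    def test_blank_slot_copies_previous_record(self):
        df = make_records([("A", "2024-01-01 08:00", DAYTIME, True, 110.0),
                           ("A", "2024-01-01 10:00", DAYTIME, True, 130.0)])
        out = dataio.impute_forward_fill(df)
        assert len(out) == 3
        assert out["sbp_ref"].tolist() == [110.0, 110.0, 130.0]
        assert out["timestamp"].tolist() == list(
            pd.date_range("2024-01-01 08:00", periods=3, freq="h"))

    def test_leading_blank_back_filled_from_first_record(self):
        df = make_records([("A", "2024-01-01 08:00", DAYTIME, False, 105.0),
                           ("A", "2024-01-01 09:00", DAYTIME, True, 125.0)])
        out = dataio.impute_forward_fill(df)
        assert out["sbp_ref"].tolist() == [125.0, 125.0]

    def test_no_gaps_is_identity_on_values(self):
        df = make_records([("A", "2024-01-01 08:00", DAYTIME, True, 111.0),
                           ("A", "2024-01-01 09:00", DAYTIME, True, 112.0)])
        out = dataio.impute_forward_fill(df)
        assert out["sbp_ref"].tolist() == [111.0, 112.0]

    def test_subject_without_valid_records_raises(self):
        df = make_records([("A", "2024-01-01 08:00", DAYTIME, False)])
        with pytest.raises(ValueError, match="no valid"):
            dataio.impute_forward_fill(df)

    def test_preprocess_equalises_per_phase_counts(self):
        cohort = synth.generate_cohort(
            synth.CohortConfig(n_subjects=25, p_missing=0.15, seed=8))
        out = dataio.preprocess(cohort)
        counts = out.groupby(["subject_id", "phase"]).size().unstack()
        assert counts[DAYTIME].nunique() == 1
        assert counts[NIGHTTIME].nunique() == 1
        assert counts[DAYTIME].iloc[0] == counts[NIGHTTIME].iloc[0] == 12
        assert out["valid"].all()


class TestSplitPlans:
    def test_100_subjects_split_60_24_16(self):
        plans = dataio.make_split_plans([f"S{i}" for i in range(100)], seed=0)
        assert len(plans) == 5
        for p in plans:
            assert (len(p.train_subjects), len(p.calibration_subjects),
                    len(p.test_subjects)) == (60, 24, 16)

    def test_10_subjects_split_6_2_2_under_rounding_rule(self):
        (p,) = dataio.make_split_plans([f"S{i}" for i in range(10)],
                                       n_repeats=1, seed=0)
        assert (len(p.train_subjects), len(p.calibration_subjects),
                len(p.test_subjects)) == (6, 2, 2)

    def test_partition_is_disjoint_and_exhaustive(self):
        ids = [f"S{i}" for i in range(37)]
        for p in dataio.make_split_plans(ids, seed=5):
            union = set(p.train_subjects) | set(p.calibration_subjects) | set(p.test_subjects)
            total = len(p.train_subjects) + len(p.calibration_subjects) + len(p.test_subjects)
            assert union == set(ids) and total == len(ids)

    def test_same_seed_gives_identical_plans(self):
        ids = [f"S{i}" for i in range(30)]
        assert dataio.make_split_plans(ids, seed=11) == dataio.make_split_plans(ids, seed=11)
        assert dataio.make_split_plans(ids, seed=11) != dataio.make_split_plans(ids, seed=12)

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            dataio.make_split_plans(["a", "b", "c"], seed=0)

    def test_plans_json_roundtrip(self, tmp_path):
        plans = dataio.make_split_plans([f"S{i}" for i in range(20)], seed=2)
        path = tmp_path / "plans.json"
        dataio.save_split_plans(plans, path)
        assert dataio.load_split_plans(path) == plans
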