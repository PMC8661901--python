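"""Time-window resolution and the sqrt-proportion feature matrix."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from bseqlab.categories import DISTANCE_LABEL, get_scheme
from bseqlab.errors import EmptyInputError, ScheduleError
from bseqlab.features import (
    apply_exclusions,
    available_windows,
    build_features,
    define_windows,
)
from bseqlab.metadata import LabRecord
from conftest import matrix_from_cfg
from bseqlab.synth import SimConfig, simulate_tables

LAB = LabRecord(lab_id="L", light_off_time=dt.time(19, 0),
                light_on_time=dt.time(7, 0))
SPAN = (-120.0, 1260.0)


class TestDefineWindows:
    def test_nine_windows(self):
        assert len(define_windows(LAB, SPAN)) == 9

    def test_last_three_hours_of_a_twelve_hour_night(self):
        w4 = {w.id: w for w in define_windows(LAB, SPAN)}["W4"]
        assert (w4.start, w4.end) == (540.0, 720.0)

    def test_window_six_starts_two_hours_before_dark(self):
        w6 = {w.id: w for w in define_windows(LAB, SPAN)}["W6"]
        assert w6.start == -120.0
        assert w6.end == SPAN[1]

    def test_requires_lights_off_inside_recording(self):
        with pytest.raises(ScheduleError):
            define_windows(LAB, (10.0, 600.0))

    def test_overlap_trio_is_configurable(self):
        custom = define_windows(LAB, SPAN, overlap_trio={"W7": (-60.0, 60.0)})
        w7 = {w.id: w for w in custom}["W7"]
        assert (w7.start, w7.end) == (-60.0, 60.0)


class TestAvailability:
    def test_full_cohort_has_all_nine(self, null_pipeline):
        _, tables, _, lab = null_pipeline
        wins = define_windows(lab, SPAN)
        assert len(available_windows(tables, wins)) == 9

    def test_truncated_animal_drops_late_windows(self, null_pipeline):
        _, tables, _, lab = null_pipeline
        truncated = [t.iloc[:-240].copy() if i == 0 else t
                     for i, t in enumerate(tables)]
        wins = define_windows(lab, SPAN)
        avail = {w.id for w in available_windows(truncated, wins)}
        # recording now ends 4 h early (minute 1020 < W5 end 900 stays)
        assert "W6" not in avail and "W9" not in avail
        assert {"W1", "W2", "W3", "W4", "W5", "W7", "W8"} <= avail

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyInputError):
            available_windows([], define_windows(LAB, SPAN))


class TestBuildFeatures:
    def test_quarter_proportion_gives_half(self, null_pipeline):
        """A category filling 25% of a window has feature sqrt(0.25)=0.5."""
        _, tables, _, lab = null_pipeline
        from bseqlab.categories import RAW_LABELS

        table = tables[0].copy()
        behavior_cols = [c for c in table.columns if c in set(RAW_LABELS)]
        table[behavior_cols] = 0.0
        table["Sleep"] = 45.0
        table["Groom"] = 15.0
        wins = define_windows(lab, SPAN)
        m = build_features([table], wins, get_scheme("berlin"),
                           drop_distance=True)
        assert m.data.iloc[0][f"Groom__W9"] == pytest.approx(0.5)
        assert m.data.iloc[0][f"Immobile__W9"] == pytest.approx(np.sqrt(0.75))

    def test_berlin_nine_windows_with_distance_has_162_columns(
            self, null_matrix):
        assert null_matrix.data.shape[1] == 162

    def test_squared_behavior_features_sum_to_one(self, null_matrix):
        scheme = get_scheme("berlin")
        for wid in null_matrix.window_ids:
            cols = [f"{c}__{wid}" for c in scheme.behavior_labels()]
            sums = (null_matrix.data[cols] ** 2).sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-6)

    def test_behavior_features_within_unit_interval(self, null_matrix):
        behavior = [c for c in null_matrix.data.columns
                    if not c.startswith(DISTANCE_LABEL)]
        assert ((null_matrix.data[behavior] >= 0)
                & (null_matrix.data[behavior] <= 1)).all().all()

    def test_unit_rescaling_invariance(self, null_pipeline):
        """Features do not change if all inputs are rescaled to e.g. ms."""
        _, tables, _, lab = null_pipeline
        wins = define_windows(lab, SPAN)
        scheme = get_scheme("berlin")
        base = build_features(tables[:3], wins, scheme)
        cols = [c for c in tables[0].columns
                if c not in ("animal_id", "test_id", "group", "confound",
                             "minute_index", "bintodark", "phase")]
        scaled_tables = []
        for t in tables[:3]:
            t2 = t.copy()
            t2[cols] = t2[cols] * 1000.0
            scaled_tables.append(t2)
        scaled = build_features(scaled_tables, wins, scheme)
        pd.testing.assert_frame_equal(base.data, scaled.data)

    def test_window_subset_only_removes_columns(self, null_pipeline):
        _, tables, _, lab = null_pipeline
        wins = define_windows(lab, SPAN)
        scheme = get_scheme("berlin")
        full = build_features(tables[:3], wins, scheme)
        subset = build_features(tables[:3], wins[:4], scheme)
        shared = subset.data.columns
        pd.testing.assert_frame_equal(full.data[shared], subset.data)

    def test_drop_distance_gives_153_berlin_columns(self, null_pipeline):
        _, tables, _, lab = null_pipeline
        wins = define_windows(lab, SPAN)
        m = build_features(tables[:2], wins, get_scheme("berlin"),
                           drop_distance=True)
        assert m.data.shape[1] == 17 * 9


class TestExclusions:
    def test_no_flags_is_identity(self, null_pipeline):
        matrix, _, rows, _ = null_pipeline
        out = apply_exclusions(matrix, rows)
        pd.testing.assert_frame_equal(out.data, matrix.data)

    def test_one_of_twentytwo_flagged_leaves_twentyone(self, null_pipeline):
        matrix, _, rows, _ = null_pipeline
        import copy
        rows2 = copy.deepcopy(rows)
        rows2[3].exclude = "inconsistent raw data"
        out = apply_exclusions(matrix, rows2)
        assert matrix.n_rows == 22 and out.n_rows == 21
        assert rows2[3].animal_id not in set(out.animal_ids)

    def test_excluding_commutes_with_building(self):
        cfg = SimConfig(seed=31, n_per_group=3)
        matrix, tables, rows, lab = matrix_from_cfg(cfg)
        import copy
        rows2 = copy.deepcopy(rows)
        rows2[1].exclude = "1"
        excl_after = apply_exclusions(matrix, rows2)
        keep_tables = [t for t in tables
                       if str(t["animal_id"].iloc[0]) != rows2[1].animal_id]
        wins = define_windows(lab, SPAN)
        excl_before = build_features(keep_tables, wins, get_scheme("berlin"))
        pd.testing.assert_frame_equal(excl_after.data, excl_before.data)
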