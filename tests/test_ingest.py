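"""Event parsing, minute binning, synchronization, consistency checks."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bseqlab.categories import RAW_LABELS
from bseqlab.errors import (
    ConsistencyRangeError,
    EmptyInputError,
    OverlappingEventsError,
    UnknownLabelError,
)
from bseqlab.ingest import (
    BehaviorSequence,
    check_consistency,
    events_to_minutes,
    read_events,
    read_hour_summary,
    synchronize,
)
from bseqlab.metadata import ExperimentRow, LabRecord

LAB = LabRecord(lab_id="L", light_off_time=dt.time(19, 0),
                light_on_time=dt.time(7, 0))


def make_seq(rows, animal="A1", test="T1"):
    return BehaviorSequence(
        animal_id=animal, test_id=test,
        events=pd.DataFrame(rows, columns=["start_s", "end_s", "label"]),
    )


def write_events(path, rows):
    pd.DataFrame(rows, columns=["start_s", "end_s", "label"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def brute_force_minutes(rows, n_minutes):
    """Per-second label counting: the independent minute-binning oracle."""
    out = {lab: np.zeros(n_minutes) for lab in RAW_LABELS}
    for start, end, lab in rows:
        for s in range(int(start), int(end)):
            minute = s // 60
            if minute < n_minutes:
                out[lab][minute] += 1
    return pd.DataFrame(out)


class TestReadEvents:
    def test_parses_simple_fixture(self, tmp_path):
        path = write_events(tmp_path / "e.tsv", [
            (0, 10, "Sleep"), (10, 12, "Twitch"), (12, 60, "Sleep"),
        ])
        seq = read_events(path)
        assert len(seq.events) == 3
        assert list(seq.events["label"]) == ["Sleep", "Twitch", "Sleep"]

    def test_out_of_order_rows_sorted_with_warning(self, tmp_path):
        path = write_events(tmp_path / "e.tsv", [
            (10, 12, "Twitch"), (0, 10, "Sleep"), (12, 60, "Sleep"),
        ])
        with pytest.warns(UserWarning, match="out of order"):
            seq = read_events(path)
        assert seq.events["start_s"].is_monotonic_increasing

    def test_unknown_label_rejected(self, tmp_path):
        path = write_events(tmp_path / "e.tsv", [(0, 10, "Napping")])
        with pytest.raises(UnknownLabelError):
            read_events(path)

    def test_overlap_rejected(self, tmp_path):
        path = write_events(tmp_path / "e.tsv", [
            (0, 30, "Sleep"), (20, 40, "Groom"),
        ])
        with pytest.raises(OverlappingEventsError):
            read_events(path)

    def test_empty_file_rejected(self, tmp_path):
        path = write_events(tmp_path / "e.tsv", [])
        with pytest.raises(EmptyInputError):
            read_events(path)


class TestEventsToMinutes:
    def test_exact_two_minute_split(self):
        minutes = events_to_minutes(make_seq([(0, 120, "Sleep")]))
        assert list(minutes["Sleep"]) == [60.0, 60.0]

    def test_boundary_split(self):
        minutes = events_to_minutes(make_seq([
            (0, 50, "Sleep"), (50, 70, "Eat.Z1."), (70, 120, "Sleep"),
        ]))
        assert minutes.loc[0, "Eat.Z1."] == pytest.approx(10.0)
        assert minutes.loc[1, "Eat.Z1."] == pytest.approx(10.0)

    def test_trailing_partial_minute_dropped(self):
        minutes = events_to_minutes(make_seq([(0, 150, "Sleep")]))
        assert len(minutes) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_second_oracle_on_random_fixture(self, seed):
        rng = np.random.default_rng(seed)
        t, rows = 0, []
        while t < 600:
            dur = int(rng.integers(1, 90))
            rows.append((t, t + dur, str(rng.choice(RAW_LABELS[:40]))))
            t += dur
        seq = make_seq(rows)
        minutes = events_to_minutes(seq)
        oracle = brute_force_minutes(rows, len(minutes))
        for lab in RAW_LABELS:
            assert np.allclose(minutes[lab], oracle[lab])

    @given(st.lists(
        st.tuples(st.integers(1, 90), st.sampled_from(RAW_LABELS[:12])),
        min_size=1, max_size=40,
    ))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_time_conservation_property(self, chunks):
        """For any contiguous event sequence, binned seconds per label equal
        event durations up to the dropped trailing partial minute."""
        t, rows = 0, []
        for dur, lab in chunks:
            rows.append((t, t + dur, lab))
            t += dur
        seq = make_seq(rows)
        minutes = events_to_minutes(seq)
        per_label = seq.total_seconds_per_label()
        binned = minutes[list(RAW_LABELS)].to_numpy().sum()
        assert binned == pytest.approx(len(minutes) * 60.0)
        assert binned <= per_label.sum() + 1e-9
        for lab in per_label.index:
            assert minutes[lab].sum() <= per_label[lab] + 1e-9

    def test_time_conservation(self):
        """Total seconds per label survive minute binning (+ dropped tail)."""
        rows = [(0, 61, "Sleep"), (61, 100, "Groom"), (100, 187, "Sniff")]
        seq = make_seq(rows)
        minutes = events_to_minutes(seq)
        binned = minutes[list(RAW_LABELS)].to_numpy().sum()
        tail = 187 - len(minutes) * 60
        assert binned + tail == pytest.approx(187)


class TestHourSummary:
    def test_hour_expands_to_sixty_minutes(self, tmp_path):
        path = tmp_path / "h.csv"
        pd.DataFrame({"Eat.Z1.": [600.0], "Sleep": [3000.0]}).to_csv(
            path, index=False)
        minutes = read_hour_summary(path)
        assert len(minutes) == 60
        assert (minutes["Eat.Z1."] == 10.0).all()

    def test_zero_hour_stays_zero(self, tmp_path):
        path = tmp_path / "h.csv"
        pd.DataFrame({"Sleep": [0.0]}).to_csv(path, index=False)
        minutes = read_hour_summary(path)
        assert (minutes["Sleep"] == 0.0).all()

    def test_reaggregation_inverts_expansion(self, tmp_path):
        rng = np.random.default_rng(3)
        hours = pd.DataFrame(
            rng.uniform(0, 3600, size=(5, 3)),
            columns=["Sleep", "Groom", "Sniff"],
        )
        path = tmp_path / "h.csv"
        hours.to_csv(path, index=False)
        minutes = read_hour_summary(path)
        back = minutes.groupby(minutes["minute_index"] // 60)[
            ["Sleep", "Groom", "Sniff"]].sum()
        assert np.allclose(back.to_numpy(), hours.to_numpy())


def _row(start):
    return ExperimentRow(animal_id="A1", test_id="T1", group="g",
                         recording_start=start, data_file="x.tsv")


class TestSynchronize:
    def test_hour_before_lights_off(self):
        minutes = events_to_minutes(make_seq([(0, 3600, "Sleep")]))
        sync = synchronize(minutes, _row(dt.datetime(2026, 3, 2, 18, 0)), LAB)
        assert sync.loc[0, "bintodark"] == pytest.approx(-60.0)
        assert sync.loc[0, "phase"] == "DAY"

    def test_minute_at_lights_off_is_night(self):
        minutes = events_to_minutes(make_seq([(0, 3600, "Sleep")]))
        sync = synchronize(minutes, _row(dt.datetime(2026, 3, 2, 19, 0)), LAB)
        assert sync.loc[0, "bintodark"] == pytest.approx(0.0)
        assert sync.loc[0, "phase"] == "NIGHT"

    def test_phase_matches_bintodark_rule(self):
        minutes = events_to_minutes(make_seq([(0, 8 * 3600, "Sleep")]))
        sync = synchronize(minutes, _row(dt.datetime(2026, 3, 2, 17, 0)), LAB)
        night = np.mod(sync["bintodark"], 24 * 60) < LAB.night_length_minutes
        assert (np.where(night, "NIGHT", "DAY") == sync["phase"]).all()

    def test_behavior_columns_untouched(self):
        minutes = events_to_minutes(make_seq([(0, 7200, "Groom")]))
        sync = synchronize(minutes, _row(dt.datetime(2026, 3, 2, 12, 30)), LAB)
        assert np.allclose(sync["Groom"], minutes["Groom"])
        assert (np.diff(sync["bintodark"]) > 0).all()


class TestConsistency:
    def _tables(self):
        minutes = events_to_minutes(make_seq([(0, 600, "Sleep")]))
        a = minutes.copy()
        a.insert(0, "animal_id", "A1")
        a.insert(1, "test_id", "T1")
        return a, a.copy()

    def test_identical_tables_consistent(self):
        a, b = self._tables()
        report = check_consistency(a, b, tol_s=1.0)
        assert report.consistent
        assert report.n_compared == 10

    def test_forced_discrepancy_flagged(self):
        a, b = self._tables()
        b.loc[4, "Eat.Z1."] = b.loc[4, "Eat.Z1."] + 30.0
        report = check_consistency(a, b, tol_s=1.0)
        assert not report.consistent
        assert set(report.flagged["minute_index"]) == {4}
        assert set(report.flagged["label"]) == {"Eat.Z1."}

    def test_disjoint_ranges_rejected(self):
        a, b = self._tables()
        b["minute_index"] = b["minute_index"] + 100
        with pytest.raises(ConsistencyRangeError):
            check_consistency(a, b)
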