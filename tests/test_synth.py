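"""The synthetic recording generator: invariants, ground truth, defects."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from bseqlab.categories import get_scheme
from bseqlab.features import available_windows, define_windows
from bseqlab.ingest import check_consistency, events_to_minutes, load_minutes, read_events
from bseqlab.metadata import load_project, validate_project
from bseqlab.synth import (
    STATE_LABELS,
    SimConfig,
    corrupt,
    simulate_project,
    simulate_sequence,
    simulate_tables,
)


@pytest.mark.parametrize("seed", [0, 3, 17])
def test_generated_sequences_satisfy_invariants(seed):
    cfg = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    seq = simulate_sequence(cfg, "A01", "T1", 0, rng)
    ev = seq.events
    assert (ev["end_s"] > ev["start_s"]).all()
    assert (ev["start_s"].to_numpy()[1:] >= ev["end_s"].to_numpy()[:-1]).all()
    assert set(ev["label"]) <= set(STATE_LABELS)
    assert float(ev["end_s"].max()) <= cfg.recording_minutes * 60 + 1e-6


def test_same_seed_gives_byte_identical_projects(tmp_path):
    cfg = SimConfig(seed=5, n_per_group=2)
    a = simulate_project(cfg, tmp_path / "a")
    b = simulate_project(cfg, tmp_path / "b")
    files_a = sorted(p.relative_to(tmp_path / "a")
                     for p in (tmp_path / "a").rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(tmp_path / "b")
                     for p in (tmp_path / "b").rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel,
                           shallow=False), rel


def test_simulated_project_validates_cleanly(small_project):
    master, cfg = small_project
    bundle = load_project(master, cfg.proj_name)
    assert validate_project(bundle) == []


def test_minute_summaries_equal_binned_events(small_project):
    """Generator-written summaries are the minute binning of the events."""
    master, cfg = small_project
    bundle = load_project(master, cfg.proj_name)
    row = bundle.experiments[0]
    summary = pd.read_csv(bundle.data_path(row))
    events_path = bundle.data_path(row).parent / row.extra["events_file"]
    seq = read_events(events_path, row.animal_id, row.test_id)
    minutes = events_to_minutes(seq)
    for col in minutes.columns:
        if col in ("minute_index", "Travel.m."):  # distance is simulated
            continue
        assert np.allclose(summary[col], minutes[col], atol=1e-9), col


def test_time_shares_converge_to_stationary_ground_truth():
    """Pooled over 10x the default recording length (circadian modulation
    and animal noise off), time shares approach propensity x dwell."""
    cfg = SimConfig(seed=2, animal_sigma=0.0, night_activity_factor=1.0)
    rng = np.random.default_rng(2)
    shares = pd.Series(0.0, index=list(STATE_LABELS))
    total = 0.0
    for _ in range(10):
        seq = simulate_sequence(cfg, "A", "T", 0, rng)
        dur = (seq.events["end_s"] - seq.events["start_s"]).groupby(
            seq.events["label"]).sum()
        shares = shares.add(dur, fill_value=0.0)
        total += float(dur.sum())
    observed = shares / total
    expected = cfg.stationary_shares("DAY")  # all phases identical here
    assert (observed - expected).abs().max() < 0.05
    major = expected[expected > 0.02].index
    assert np.allclose(observed[major], expected[major], rtol=0.05)


def test_planted_night_effect_shifts_walk_in_planted_direction():
    cfg = SimConfig(seed=4, n_per_group=4,
                    effects=(("WalkLeft", "NIGHT", 3.0),
                             ("WalkRght", "NIGHT", 3.0)))
    tables, rows, lab = simulate_tables(cfg)
    walk_night = []
    for t in tables:
        night = t["phase"] == "NIGHT"
        walk_night.append(
            float(t.loc[night, ["WalkLeft", "WalkRght"]].sum().sum()))
    control = np.mean(walk_night[:4])
    treated = np.mean(walk_night[4:])
    assert treated > 1.5 * control


class TestCorrupt:
    def test_scaled_category_is_flagged_by_consistency_check(
            self, small_project, tmp_path):
        master, cfg = small_project
        truth = corrupt(master, cfg.proj_name, tmp_path / "c",
                        mode="scale_category", seed=0)
        bundle = load_project(tmp_path / "c" / Path(master).name,
                              cfg.proj_name)
        flagged_animals = []
        for row in bundle.experiments:
            summary = load_minutes(bundle, row)
            events_path = (bundle.data_path(row).parent
                           / row.extra["events_file"])
            seq = read_events(events_path, row.animal_id, row.test_id)
            from_events = events_to_minutes(seq)
            from_events.insert(0, "animal_id", row.animal_id)
            from_events.insert(1, "test_id", row.test_id)
            report = check_consistency(from_events, summary, tol_s=1.0)
            if not report.consistent:
                flagged_animals.append(row.animal_id)
        assert flagged_animals == [truth["animal_id"]]

    def test_truncation_drops_end_anchored_windows(self, small_project,
                                                   tmp_path):
        master, cfg = small_project
        corrupt(master, cfg.proj_name, tmp_path / "t", mode="truncate",
                seed=1, minutes_cut=120)
        bundle = load_project(tmp_path / "t" / Path(master).name,
                              cfg.proj_name)
        tables = [load_minutes(bundle, r) for r in bundle.experiments]
        span = (min(float(t["bintodark"].min()) for t in tables),
                max(float(t["bintodark"].max()) for t in tables) + 1.0)
        avail = {w.id for w in available_windows(
            tables, define_windows(bundle.lab, span))}
        assert "W6" not in avail and "W9" not in avail
        assert {"W1", "W2", "W3", "W4", "W5", "W7", "W8"} <= avail

    def test_shift_mode_flagged(self, small_project, tmp_path):
        master, cfg = small_project
        truth = corrupt(master, cfg.proj_name, tmp_path / "s",
                        mode="shift_minutes", seed=2)
        bundle = load_project(tmp_path / "s" / Path(master).name,
                              cfg.proj_name)
        row = next(r for r in bundle.experiments
                   if r.animal_id == truth["animal_id"])
        summary = load_minutes(bundle, row)
        events_path = bundle.data_path(row).parent / row.extra["events_file"]
        seq = read_events(events_path, row.animal_id, row.test_id)
        from_events = events_to_minutes(seq)
        from_events.insert(0, "animal_id", row.animal_id)
        from_events.insert(1, "test_id", row.test_id)
        assert not check_consistency(from_events, summary).consistent

    def test_unknown_mode_rejected(self, small_project, tmp_path):
        master, cfg = small_project
        with pytest.raises(ValueError):
            corrupt(master, cfg.proj_name, tmp_path / "x", mode="noop")


def test_distance_tracks_walking(small_project):
    master, cfg = small_project
    bundle = load_project(master, cfg.proj_name)
    summary = pd.read_csv(bundle.data_path(bundle.experiments[0]))
    walk = summary[["WalkLeft", "WalkRght", "WalkSlow", "Turn", "Circle"]].sum(axis=1)
    r = np.corrcoef(walk, summary["Travel.m."])[0, 1]
    assert r > 0.8
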