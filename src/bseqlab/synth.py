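"""Synthetic home-cage recordings with known ground truth.

The generator emits complete fake projects -- master registry row,
experiment and lab spreadsheets, per-animal event TSVs and minute-summary
CSVs -- so that every pipeline stage and every statistical property can be
exercised without any real recording.  Behavior is a semi-Markov chain over
the 45 raw labels: states are drawn with label-specific propensities and
held for exponentially distributed dwell times; activity-type labels are
up-weighted during the dark phase (mice are nocturnal) and rest-type labels
during the light phase.  Group differences are *planted* as multiplicative
propensity shifts on chosen labels in a chosen phase, giving tests an exact
ground truth to recover.  Dwell times are exponential for simplicity; no
claim of behavioral realism is made beyond gross circadian structure.
"""

from __future__ import annotations

import datetime as dt
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import RAW_LABELS, DISTANCE_SOURCE
from .ingest import BehaviorSequence, events_to_minutes, synchronize
from .metadata import (
    ExperimentRow,
    LabRecord,
    MasterRecord,
    ProjectBundle,
    write_master,
)

#: behavior states the generator can emit (distance is not a behavior)
STATE_LABELS = tuple(l for l in RAW_LABELS if l != DISTANCE_SOURCE)

__all__ = [
    "SimConfig",
    "STRONG_NIGHT_WALK_EFFECT",
    "simulate_sequence",
    "simulate_tables",
    "simulate_project",
    "corrupt",
]

# (propensity, mean dwell seconds, is_activity) per raw label.  Propensity x
# dwell sets the stationary time share; activity labels are boosted at NIGHT
# and rest labels at DAY by the circadian factor.
_BASELINE: dict[str, tuple[float, float, bool]] = {
    "Sleep":    (1.00, 240.0, False),
    "Stationa": (0.50,  60.0, False),
    "Pause":    (0.60,  20.0, False),
    "Twitch":   (0.40,   5.0, False),
    "Awaken":   (0.20,  10.0, False),
    "Groom":    (0.50,  40.0, True),
    "WalkLeft": (0.50,   6.0, True),
    "WalkRght": (0.50,   6.0, True),
    "WalkSlow": (0.30,   8.0, True),
    "Turn":     (0.30,   4.0, True),
    "Circle":   (0.10,   5.0, True),
    "RearUp":   (0.60,   8.0, True),
    "ComeDown": (0.50,   4.0, True),
    "CDfromPR": (0.10,   3.0, True),
    "CDtoPR":   (0.10,   3.0, True),
    "RUfromPR": (0.10,   4.0, True),
    "RUtoPR":   (0.10,   4.0, True),
    "RemainRU": (0.20,   6.0, True),
    "RemainPR": (0.10,   6.0, True),
    "RemainLw": (0.30,  10.0, False),
    "RemainHV": (0.08,   5.0, True),
    "RemainHC": (0.08,   5.0, True),
    "HangCudl": (0.10,   6.0, True),
    "HangVert": (0.20,   5.0, True),
    "HVfromRU": (0.10,   3.0, True),
    "HVfromHC": (0.05,   3.0, True),
    "LandVert": (0.20,   2.0, True),
    "Stretch":  (0.20,   5.0, True),
    "Drnk.S1.": (0.20,  15.0, True),
    "Drnk.S2.": (0.05,  12.0, True),
    "Drnk.S3.": (0.05,  12.0, True),
    "Eat.Z1.":  (0.40,  30.0, True),
    "Eat.Z2.":  (0.10,  25.0, True),
    "Eat.Z3.":  (0.05,  25.0, True),
    "Jump":     (0.05,   2.0, True),
    "ReptJump": (0.02,   3.0, True),
    "Unknown":  (0.10,   5.0, False),
    "Urinate":  (0.05,   8.0, False),
    "Dig":      (0.20,  20.0, True),
    "Forage":   (0.30,  20.0, True),
    "Chew":     (0.20,  15.0, True),
    "Sniff":    (0.60,   8.0, True),
    "Arousal":  (0.05,   5.0, False),
    "No.Data":  (0.05,  10.0, False),
}

#: a strong planted effect: treated animals walk twice as much at night
STRONG_NIGHT_WALK_EFFECT = (
    ("WalkLeft", "NIGHT", 2.5),
    ("WalkRght", "NIGHT", 2.5),
    ("WalkSlow", "NIGHT", 2.5),
    ("RearUp", "NIGHT", 2.0),
    ("Sleep", "NIGHT", 0.5),
)


@dataclass
class SimConfig:
    """Study conditions for one simulated project.

    Defaults mirror a typical single-animal home-cage session: 11 animals
    per group recorded once for 1380 min (~23 h), placed in the cage 2 h
    before a 19:00 lights-off with a 12-h dark phase.
    """

    n_per_group: int = 11
    groups: tuple[str, ...] = ("control", "treated")
    group_by: str = "Treatment"
    recording_minutes: int = 1380
    recording_start: dt.datetime = dt.datetime(2026, 3, 2, 17, 0)
    light_off: dt.time = dt.time(19, 0)
    light_on: dt.time = dt.time(7, 0)
    night_activity_factor: float = 3.0
    animal_sigma: float = 0.15  # lognormal sd of per-animal propensity scaling
    effects: tuple[tuple[str, str, float], ...] = ()  # (label, phase, multiplier)
    distance_per_walk_second: float = 0.25
    distance_noise_sd: float = 0.5
    proj_name: str = "sim_project"
    data_kind: str = "minute_summary"
    seed: int = 0

    def lab_record(self) -> LabRecord:
        return LabRecord(lab_id="sim_lab", light_off_time=self.light_off,
                         light_on_time=self.light_on, timezone="local")

    def stationary_shares(self, phase: str, group_index: int = 0,
                          ) -> pd.Series:
        """Expected time share per label in one phase (generator ground truth)."""
        prop, dwell = self._phase_rates(phase, group_index)
        share = prop * dwell
        return pd.Series(share / share.sum(), index=list(STATE_LABELS))

    def _phase_rates(self, phase: str, group_index: int,
                     ) -> tuple[np.ndarray, np.ndarray]:
        prop = np.array([_BASELINE[lab][0] for lab in STATE_LABELS])
        dwell = np.array([_BASELINE[lab][1] for lab in STATE_LABELS])
        active = np.array([_BASELINE[lab][2] for lab in STATE_LABELS])
        if phase == "NIGHT":
            prop = np.where(active, prop * self.night_activity_factor, prop)
        else:
            prop = np.where(~active, prop * self.night_activity_factor, prop)
        if group_index > 0:
            for label, eff_phase, mult in self.effects:
                if eff_phase == phase:
                    if mult <= 0:
                        raise ValueError("effect multipliers must be positive")
                    prop[STATE_LABELS.index(label)] *= mult
        return prop, dwell


def _phase_segments(cfg: SimConfig) -> list[tuple[float, float, str]]:
    """(start_s, end_s, phase) segments of the recording."""
    lab = cfg.lab_record()
    anchor = dt.datetime.combine(cfg.recording_start.date(), cfg.light_off)
    if anchor < cfg.recording_start:
        anchor += dt.timedelta(days=1)
    t_off = (anchor - cfg.recording_start).total_seconds()
    t_on = t_off + lab.night_length_minutes * 60.0
    end = cfg.recording_minutes * 60.0
    if end > t_off + 24 * 3600:
        raise ValueError("recording spans more than one lights-off event")
    cuts = [(0.0, min(t_off, end), "DAY"),
            (min(t_off, end), min(t_on, end), "NIGHT"),
            (min(t_on, end), end, "DAY")]
    return [(a, b, ph) for a, b, ph in cuts if b > a]


def simulate_sequence(cfg: SimConfig, animal_id: str, test_id: str,
                      group_index: int, rng: np.random.Generator,
                      ) -> BehaviorSequence:
    """Generate one animal's behavior sequence for the whole recording."""
    animal_scale = rng.lognormal(0.0, cfg.animal_sigma, size=len(STATE_LABELS)) \
        if cfg.animal_sigma > 0 else np.ones(len(STATE_LABELS))
    starts_all, ends_all, labels_all = [], [], []
    for seg_start, seg_end, phase in _phase_segments(cfg):
        prop, dwell = cfg._phase_rates(phase, group_index)
        prop = prop * animal_scale
        p = prop / prop.sum()
        mean_dwell = float((p * dwell).sum())
        t = seg_start
        while t < seg_end - 1e-9:
            # draw label/dwell pairs in batches until the segment is filled
            n_draw = max(16, int((seg_end - t) / mean_dwell * 1.3) + 8)
            labs = rng.choice(len(STATE_LABELS), size=n_draw, p=p)
            durs = rng.exponential(dwell[labs])
            bounds = t + np.cumsum(durs)
            keep = int(np.searchsorted(bounds, seg_end)) + 1
            filled = keep <= len(bounds)
            labs, bounds = labs[:keep], bounds[:keep]
            bounds[-1] = min(bounds[-1], seg_end)
            starts = np.concatenate([[t], bounds[:-1]])
            ok = bounds > starts
            starts_all.append(starts[ok])
            ends_all.append(bounds[ok])
            labels_all.append(labs[ok])
            t = seg_end if filled else float(bounds[-1])
    starts = np.concatenate(starts_all)
    ends = np.concatenate(ends_all)
    labels = np.concatenate(labels_all)
    # merge consecutive identical labels (also across phase boundaries)
    new_run = np.concatenate([[True], labels[1:] != labels[:-1]])
    run_id = np.cumsum(new_run) - 1
    run_starts = starts[new_run]
    run_ends = np.zeros(run_id[-1] + 1)
    np.maximum.at(run_ends, run_id, ends)
    events = pd.DataFrame({
        "start_s": np.round(run_starts, 3),
        "end_s": np.round(run_ends, 3),
        "label": np.array(STATE_LABELS, dtype=object)[labels[new_run]],
    })
    # rounding must not create zero-length or overlapping events
    events = events[events["end_s"] > events["start_s"]].reset_index(drop=True)
    return BehaviorSequence(animal_id=animal_id, test_id=test_id,
                            events=events,
                            recording_start=cfg.recording_start).validate()


_WALK_SOURCES = ("WalkLeft", "WalkRght", "WalkSlow", "Turn", "Circle")


def _minutes_with_distance(seq: BehaviorSequence, cfg: SimConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    minutes = events_to_minutes(seq)
    walk = minutes[list(_WALK_SOURCES)].sum(axis=1).to_numpy()
    noise = rng.normal(0.0, cfg.distance_noise_sd, size=len(minutes))
    dist = np.clip(cfg.distance_per_walk_second * walk + noise, 0.0, None)
    minutes[DISTANCE_SOURCE] = np.round(dist, 3)
    return minutes


def _experiment_rows(cfg: SimConfig) -> list[tuple[str, str, int]]:
    rows = []
    i = 0
    for g_idx, _group in enumerate(cfg.groups):
        for _ in range(cfg.n_per_group):
            i += 1
            rows.append((f"A{i:02d}", "T1", g_idx))
    return rows


def simulate_tables(cfg: SimConfig) -> tuple[list[pd.DataFrame], list[ExperimentRow], LabRecord]:
    """In-memory pipeline input: synchronized minute tables for all animals.

    Equivalent to simulating a project on disk and ingesting it, without
    the file round-trip; statistical tests use this for speed.
    """
    rng = np.random.default_rng(cfg.seed)
    lab = cfg.lab_record()
    tables, rows = [], []
    for animal_id, test_id, g_idx in _experiment_rows(cfg):
        seq = simulate_sequence(cfg, animal_id, test_id, g_idx, rng)
        minutes = _minutes_with_distance(seq, cfg, rng)
        row = ExperimentRow(
            animal_id=animal_id, test_id=test_id, group=cfg.groups[g_idx],
            recording_start=cfg.recording_start,
            data_file=f"{animal_id}_{test_id}_minutes.csv",
            data_kind="minute_summary",
        )
        tables.append(synchronize(minutes, row, lab))
        rows.append(row)
    return tables, rows, lab


def simulate_project(cfg: SimConfig, out_dir: str | Path) -> Path:
    """Write a complete synthetic project; returns the master file path.

    Layout: ``<out_dir>/master_metadata.csv`` plus
    ``<out_dir>/<proj_name>/{metadata,rawdata}`` with one event TSV and one
    minute-summary CSV per animal.  The minute summaries equal the
    minute-binned event files plus a simulated distance column.  Identical
    configurations (same seed) produce byte-identical trees.
    """
    out = Path(out_dir)
    proj = out / cfg.proj_name
    (proj / "metadata").mkdir(parents=True, exist_ok=True)
    (proj / "rawdata").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(cfg.seed)
    exp_records = []
    for k, (animal_id, test_id, g_idx) in enumerate(_experiment_rows(cfg)):
        seq = simulate_sequence(cfg, animal_id, test_id, g_idx, rng)
        minutes = _minutes_with_distance(seq, cfg, rng)
        events_name = f"{animal_id}_{test_id}_events.tsv"
        minutes_name = f"{animal_id}_{test_id}_minutes.csv"
        seq.events.to_csv(proj / "rawdata" / events_name, sep="\t", index=False)
        minutes.drop(columns=["minute_index"]).to_csv(
            proj / "rawdata" / minutes_name, index=False
        )
        exp_records.append({
            "animal_id": animal_id,
            "test_id": test_id,
            cfg.group_by: cfg.groups[g_idx],
            "birth_date": (cfg.recording_start.date()
                           - dt.timedelta(days=120 + 2 * k)).isoformat(),
            "recording_start": cfg.recording_start.isoformat(sep=" "),
            "data_file": (events_name if cfg.data_kind == "events"
                          else minutes_name),
            "data_kind": cfg.data_kind,
            "exclude": "",
            "events_file": events_name,
        })
    pd.DataFrame(exp_records).to_csv(
        proj / "metadata" / "experiment_metadata.csv", index=False
    )
    pd.DataFrame([{
        "lab_id": "sim_lab",
        "light_off_time": cfg.light_off.strftime("%H:%M"),
        "light_on_time": cfg.light_on.strftime("%H:%M"),
        "timezone": "local",
    }]).to_csv(proj / "metadata" / "lab_metadata.csv", index=False)

    master = MasterRecord(
        identifier=f"SIM{cfg.seed:04d}",
        proj_name=cfg.proj_name,
        title="synthetic home-cage recording for pipeline testing",
        creator="bseqlab synthetic generator",
        subject_area="Behavioral neurobiology",
        resource="Dataset",
        rights="CC0",
        video_acquisition="synthetic",
        video_analysis="synthetic",
        group_by=cfg.group_by,
        source_data="local",
        folder_path=cfg.proj_name,
        raw_data_folder="rawdata",
        animal_metadata="metadata/experiment_metadata.csv",
        lab_metadata="metadata/lab_metadata.csv",
    )
    master_file = out / "master_metadata.csv"
    write_master([master], master_file)
    return master_file


_CORRUPT_MODES = ("shift_minutes", "scale_category", "truncate")


def corrupt(master_file: str | Path, project_id: str, out_dir: str | Path,
            mode: str, seed: int = 0, *, shift: int = 10,
            category: str = "Eat", factor: float = 0.5,
            minutes_cut: int = 120) -> dict:
    """Copy a project and plant a defect in one animal's minute summary.

    Only the summary CSV is touched, never the event file, so a
    raw-vs-export consistency check must flag the corrupted animal.
    Returns the ground-truth defect description.  ``mode``:

    * ``shift_minutes`` -- behavior rows rotated by ``shift`` minutes;
    * ``scale_category`` -- every raw column of ``category`` (Eat or Drink
      zones, or one raw label) multiplied by ``factor``;
    * ``truncate`` -- last ``minutes_cut`` rows removed.
    """
    if mode not in _CORRUPT_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}")
    src_master = Path(master_file)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    new_master = out / src_master.name
    shutil.copy(src_master, new_master)
    from .metadata import load_project

    src_bundle = load_project(src_master, project_id)
    dst_proj = out / src_bundle.master.folder_path
    if dst_proj.exists():
        shutil.rmtree(dst_proj)
    shutil.copytree(src_bundle.project_dir, dst_proj)

    bundle = load_project(new_master, project_id)
    rng = np.random.default_rng(seed)
    victims = [r for r in bundle.experiments if r.data_kind == "minute_summary"]
    row = victims[int(rng.integers(len(victims)))]
    path = bundle.data_path(row)
    table = pd.read_csv(path)
    label_cols = [c for c in table.columns if c in set(RAW_LABELS)]
    if mode == "shift_minutes":
        table[label_cols] = np.roll(table[label_cols].to_numpy(), shift, axis=0)
        detail = {"shift": shift}
    elif mode == "scale_category":
        cols = [c for c in label_cols if c == category or
                c.startswith(f"{'Drnk' if category == 'Drink' else category}")]
        table[cols] = table[cols] * factor
        detail = {"category": category, "factor": factor, "columns": cols}
    else:
        table = table.iloc[:-minutes_cut]
        detail = {"minutes_cut": minutes_cut}
    table.to_csv(path, index=False)
    return {"mode": mode, "animal_id": row.animal_id, "test_id": row.test_id,
            "file": str(path), **detail}
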