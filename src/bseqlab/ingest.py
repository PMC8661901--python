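"""Reading behavior data and building the synchronized minute table.

The canonical raw input is a TSV of labeled intervals (``start_s``,
``end_s``, ``label``), one file per ~23-h single-animal recording.  Hourly
or per-minute summary exports (CSV, one column per raw label, seconds per
bin) are accepted as fallbacks.  Whatever the source, ingestion produces a
*synchronized minute table*: one row per minute with the seconds spent in
each raw behavior, the signed time to the light-off event (``bintodark``)
and the light phase (DAY/NIGHT).  Anchoring every recording to its own
lights-off makes animals recorded on different days comparable, which is
what the circadian analysis downstream relies on.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import DISTANCE_SOURCE, RAW_LABELS
from .errors import (
    ConsistencyRangeError,
    EmptyInputError,
    MetadataParseError,
    OverlappingEventsError,
    ScheduleError,
    UnknownLabelError,
)
from .metadata import ExperimentRow, LabRecord, ProjectBundle

__all__ = [
    "BehaviorSequence",
    "read_events",
    "events_to_minutes",
    "read_minute_summary",
    "read_hour_summary",
    "synchronize",
    "load_minutes",
    "ConsistencyReport",
    "check_consistency",
]

_RAW_SET = frozenset(RAW_LABELS)


@dataclass
class BehaviorSequence:
    """Ordered, non-overlapping labeled intervals for one recording."""

    animal_id: str
    test_id: str
    events: pd.DataFrame  # columns start_s, end_s, label
    recording_start: dt.datetime | None = None

    def validate(self) -> "BehaviorSequence":
        ev = self.events
        if ev.empty:
            raise EmptyInputError("behavior sequence has no events")
        bad = set(ev["label"]) - _RAW_SET
        if bad:
            raise UnknownLabelError(f"unknown behavior label(s): {sorted(bad)}")
        if not (ev["end_s"].to_numpy() > ev["start_s"].to_numpy()).all():
            raise OverlappingEventsError("every event must have end_s > start_s")
        starts = ev["start_s"].to_numpy()
        ends = ev["end_s"].to_numpy()
        if (starts[1:] < ends[:-1] - 1e-9).any():
            raise OverlappingEventsError("events overlap in time")
        return self

    def total_seconds_per_label(self) -> pd.Series:
        dur = self.events["end_s"] - self.events["start_s"]
        return dur.groupby(self.events["label"]).sum()


def read_events(file: str | Path, animal_id: str = "", test_id: str = "",
                recording_start: dt.datetime | None = None) -> BehaviorSequence:
    """Read an event TSV (columns ``start_s``, ``end_s``, ``label``).

    Rows out of chronological order are sorted with a warning; overlapping
    intervals and labels outside the 45-label vocabulary are rejected.
    """
    path = Path(file)
    table = pd.read_csv(path, sep="\t")
    if table.empty:
        raise EmptyInputError(f"event file {path} has no rows")
    missing = {"start_s", "end_s", "label"} - set(table.columns)
    if missing:
        raise MetadataParseError(f"event file {path} lacks columns {sorted(missing)}")
    if not table["start_s"].is_monotonic_increasing:
        warnings.warn(f"events out of order in {path}; sorting by start_s")
        table = table.sort_values("start_s", kind="stable").reset_index(drop=True)
    seq = BehaviorSequence(
        animal_id=animal_id or path.stem,
        test_id=test_id,
        events=table[["start_s", "end_s", "label"]].reset_index(drop=True),
        recording_start=recording_start,
    )
    return seq.validate()


def events_to_minutes(seq: BehaviorSequence) -> pd.DataFrame:
    """Apportion event durations to the minutes they span.

    Returns one row per complete minute with a column for each of the 45 raw
    labels holding the seconds spent in that behavior during the minute.
    The trailing incomplete minute is dropped so every row has a uniform
    60-s denominator.
    """
    seq.validate()
    ev = seq.events
    n_minutes = int(ev["end_s"].max() // 60)
    out = np.zeros((n_minutes, len(RAW_LABELS)))
    if n_minutes == 0:
        return pd.DataFrame(out, columns=list(RAW_LABELS))
    label_idx = {lab: i for i, lab in enumerate(RAW_LABELS)}
    labels = ev["label"].map(label_idx).to_numpy()
    cur = ev["start_s"].to_numpy(dtype=float).copy()
    ends = np.minimum(ev["end_s"].to_numpy(dtype=float), n_minutes * 60.0)
    # split each event at minute boundaries; loop count = max minutes spanned
    while True:
        alive = cur < ends - 1e-12
        if not alive.any():
            break
        minute = np.floor(cur[alive] / 60.0).astype(int)
        piece_end = np.minimum(ends[alive], (minute + 1) * 60.0)
        np.add.at(out, (minute, labels[alive]), piece_end - cur[alive])
        nxt = cur.copy()
        nxt[alive] = piece_end
        cur = nxt
    frame = pd.DataFrame(out, columns=list(RAW_LABELS))
    frame.insert(0, "minute_index", np.arange(n_minutes))
    return frame


def _check_summary_values(table: pd.DataFrame, path: Path, cap: float) -> pd.DataFrame:
    labels = [c for c in table.columns if c in _RAW_SET]
    if not labels:
        raise EmptyInputError(f"summary file {path} has no raw-label columns")
    values = table[labels].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise MetadataParseError(f"summary file {path} contains non-numeric cells")
    if (values < 0).any().any():
        raise MetadataParseError(f"summary file {path} contains negative values")
    behavior = [c for c in labels if c != DISTANCE_SOURCE]
    over = values[behavior] > cap
    if over.any().any():
        if (values[behavior] > cap + 1.0).any().any():
            raise MetadataParseError(
                f"summary file {path} has behavior values far above {cap} s/bin"
            )
        warnings.warn(
            f"summary file {path}: values slightly above {cap} s clamped"
        )
        values[behavior] = values[behavior].clip(upper=cap)
    table = table.copy()
    table[labels] = values
    return table


def read_minute_summary(file: str | Path) -> pd.DataFrame:
    """Read a per-minute summary CSV (seconds per raw label per minute)."""
    path = Path(file)
    table = pd.read_csv(path)
    if table.empty:
        raise EmptyInputError(f"minute summary {path} has no rows")
    table = _check_summary_values(table, path, cap=60.0)
    labels = [c for c in table.columns if c in _RAW_SET]
    out = table[labels].reset_index(drop=True)
    out.insert(0, "minute_index", np.arange(len(out)))
    return out


def read_hour_summary(file: str | Path) -> pd.DataFrame:
    """Expand an hourly summary CSV to minutes (hour value / 60 per minute)."""
    path = Path(file)
    table = pd.read_csv(path)
    if table.empty:
        raise EmptyInputError(f"hour summary {path} has no rows")
    table = _check_summary_values(table, path, cap=3600.0)
    labels = [c for c in table.columns if c in _RAW_SET]
    hours = table[labels].to_numpy(dtype=float)
    minutes = np.repeat(hours / 60.0, 60, axis=0)
    out = pd.DataFrame(minutes, columns=labels)
    out.insert(0, "minute_index", np.arange(len(out)))
    return out


def _first_light_off(start: dt.datetime, lab: LabRecord) -> dt.datetime:
    candidate = dt.datetime.combine(start.date(), lab.light_off_time)
    if candidate < start:
        candidate += dt.timedelta(days=1)
    return candidate


def synchronize(minute_table: pd.DataFrame, row: ExperimentRow,
                lab: LabRecord) -> pd.DataFrame:
    """Attach light-cycle context to a per-minute table.

    The anchor is the first lights-off at or after ``recording_start``;
    ``bintodark`` is the signed offset in minutes of each minute's start from
    that anchor (negative before lights-off, 0 at lights-off).  ``phase`` is
    NIGHT exactly when ``bintodark`` modulo 24 h falls within the night
    length of the lab schedule.  Behavior columns are never altered.
    """
    if row.recording_start is None:
        raise MetadataParseError("recording_start missing; cannot synchronize")
    night_len = lab.night_length_minutes
    if night_len <= 0:
        raise ScheduleError("light schedule is degenerate (no night phase)")
    anchor = _first_light_off(row.recording_start, lab)
    offset_min = (row.recording_start - anchor).total_seconds() / 60.0
    out = minute_table.copy()
    bintodark = out["minute_index"].to_numpy(dtype=float) + offset_min
    out.insert(1, "bintodark", bintodark)
    is_night = np.mod(bintodark, 24 * 60) < night_len
    out.insert(2, "phase", np.where(is_night, "NIGHT", "DAY"))
    out.insert(0, "animal_id", row.animal_id)
    out.insert(1, "test_id", row.test_id)
    out.insert(2, "group", row.group)
    return out


def load_minutes(bundle: ProjectBundle, row: ExperimentRow) -> pd.DataFrame:
    """Read one test's data file (per its ``data_kind``) and synchronize it."""
    path = bundle.data_path(row)
    if row.data_kind == "events":
        seq = read_events(path, animal_id=row.animal_id, test_id=row.test_id,
                          recording_start=row.recording_start)
        minutes = events_to_minutes(seq)
    elif row.data_kind == "minute_summary":
        minutes = read_minute_summary(path)
    else:
        minutes = read_hour_summary(path)
    return synchronize(minutes, row, bundle.lab)


@dataclass
class ConsistencyReport:
    """Minutes on which two derivations of the same recording disagree."""

    animal_id: str
    test_id: str
    tol_s: float
    flagged: pd.DataFrame  # columns minute_index, label, value_a, value_b
    n_compared: int

    @property
    def consistent(self) -> bool:
        return self.flagged.empty


def check_consistency(from_events: pd.DataFrame, from_summary: pd.DataFrame,
                      tol_s: float = 1.0) -> ConsistencyReport:
    """Compare two minute tables of the same recording category by category.

    Lists every (minute, label) where the two derivations differ by more
    than ``tol_s`` seconds; the verdict is *consistent* iff nothing is
    flagged.  This is how corrupted vendor exports are caught: the summary
    a closed export function wrote is replayed against the raw sequence.
    """
    def ids(tab: pd.DataFrame) -> tuple[str, str]:
        return (
            str(tab["animal_id"].iloc[0]) if "animal_id" in tab else "",
            str(tab["test_id"].iloc[0]) if "test_id" in tab else "",
        )

    labels = [c for c in from_events.columns
              if c in _RAW_SET and c in from_summary.columns
              and c != DISTANCE_SOURCE]
    a = from_events.set_index("minute_index")[labels]
    b = from_summary.set_index("minute_index")[labels]
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ConsistencyRangeError("minute tables share no minute range")
    diff = (a.loc[shared, labels] - b.loc[shared, labels]).abs()
    bad = diff.stack()
    bad = bad[bad > tol_s]
    records = [
        {"minute_index": int(m), "label": lab,
         "value_a": float(a.at[m, lab]), "value_b": float(b.at[m, lab])}
        for (m, lab) in bad.index
    ]
    animal, test = ids(from_events)
    return ConsistencyReport(
        animal_id=animal, test_id=test, tol_s=tol_s,
        flagged=pd.DataFrame(records, columns=["minute_index", "label",
                                               "value_a", "value_b"]),
        n_compared=len(shared),
    )
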