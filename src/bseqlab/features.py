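"""Light-cycle-anchored time windows and the multivariate feature matrix.

A recording of roughly 23 h spanning one lights-off event is cut into nine
windows anchored to the light cycle: six primary windows (first 2 h of
recording, last 2 h of day, first 3 h of night, last 3 h of night, first
3 h of the second day, and 2 h-before-dark to end) plus three overlapping
windows (whole day phase before dark, whole night phase, whole recording).
For each animal, window and pooled behavior category, the feature is the
square root of the proportion of window time spent in the category -- a
variance-stabilizing transform that, unlike a log, tolerates zeros.  With
the 18-category Berlin scheme and all nine windows this yields 162
variables per animal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .categories import DISTANCE_LABEL, CategoryScheme, derive_base38, pool
from .errors import (
    AllRowsExcludedError,
    EmptyInputError,
    ScheduleError,
    WindowCoverageError,
)
from .metadata import ExperimentRow, LabRecord, is_excluded

__all__ = [
    "TimeWindow",
    "FeatureMatrix",
    "WINDOW_IDS",
    "define_windows",
    "available_windows",
    "build_features",
    "apply_exclusions",
]

WINDOW_IDS = tuple(f"W{i}" for i in range(1, 10))

_COVER_TOL = 1e-6


@dataclass(frozen=True)
class TimeWindow:
    """Half-open interval [start, end) in minutes relative to lights-off."""

    id: str
    start: float
    end: float
    description: str = ""

    @property
    def length_minutes(self) -> float:
        return self.end - self.start


def define_windows(lab: LabRecord, recording_span: tuple[float, float],
                   overlap_trio: dict[str, tuple[float, float]] | None = None,
                   ) -> list[TimeWindow]:
    """Resolve the nine standard windows against a concrete recording.

    ``recording_span`` is (first, last+1) minute of the recording in
    lights-off-relative minutes; it must bracket the lights-off instant.
    The composition of the overlapping trio W7-W9 defaults to day phase /
    night phase / whole recording but can be overridden.
    """
    start, end = recording_span
    if not (start <= 0 < end):
        raise ScheduleError(
            f"recording span [{start}, {end}) does not contain a lights-off event"
        )
    night = lab.night_length_minutes
    spec: list[tuple[str, float, float, str]] = [
        ("W1", start, start + 120, "first 2 h of recording"),
        ("W2", -120, 0, "last 2 h before nightfall"),
        ("W3", 0, 180, "first 3 h of the night"),
        ("W4", night - 180, night, "last 3 h of the night"),
        ("W5", night, night + 180, "first 3 h of the second day"),
        ("W6", -120, end, "2 h before lights-off to end of recording"),
        ("W7", start, 0, "whole day phase before lights-off"),
        ("W8", 0, night, "whole night phase"),
        ("W9", start, end, "entire recording"),
    ]
    if overlap_trio:
        spec = [
            (wid, *overlap_trio[wid], f"custom {wid}") if wid in overlap_trio
            else (wid, s, e, d)
            for (wid, s, e, d) in spec
        ]
    windows = [TimeWindow(wid, s, e, d) for wid, s, e, d in spec]
    bad = [w.id for w in windows if w.end <= w.start]
    if bad:
        raise ScheduleError(f"degenerate window(s) after resolution: {bad}")
    return windows


def _covers(table: pd.DataFrame, window: TimeWindow) -> bool:
    btd = table["bintodark"].to_numpy(dtype=float)
    inside = (btd >= window.start - _COVER_TOL) & (btd < window.end - _COVER_TOL)
    n_needed = int(round(window.length_minutes))
    if inside.sum() < n_needed:
        return False
    sel = np.sort(btd[inside])
    return bool(
        sel[0] <= window.start + _COVER_TOL
        and sel[-1] + 1 >= window.end - _COVER_TOL
    )


def available_windows(tables: list[pd.DataFrame],
                      windows: list[TimeWindow]) -> list[TimeWindow]:
    """Keep only windows that every animal's minutes fully cover.

    Restricting the analysis to fully shared windows keeps every sample at
    equal valence; a truncated recording silently removing data from one
    group would otherwise bias group comparisons.
    """
    if not tables:
        raise EmptyInputError("no minute tables supplied")
    return [w for w in windows if all(_covers(t, w) for t in tables)]


@dataclass
class FeatureMatrix:
    """Animals x (category x window) sqrt-proportion features with groups."""

    data: pd.DataFrame            # numeric feature columns "<category>__<Wk>"
    groups: pd.Series             # aligned with data.index
    animal_ids: pd.Series
    test_ids: pd.Series
    confound: pd.Series | None = None
    scheme_name: str = ""
    window_ids: tuple[str, ...] = ()

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame({
            "animal_id": self.animal_ids,
            "test_id": self.test_ids,
            "group": self.groups,
        }, index=self.data.index)
        if self.confound is not None:
            head["confound"] = self.confound
        return pd.concat([head, self.data], axis=1)

    def select_rows(self, keep: np.ndarray | list[bool]) -> "FeatureMatrix":
        mask = np.asarray(keep, dtype=bool)
        return replace(
            self,
            data=self.data.loc[mask],
            groups=self.groups.loc[mask],
            animal_ids=self.animal_ids.loc[mask],
            test_ids=self.test_ids.loc[mask],
            confound=None if self.confound is None else self.confound.loc[mask],
        )


def build_features(tables: list[pd.DataFrame], windows: list[TimeWindow],
                   scheme: CategoryScheme,
                   drop_distance: bool = False) -> FeatureMatrix:
    """Compute sqrt-proportion features per animal, window and category.

    The denominator is the total behavior time actually recorded inside the
    window (not its nominal length), so a dropped partial minute cannot
    distort proportions; per (row, window) the squared behavior features
    therefore sum to exactly 1.  The distance channel, when the source
    provides one and ``drop_distance`` is false, becomes one extra feature
    per window on the same denominator (its scale is arbitrary, a reason to
    consider dropping it).
    """
    if not tables:
        raise EmptyInputError("no minute tables supplied")
    behaviors = list(scheme.behavior_labels())
    records: list[dict[str, float]] = []
    meta: list[tuple[str, str, str, str]] = []
    with_distance = None
    for table in tables:
        pooled = pool(derive_base38(table), scheme)
        has_dist = DISTANCE_LABEL in pooled.columns and not drop_distance
        if with_distance is None:
            with_distance = has_dist
        elif with_distance != has_dist:
            raise WindowCoverageError(
                "distance channel present for some animals only; "
                "use drop_distance=True"
            )
        btd = pooled["bintodark"].to_numpy(dtype=float)
        values = pooled[behaviors].to_numpy(dtype=float)
        dist_values = (pooled[DISTANCE_LABEL].to_numpy(dtype=float)
                       if has_dist else None)
        rec: dict[str, float] = {}
        for win in windows:
            inside = (btd >= win.start - _COVER_TOL) & (btd < win.end - _COVER_TOL)
            if not inside.any():
                raise WindowCoverageError(
                    f"window {win.id} has no data for animal "
                    f"{pooled['animal_id'].iloc[0]}"
                )
            seconds = values[inside].sum(axis=0)
            total = float(seconds.sum())
            if total <= 0:
                raise WindowCoverageError(
                    f"window {win.id} has zero behavior time"
                )
            feats = np.sqrt(seconds / total)
            for cat, val in zip(behaviors, feats):
                rec[f"{cat}__{win.id}"] = float(val)
            if dist_values is not None:
                dist = float(dist_values[inside].sum())
                rec[f"{DISTANCE_LABEL}__{win.id}"] = float(np.sqrt(dist / total))
        records.append(rec)
        meta.append((
            str(pooled["animal_id"].iloc[0]), str(pooled["test_id"].iloc[0]),
            str(pooled["group"].iloc[0]),
            str(pooled["confound"].iloc[0]) if "confound" in pooled else "",
        ))
    index = [f"{a}|{t}" for a, t, _, _ in meta]
    data = pd.DataFrame(records, index=index)
    # column order: windows-major, categories within window
    cats = behaviors + ([DISTANCE_LABEL] if with_distance else [])
    ordered = [f"{c}__{w.id}" for w in windows for c in cats]
    data = data[ordered]
    return FeatureMatrix(
        data=data,
        groups=pd.Series([g for _, _, g, _ in meta], index=index, name="group"),
        animal_ids=pd.Series([a for a, _, _, _ in meta], index=index, name="animal_id"),
        test_ids=pd.Series([t for _, t, _, _ in meta], index=index, name="test_id"),
        confound=pd.Series([c for _, _, _, c in meta], index=index, name="confound"),
        scheme_name=scheme.name,
        window_ids=tuple(w.id for w in windows),
    )


def apply_exclusions(matrix: FeatureMatrix,
                     rows: list[ExperimentRow]) -> FeatureMatrix:
    """Drop matrix rows flagged for exclusion in the experiment metadata."""
    flagged = {
        (r.animal_id, r.test_id) for r in rows if is_excluded(r)
    }
    keep = [
        (a, t) not in flagged
        for a, t in zip(matrix.animal_ids, matrix.test_ids)
    ]
    if not any(keep):
        raise AllRowsExcludedError("every row is excluded by the metadata")
    return matrix.select_rows(keep)
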