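"""Behavior-label vocabulary and category pooling.

Home-cage video classifiers emit one of 45 raw behavior labels per frame.
For analysis those labels are first reduced to 38 base behaviors (the
horizontal distance channel is not a behavior; the ``No.Data`` and
``Arousal`` markers are discarded; three drink zones and three eat zones are
pooled into one ``Drink`` and one ``Eat``), and then optionally pooled
further by one of two published schemes:

* **Berlin** (18 categories, counting ``Distance_traveled``): merges
  behaviors that occur too rarely to analyse on their own.
* **Jhuang** (10 categories, counting ``Distance_traveled``): the coarser
  set that an open-source video classifier can detect, useful when
  comparing across acquisition software.

The full mapping ships as a CSV data file (``data/categories.csv``) rather
than as code, so users can audit it or supply their own scheme file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UnmappedColumnError

__all__ = [
    "RAW_LABELS",
    "BASE38_LABELS",
    "DISTANCE_LABEL",
    "DISTANCE_SOURCE",
    "DISCARDED_LABELS",
    "CategoryScheme",
    "scheme_table",
    "get_scheme",
    "derive_base38",
    "pool",
]

DISTANCE_SOURCE = "Travel.m."
DISTANCE_LABEL = "Distance_traveled"
DISCARDED_LABELS = ("No.Data", "Arousal")

#: raw drink/eat zone labels pooled into two base behaviors
_DRINK_SOURCES = ("Drnk.S1.", "Drnk.S2.", "Drnk.S3.")
_EAT_SOURCES = ("Eat.Z1.", "Eat.Z2.", "Eat.Z3.")

# columns in a minute table that are not behavior categories
ID_COLUMNS = (
    "animal_id",
    "test_id",
    "group",
    "confound",
    "minute_index",
    "bintodark",
    "phase",
)


def _default_scheme_path() -> Path:
    return Path(resources.files("bseqlab").joinpath("data/categories.csv"))  # type: ignore[arg-type]


def scheme_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the raw-label / Berlin / Jhuang mapping table.

    Blank scheme cells mean the raw label is discarded by that scheme.
    """
    table = pd.read_csv(path or _default_scheme_path(), dtype=str, keep_default_na=False)
    expected = {"raw_label", "berlin_label", "jhuang_label"}
    if not expected.issubset(table.columns):
        raise ValueError(f"scheme file must have columns {sorted(expected)}")
    return table


_TABLE = scheme_table()

RAW_LABELS: tuple[str, ...] = tuple(_TABLE["raw_label"])

#: the 38 base behavior labels (distance held separately, markers discarded,
#: drink/eat zones pooled)
BASE38_LABELS: tuple[str, ...] = tuple(
    dict.fromkeys(
        ("Drink" if lab in _DRINK_SOURCES else "Eat" if lab in _EAT_SOURCES else lab)
        for lab in RAW_LABELS
        if lab != DISTANCE_SOURCE and lab not in DISCARDED_LABELS
    )
)


@dataclass(frozen=True)
class CategoryScheme:
    """A total mapping from raw (or base-38) labels to pooled categories.

    ``mapping`` sends every raw label to a pooled label or to ``None``
    (discard).  ``pooled_labels`` is the ordered pooled category set;
    for Berlin and Jhuang it includes ``Distance_traveled``.
    """

    name: str
    mapping: dict[str, str | None] = field(repr=False)
    pooled_labels: tuple[str, ...] = ()

    def behavior_labels(self) -> tuple[str, ...]:
        """Pooled categories excluding the distance channel."""
        return tuple(c for c in self.pooled_labels if c != DISTANCE_LABEL)


def _build_scheme(name: str, column: str, table: pd.DataFrame) -> CategoryScheme:
    mapping: dict[str, str | None] = {}
    for raw, pooled in zip(table["raw_label"], table[column]):
        mapping[raw] = pooled if pooled else None
    # base-38 labels map like their raw sources (all drink/eat zones agree)
    mapping["Drink"] = mapping["Drnk.S1."]
    mapping["Eat"] = mapping["Eat.Z1."]
    pooled_order = tuple(dict.fromkeys(v for v in mapping.values() if v))
    return CategoryScheme(name=name, mapping=mapping, pooled_labels=pooled_order)


def get_scheme(name: str, path: str | Path | None = None) -> CategoryScheme:
    """Return a pooling scheme by name: ``berlin``, ``jhuang`` or ``raw38``."""
    key = name.lower()
    table = scheme_table(path) if path else _TABLE
    if key == "berlin":
        return _build_scheme("berlin", "berlin_label", table)
    if key == "jhuang":
        return _build_scheme("jhuang", "jhuang_label", table)
    if key == "raw38":
        mapping: dict[str, str | None] = {lab: lab for lab in BASE38_LABELS}
        for lab in _DRINK_SOURCES:
            mapping[lab] = "Drink"
        for lab in _EAT_SOURCES:
            mapping[lab] = "Eat"
        for lab in DISCARDED_LABELS:
            mapping[lab] = None
        mapping[DISTANCE_SOURCE] = DISTANCE_LABEL
        return CategoryScheme(name="raw38", mapping=mapping, pooled_labels=BASE38_LABELS)
    raise ValueError(f"unknown scheme {name!r}; expected berlin, jhuang or raw38")


def _split_columns(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    id_cols = [c for c in table.columns if c in ID_COLUMNS]
    label_cols = [c for c in table.columns if c not in ID_COLUMNS]
    return id_cols, label_cols


def _aggregate(minute_table: pd.DataFrame, id_cols: list[str],
               label_cols: list[str],
               groups: dict[str, list[str]]) -> pd.DataFrame:
    """Sum source columns into target columns in one vectorized pass."""
    values = minute_table[label_cols].to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(label_cols)}
    out = np.empty((len(minute_table), len(groups)))
    for j, (_, sources) in enumerate(groups.items()):
        idx = [col_idx[c] for c in sources]
        out[:, j] = values[:, idx].sum(axis=1) if idx else 0.0
    pooled = pd.DataFrame(out, columns=list(groups), index=minute_table.index)
    return pd.concat([minute_table[id_cols], pooled], axis=1)


def derive_base38(minute_table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a 45-raw-label minute table to the 38 base behaviors.

    Drink and eat zones are summed, the ``No.Data`` and ``Arousal`` markers
    are dropped, and ``Travel.m.`` (when present) is carried over as the
    separate ``Distance_traveled`` column.
    """
    id_cols, label_cols = _split_columns(minute_table)
    present = set(label_cols)
    groups: dict[str, list[str]] = {}
    for lab in BASE38_LABELS:
        if lab == "Drink":
            groups[lab] = [c for c in _DRINK_SOURCES if c in present]
        elif lab == "Eat":
            groups[lab] = [c for c in _EAT_SOURCES if c in present]
        else:
            groups[lab] = [lab] if lab in present else []
    if DISTANCE_SOURCE in present:
        groups[DISTANCE_LABEL] = [DISTANCE_SOURCE]
    elif DISTANCE_LABEL in present:
        groups[DISTANCE_LABEL] = [DISTANCE_LABEL]
    return _aggregate(minute_table, id_cols, label_cols, groups)


def pool(minute_table: pd.DataFrame, scheme: CategoryScheme) -> pd.DataFrame:
    """Pool behavior columns of a (45-raw or 38-base) minute table.

    Each pooled column is the sum of its mapped source columns; per-minute
    time is conserved up to the discarded labels.  The distance channel, when
    present, is passed through unchanged under its pooled name.
    """
    id_cols, label_cols = _split_columns(minute_table)
    unmapped = [
        c for c in label_cols
        if c not in scheme.mapping and c != DISTANCE_LABEL
    ]
    if unmapped:
        raise UnmappedColumnError(
            f"columns not covered by scheme {scheme.name!r}: {unmapped}"
        )
    groups = {
        pooled: [c for c in label_cols if scheme.mapping.get(c) == pooled]
        for pooled in scheme.behavior_labels()
    }
    dist_src = [
        c for c in label_cols
        if c == DISTANCE_LABEL or scheme.mapping.get(c) == DISTANCE_LABEL
    ]
    if dist_src:
        groups[DISTANCE_LABEL] = dist_src
    return _aggregate(minute_table, id_cols, label_cols, groups)
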