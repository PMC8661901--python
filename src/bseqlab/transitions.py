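"""Behavior-transition context around a focal behavior.

Raw event sequences allow questions that binned summaries cannot answer,
e.g. *what does a mouse do just before and just after landing from a
vertical hang?*  For every occurrence of a focal behavior the immediately
preceding and following *distinct* behaviors are tallied (consecutive
identical labels are first merged into runs, since frame-wise classifiers
emit repeated labels), each occurrence weighted equally regardless of
duration.  Per-animal percentage distributions are then summarized across
animals by their mean and median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import UnknownLabelError
from .categories import RAW_LABELS
from .ingest import BehaviorSequence

__all__ = ["TransitionContext", "transition_context", "merge_runs"]


def merge_runs(labels: list[str]) -> list[str]:
    """Collapse consecutive identical labels into single runs."""
    out: list[str] = []
    for lab in labels:
        if not out or out[-1] != lab:
            out.append(lab)
    return out


@dataclass
class TransitionContext:
    """Neighbor-label distributions around a focal behavior."""

    focal: str
    per_animal: pd.DataFrame  # columns: animal_id, side, label, count, percent
    summary: pd.DataFrame     # columns: side, label, mean_percent, median_percent
    n_occurrences: int
    top_k: int

    @property
    def empty(self) -> bool:
        return self.n_occurrences == 0


def _tally(seqs: list[BehaviorSequence], focal: str) -> pd.DataFrame:
    records = []
    for seq in seqs:
        runs = merge_runs(list(seq.events["label"]))
        for i, lab in enumerate(runs):
            if lab != focal:
                continue
            if i > 0:
                records.append((seq.animal_id, "before", runs[i - 1]))
            if i < len(runs) - 1:
                records.append((seq.animal_id, "after", runs[i + 1]))
    return pd.DataFrame(records, columns=["animal_id", "side", "label"])


def transition_context(seqs: list[BehaviorSequence], focal: str,
                       top_k: int = 8) -> TransitionContext:
    """Count which behaviors immediately precede/follow each focal event.

    A focal run at the very start (end) of a sequence contributes no
    before-side (after-side) observation.  The summary reports, for each
    side, the ``top_k`` labels by median per-animal percentage, with the
    mean alongside.
    """
    if focal not in RAW_LABELS:
        raise UnknownLabelError(f"focal label {focal!r} not in the vocabulary")
    tally = _tally(seqs, focal)
    if tally.empty:
        warnings.warn(f"focal behavior {focal!r} never occurs; empty context")
        empty_pa = pd.DataFrame(
            columns=["animal_id", "side", "label", "count", "percent"]
        )
        empty_sum = pd.DataFrame(
            columns=["side", "label", "mean_percent", "median_percent"]
        )
        return TransitionContext(focal=focal, per_animal=empty_pa,
                                 summary=empty_sum, n_occurrences=0,
                                 top_k=top_k)

    counts = (tally.groupby(["animal_id", "side", "label"])
              .size().rename("count").reset_index())
    totals = (counts.groupby(["animal_id", "side"])["count"]
              .transform("sum"))
    counts["percent"] = counts["count"] / totals * 100.0

    # per (animal, side) the percentage of an absent label is 0, which must
    # enter the across-animal mean/median
    animals = counts["animal_id"].unique()
    rows = []
    for side in ("before", "after"):
        side_counts = counts[counts["side"] == side]
        present_animals = side_counts["animal_id"].unique()
        for label in side_counts["label"].unique():
            percents = []
            for animal in animals:
                if animal not in present_animals:
                    continue
                sub = side_counts[(side_counts["animal_id"] == animal)
                                  & (side_counts["label"] == label)]
                percents.append(float(sub["percent"].iloc[0]) if len(sub) else 0.0)
            series = pd.Series(percents)
            rows.append({"side": side, "label": label,
                         "mean_percent": float(series.mean()),
                         "median_percent": float(series.median())})
    summary = pd.DataFrame(rows)
    summary = (summary.sort_values(["side", "median_percent", "label"],
                                   ascending=[True, False, True])
               .groupby("side", group_keys=False).head(top_k)
               .reset_index(drop=True))
    n_occ = sum(
        sum(1 for lab in merge_runs(list(s.events["label"])) if lab == focal)
        for s in seqs
    )
    return TransitionContext(focal=focal, per_animal=counts, summary=summary,
                             n_occurrences=n_occ, top_k=top_k)
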