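"""Multivariate visualization and the confirmatory group test.

With up to 162 correlated variables and ~10 animals per group, testing each
variable separately invites p-hacking.  The strategy here is split in two:

* an **explorative** branch -- a double random-forest pass picks the 8-20
  variables most useful for telling the groups apart (first forest keeps
  the top 20 by Gini importance, a second forest re-ranks those and keeps
  everything within 95% of the best, or the top 8 if that is larger), and
  an independent component analysis embeds the animals in 3-D for visual
  inspection.  This branch *always* finds structure and is never used for
  inference;
* a **confirmatory** branch -- a single PCA on all features, with one
  nonparametric test on the first principal component.  One test, decided
  before looking at the data, is the guard against hypothesizing after the
  results are known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA, FastICA
from sklearn.ensemble import RandomForestClassifier

from .errors import GroupCountError
from .features import FeatureMatrix

__all__ = [
    "SelectionResult",
    "GroupTestResult",
    "rf_select",
    "ica_embed",
    "pca_group_test",
]

FIRST_PASS_KEEP = 20
MIN_SELECTED = 8
IMPORTANCE_THRESHOLD = 0.95  # fraction of the maximum pass-2 importance
N_TREES = 500


@dataclass
class SelectionResult:
    """Outcome of the double random-forest variable selection."""

    first_pass: pd.Series   # importance of every variable, pass 1
    second_pass: pd.Series  # importance of the top-20 subset, pass 2
    selected: list[str]
    seed: int

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _ranked(importances: np.ndarray, names: list[str]) -> pd.Series:
    series = pd.Series(importances, index=names)
    # ties broken deterministically by variable name
    order = sorted(series.index, key=lambda c: (-series[c], c))
    return series.loc[order]


def _check_groups(groups: pd.Series, lo: int = 2, hi: int = 3) -> list[str]:
    levels = sorted(groups.unique())
    if not (lo <= len(levels) <= hi):
        raise GroupCountError(
            f"found {len(levels)} groups; supported range is {lo}-{hi}"
        )
    counts = groups.value_counts()
    if (counts < 2).any():
        raise GroupCountError("every group needs at least 2 animals")
    return levels


def rf_select(matrix: FeatureMatrix, seed: int = 0,
              n_trees: int = N_TREES) -> SelectionResult:
    """Double random-forest selection of 8-20 discriminative variables.

    Pass 1 fits a classification forest on all variables and keeps the top
    20 by mean decrease in Gini impurity.  Pass 2 refits on those 20 and
    keeps every variable whose importance exceeds 95% of the pass-2
    maximum -- or the top 8, whichever set is larger.  Deterministic for a
    given seed; importance ties are broken by variable name.
    """
    _check_groups(matrix.groups)
    X = matrix.data.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise GroupCountError("need at least 2 variables to select from")
    y = matrix.groups.to_numpy()
    names = list(matrix.data.columns)

    forest1 = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest1.fit(X, y)
    first = _ranked(forest1.feature_importances_, names)
    top20 = list(first.index[:FIRST_PASS_KEEP])

    forest2 = RandomForestClassifier(n_estimators=n_trees, random_state=seed + 1)
    forest2.fit(matrix.data[top20].to_numpy(dtype=float), y)
    second = _ranked(forest2.feature_importances_, top20)

    maximum = float(second.iloc[0]) if second.iloc[0] > 0 else 1.0
    above = [name for name in second.index
             if second[name] / maximum > IMPORTANCE_THRESHOLD]
    floor = list(second.index[:min(MIN_SELECTED, len(second))])
    selected = above if len(above) > len(floor) else floor
    return SelectionResult(first_pass=first, second_pass=second,
                           selected=selected, seed=seed)


def ica_embed(matrix: FeatureMatrix, selected: list[str],
              seed: int = 0) -> pd.DataFrame:
    """Embed animals into 3 independent components of the selected variables.

    Falls back (with a warning) to the available rank when the centered
    selected data has rank below 3.  The returned frame has one row per
    animal and columns IC1..IC3 plus the group label, ready for 3-D
    plotting.
    """
    import warnings

    X = matrix.data[selected].to_numpy(dtype=float)
    centered = X - X.mean(axis=0)
    rank = int(np.linalg.matrix_rank(centered, tol=1e-10))
    n_comp = 3
    if rank < 3:
        warnings.warn(f"data rank {rank} < 3; embedding in {rank} component(s)")
        if rank == 0:  # constant data: no sources to unmix
            out = pd.DataFrame(np.zeros((len(X), 1)),
                               index=matrix.data.index, columns=["IC1"])
            out["group"] = matrix.groups
            out.attrs["mixing"] = np.zeros((X.shape[1], 1))
            out.attrs["mean"] = X.mean(axis=0)
            return out
        n_comp = rank
    ica = FastICA(n_components=n_comp, random_state=seed, whiten="unit-variance",
                  max_iter=2000)
    sources = ica.fit_transform(X)
    out = pd.DataFrame(
        sources, index=matrix.data.index,
        columns=[f"IC{i + 1}" for i in range(n_comp)],
    )
    out["group"] = matrix.groups
    out.attrs["mixing"] = ica.mixing_
    out.attrs["mean"] = ica.mean_
    return out


@dataclass
class GroupTestResult:
    """PCA-first-component nonparametric group comparison."""

    pc1_scores: pd.Series
    explained_variance_ratio: np.ndarray
    statistic: float          # Z for 2 groups, H for 3 groups
    p_value: float
    effect_size_r: float | None  # |Z|/sqrt(n), 2-group case only
    test_name: str
    groups: list[str]


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney Z with tie-corrected normal approximation."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float((u1 - mu) / np.sqrt(var))


def pca_group_test(matrix: FeatureMatrix) -> GroupTestResult:
    """PCA on column-centered features, then one rank test on PC1.

    Two groups: two-sided rank-sum (normal approximation with tie
    correction) yielding Z, p and the effect size r = |Z|/sqrt(n).  Three
    groups: Kruskal-Wallis.  More than three groups are rejected.
    """
    levels = _check_groups(matrix.groups)
    X = matrix.data.to_numpy(dtype=float)
    # columns centered, not rescaled: features already share one scale
    n_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    pc1 = pd.Series(scores[:, 0], index=matrix.data.index, name="PC1")
    if np.ptp(pc1.to_numpy()) < 1e-12:  # constant scores: numerical dust only
        pc1[:] = 0.0

    by_group = [pc1[matrix.groups == g].to_numpy() for g in levels]
    if len(levels) == 2:
        z = _ranksum_z(by_group[0], by_group[1])
        p = float(2.0 * sps.norm.sf(abs(z))) if z != 0 else 1.0
        r = abs(z) / np.sqrt(len(pc1))
        return GroupTestResult(
            pc1_scores=pc1,
            explained_variance_ratio=pca.explained_variance_ratio_,
            statistic=z, p_value=min(p, 1.0), effect_size_r=float(r),
            test_name="rank-sum (normal approximation, tie-corrected)",
            groups=levels,
        )
    if all(np.ptp(g) == 0 for g in by_group) and np.ptp(pc1.to_numpy()) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*by_group)
    return GroupTestResult(
        pc1_scores=pc1,
        explained_variance_ratio=pca.explained_variance_ratio_,
        statistic=float(h), p_value=float(p), effect_size_r=None,
        test_name="Kruskal-Wallis", groups=levels,
    )
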