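"""SVM group prediction with permutation-based inference.

A support-vector machine (radial or linear kernel) is trained to predict
group membership and validated either by a repeated *two-out* scheme (one
randomly chosen animal per group held out per repeat; the small-sample
path) or by a single stratified holdout split.  Chance-corrected agreement
(Cohen's kappa) summarizes the pooled predictions.  Significance comes from
a permutation null: the whole validation is repeated many times after
randomizing group membership, the observed accuracy's exceedance count is
turned into a point p-value, and a 95% Clopper-Pearson binomial interval
on the exceedance proportion gives an honest *range* for the p-value given
the finite number of permutations (which is always reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score
from sklearn.svm import SVC

from .errors import GroupCountError, GroupSizeError
from .features import FeatureMatrix

__all__ = [
    "MLResult",
    "choose_scheme",
    "svm_validate",
    "permutation_pvalue",
    "pairwise_groups",
]

TWO_OUT_MAX_GROUP = 15  # per-group size at or below which two-out is used
DEFAULT_REPEATS = 100
HOLDOUT_FRACTION = 1 / 3


@dataclass
class MLResult:
    """Pooled predictions and (optionally) the permutation null."""

    kernel: str
    scheme: str
    truth: np.ndarray
    predictions: np.ndarray
    accuracy: float
    kappa: float
    seed: int
    repeats: int
    permutation_accuracies: list[float] = field(default_factory=list)
    n_permutations: int = 0
    n_exceeding: int = 0
    p_value: float | None = None
    p_range: tuple[float, float] | None = None


def choose_scheme(n_per_group: int) -> str:
    """Pick the validation scheme from the per-group sample size.

    Two-out for 15 or fewer animals per group, a stratified holdout above
    that.  Fewer than 3 per group cannot support either.
    """
    if n_per_group < 3:
        raise GroupSizeError(
            f"{n_per_group} animals per group is too few to validate"
        )
    return "two_out" if n_per_group <= TWO_OUT_MAX_GROUP else "holdout"


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    std[std == 0] = 1.0
    return (train - mean) / std, (test - mean) / std


def _fit_predict(train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray,
                 kernel: str) -> np.ndarray:
    if len(np.unique(train_y)) < 2:
        # a permuted fold may end up single-class; predict that class
        return np.repeat(train_y[0], len(test_x))
    svm = SVC(kernel={"radial": "rbf", "linear": "linear"}[kernel], C=1.0,
              gamma="scale")
    train_s, test_s = _standardize(train_x, test_x)
    svm.fit(train_s, train_y)
    return svm.predict(test_s)


def _pooled_scores(truth: np.ndarray, pred: np.ndarray,
                   labels: list) -> tuple[float, float]:
    accuracy = float((truth == pred).mean())
    if len(np.unique(truth)) < 2 and len(np.unique(pred)) < 2:
        kappa = 1.0 if accuracy == 1.0 else 0.0
    else:
        kappa = float(cohen_kappa_score(truth, pred, labels=labels))
        if np.isnan(kappa):
            kappa = 0.0
    return accuracy, kappa


def _run_two_out(X: np.ndarray, y: np.ndarray, idx_a: np.ndarray,
                 idx_b: np.ndarray, kernel: str, repeats: int,
                 rng: np.random.Generator,
                 permute_train: bool) -> tuple[np.ndarray, np.ndarray]:
    pairs = list(product(idx_a, idx_b))
    n_pairs = min(repeats, len(pairs))
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=n_pairs, replace=False)]
    truth, pred = [], []
    all_idx = np.arange(len(y))
    for ia, ib in chosen:
        test_idx = np.array([ia, ib])
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_y = y[train_idx]
        if permute_train:
            train_y = rng.permutation(train_y)
        p = _fit_predict(X[train_idx], train_y, X[test_idx], kernel)
        truth.extend(y[test_idx])
        pred.extend(p)
    return np.asarray(truth), np.asarray(pred)


def _run_holdout(X: np.ndarray, y: np.ndarray, idx_a: np.ndarray,
                 idx_b: np.ndarray, kernel: str, rng: np.random.Generator,
                 permute_train: bool) -> tuple[np.ndarray, np.ndarray]:
    test_idx = []
    for idx in (idx_a, idx_b):
        n_test = max(1, int(round(len(idx) * HOLDOUT_FRACTION)))
        test_idx.extend(rng.choice(idx, size=n_test, replace=False))
    test_idx = np.asarray(sorted(test_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    train_y = y[train_idx]
    if permute_train:
        train_y = rng.permutation(train_y)
    pred = _fit_predict(X[train_idx], train_y, X[test_idx], kernel)
    return y[test_idx], pred


def _validate_once(X: np.ndarray, y: np.ndarray, labels: list, scheme: str,
                   kernel: str, repeats: int, rng: np.random.Generator,
                   permute_train: bool = False) -> tuple[float, float, np.ndarray, np.ndarray]:
    idx_a = np.flatnonzero(y == labels[0])
    idx_b = np.flatnonzero(y == labels[1])
    if scheme == "two_out":
        truth, pred = _run_two_out(X, y, idx_a, idx_b, kernel, repeats, rng,
                                   permute_train)
    elif scheme == "holdout":
        truth, pred = _run_holdout(X, y, idx_a, idx_b, kernel, rng,
                                   permute_train)
    else:
        raise ValueError(f"unknown validation scheme {scheme!r}")
    accuracy, kappa = _pooled_scores(truth, pred, labels)
    return accuracy, kappa, truth, pred


def _binary(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, list]:
    labels = sorted(matrix.groups.unique())
    if len(labels) != 2:
        raise GroupCountError(
            f"SVM validation needs exactly 2 groups, got {len(labels)}; "
            "split multi-group data with pairwise_groups first"
        )
    counts = matrix.groups.value_counts()
    if (counts < 3).any():
        raise GroupSizeError("every group needs at least 3 animals")
    return (matrix.data.to_numpy(dtype=float), matrix.groups.to_numpy(),
            labels)


def svm_validate(matrix: FeatureMatrix, kernel: str = "radial",
                 scheme: str | None = None, seed: int = 0,
                 repeats: int = DEFAULT_REPEATS) -> MLResult:
    """Train and validate an SVM group classifier; no permutation fields.

    Features are standardized on the training fold only, so no information
    leaks from held-out animals.  ``repeats`` only applies to the two-out
    scheme and is capped at the number of distinct cross-group pairs.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X, y, labels = _binary(matrix)
    if scheme is None:
        scheme = choose_scheme(int(matrix.groups.value_counts().min()))
    rng = np.random.default_rng(seed)
    accuracy, kappa, truth, pred = _validate_once(
        X, y, labels, scheme, kernel, repeats, rng
    )
    return MLResult(kernel=kernel, scheme=scheme, truth=truth,
                    predictions=pred, accuracy=accuracy, kappa=kappa,
                    seed=seed, repeats=repeats)


def permutation_pvalue(matrix: FeatureMatrix, kernel: str = "radial",
                       scheme: str | None = None, n_perm: int = 100,
                       seed: int = 0, repeats: int = DEFAULT_REPEATS,
                       permute: str = "all") -> MLResult:
    """Full SVM validation plus a permutation null and a p-value range.

    The observed accuracy is computed once; each permutation then reruns
    the entire validation with shuffled labels.  The default
    (``permute='all'``) randomizes group membership before the validation,
    so each permuted run has the same animal-level label structure as the
    observed one and the null is calibrated; ``'train'`` instead shuffles
    the training-fold labels inside every split.  With exceedance count
    k = #{permuted accuracy >= observed}, the point p-value is
    (k+1)/(n_perm+1) and the range is the 95% Clopper-Pearson interval for
    k/n_perm.
    """
    import warnings

    if n_perm < 10:
        warnings.warn(f"n_perm={n_perm} is very low; the p-range will be wide")
    if permute not in ("train", "all"):
        raise ValueError("permute must be 'train' or 'all'")
    result = svm_validate(matrix, kernel=kernel, scheme=scheme, seed=seed,
                          repeats=repeats)
    X, y, labels = _binary(matrix)
    rng = np.random.default_rng(seed + 1)
    perm_acc: list[float] = []
    for _ in range(n_perm):
        if permute == "all":
            y_perm = rng.permutation(y)
            acc, _, _, _ = _validate_once(X, y_perm, labels, result.scheme,
                                          kernel, repeats, rng)
        else:
            acc, _, _, _ = _validate_once(X, y, labels, result.scheme, kernel,
                                          repeats, rng, permute_train=True)
        perm_acc.append(acc)
    k = int(sum(a >= result.accuracy for a in perm_acc))
    ci = sps.binomtest(k, n_perm).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    result.permutation_accuracies = perm_acc
    result.n_permutations = n_perm
    result.n_exceeding = k
    result.p_value = (k + 1) / (n_perm + 1)
    result.p_range = (float(ci.low), float(ci.high))
    return result


def pairwise_groups(matrix: FeatureMatrix) -> list[FeatureMatrix]:
    """Split a 2- or 3-group matrix into all unordered group pairs."""
    levels = sorted(matrix.groups.unique())
    if not (2 <= len(levels) <= 3):
        raise GroupCountError(
            f"found {len(levels)} groups; supported range is 2-3"
        )
    out = []
    for a, b in combinations(levels, 2):
        keep = matrix.groups.isin([a, b]).to_numpy()
        out.append(matrix.select_rows(keep))
    return out
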