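"""tkNN: an iterative ensemble kNN with majority voting and a greedy final choice.

The classifier sweeps a fixed 30-point parameter grid (k = 1..5, distance in
{cityblock, chebyshev, euclidean}, weighting in {inverse, equal}), producing
one out-of-fold prediction vector per configuration under either 10-fold
stratified CV or leave-one-subject-out (LOSO) CV.  Iterative majority voting
(IMV) then sorts the 30 outcome vectors by accuracy and adds, for every
q = 3..30, the per-sample mode of the top-q outcomes (28 voted vectors).
The final outcome is the accuracy-argmax over all 58 candidates, so the
ensemble can never do worse than its best single configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "PARAM_GRID",
    "OutcomePool",
    "VotedPool",
    "FinalResult",
    "make_cv",
    "parameter_outcomes",
    "iterative_majority_vote",
    "select_final",
    "confusion_metrics",
    "tknn_classify",
]

K_VALUES = (1, 2, 3, 4, 5)
DISTANCES = ("cityblock", "chebyshev", "euclidean")
WEIGHTS = ("inverse", "equal")

#: grid order fixes candidate indexing and hence argmax tie-breaking
PARAM_GRID: tuple[tuple[int, str, str], ...] = tuple(
    (k, d, w) for k, d, w in product(K_VALUES, DISTANCES, WEIGHTS)
)

_SK_METRIC = {"cityblock": "manhattan", "chebyshev": "chebyshev", "euclidean": "euclidean"}
_SK_WEIGHT = {"inverse": "distance", "equal": "uniform"}


@dataclass
class OutcomePool:
    """30 parameter-based out-of-fold prediction vectors and their accuracies."""

    predictions: np.ndarray            # (30, n_samples), label dtype
    accuracies: np.ndarray             # (30,)
    grid: tuple = PARAM_GRID


@dataclass
class VotedPool:
    """28 iterative-majority-vote prediction vectors (q = 3..30)."""

    voted: np.ndarray                  # (28, n_samples)
    accuracies: np.ndarray             # (28,)
    order: np.ndarray                  # dx: outcome indices sorted by descending accuracy


@dataclass
class FinalResult:
    chosen: np.ndarray                 # final out-of-fold prediction vector
    chosen_index: int                  # 0-based index into the 58 candidates
    chosen_source: str                 # human-readable candidate description
    candidate_accuracies: np.ndarray   # (58,)
    metrics: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(self.candidate_accuracies[self.chosen_index])


def make_cv(
    y: np.ndarray,
    scheme: str = "kfold10",
    *,
    seed: int = 0,
    groups: np.ndarray | None = None,
    n_splits: int = 10,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialize CV folds: stratified k-fold (shuffled, seeded) or LOSO by subject."""
    y = np.asarray(y)
    X_dummy = np.zeros((y.shape[0], 1))
    if scheme == "kfold10":
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in cv.split(X_dummy, y)]
    if scheme == "loso":
        if groups is None:
            raise ValueError("LOSO CV needs subject_id groups")
        cv = LeaveOneGroupOut()
        return [(tr, te) for tr, te in cv.split(X_dummy, y, groups=np.asarray(groups))]
    raise ValueError(f"unknown CV scheme {scheme!r}; use 'kfold10' or 'loso'")


def parameter_outcomes(
    X: np.ndarray,
    y: np.ndarray,
    cv: list[tuple[np.ndarray, np.ndarray]],
) -> OutcomePool:
    """Out-of-fold predictions for all 30 kNN parameter configurations.

    k is truncated (with a warning) on folds whose training set is smaller
    than k.  Inverse-distance weighting handles zero distances the sklearn
    way: an exact-match neighbor takes all the weight, i.e. its label wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.shape[0]
    covered = np.zeros(n, dtype=int)
    for _, te in cv:
        covered[te] += 1
    if not np.all(covered == 1):
        raise ValueError("CV folds must give every sample exactly one test prediction")

    preds = np.empty((len(PARAM_GRID), n), dtype=y.dtype)
    accs = np.empty(len(PARAM_GRID))
    for s, (k, dist, wname) in enumerate(PARAM_GRID):
        out = np.empty(n, dtype=y.dtype)
        for tr, te in cv:
            kk = min(k, tr.size)
            if kk < k:
                warnings.warn(
                    f"k={k} exceeds training fold size {tr.size}; using k={kk}",
                    stacklevel=2,
                )
            clf = KNeighborsClassifier(
                n_neighbors=kk, metric=_SK_METRIC[dist], weights=_SK_WEIGHT[wname]
            )
            clf.fit(X[tr], y[tr])
            out[te] = clf.predict(X[te])
        preds[s] = out
        accs[s] = accuracy_score(y, out)
    return OutcomePool(predictions=preds, accuracies=accs)


def iterative_majority_vote(pool: OutcomePool, y: np.ndarray) -> VotedPool:
    """Per-sample mode of the top-q accuracy-sorted outcomes, q = 3..30.

    Mode ties are broken by the label predicted by the most accurate
    participating outcome.
    """
    y = np.asarray(y)
    n = y.shape[0]
    dx = np.argsort(-pool.accuracies, kind="stable")
    labels, coded = np.unique(pool.predictions, return_inverse=True)
    coded = coded.reshape(pool.predictions.shape)[dx]  # (30, n), accuracy-sorted
    n_out = pool.predictions.shape[0]
    q_values = range(3, n_out + 1)

    counts = np.zeros((n, labels.size), dtype=int)
    rows = np.arange(n)
    voted = np.empty((n_out - 2, n), dtype=pool.predictions.dtype)
    accs = np.empty(n_out - 2)
    for r in range(2):  # seed counts with the top-2 outcomes
        counts[rows, coded[r]] += 1
    for qi, q in enumerate(q_values):
        counts[rows, coded[q - 1]] += 1
        maxc = counts.max(axis=1)
        choice = np.full(n, -1, dtype=int)
        remaining = np.ones(n, dtype=bool)
        for r in range(q):  # first (most accurate) outcome voting for a tied label wins
            lab = coded[r]
            pick = remaining & (counts[rows, lab] == maxc)
            choice[pick] = lab[pick]
            remaining &= ~pick
        voted[qi] = labels[choice]
        accs[qi] = accuracy_score(y, voted[qi])
    return VotedPool(voted=voted, accuracies=accs, order=dx)


def select_final(pool: OutcomePool, voted: VotedPool, y: np.ndarray) -> FinalResult:
    """Greedy argmax over the 58 candidates (30 parameter-based + 28 voted)."""
    y = np.asarray(y)
    all_preds = np.vstack([pool.predictions, voted.voted])
    all_accs = np.concatenate([pool.accuracies, voted.accuracies])
    indice = int(np.argmax(all_accs))  # first maximum: lowest candidate index wins ties
    if indice < len(pool.predictions):
        k, dist, w = pool.grid[indice]
        source = f"parameter(k={k}, distance={dist}, weight={w})"
    else:
        source = f"voted(q={indice - len(pool.predictions) + 3})"
    chosen = all_preds[indice]
    return FinalResult(
        chosen=chosen,
        chosen_index=indice,
        chosen_source=source,
        candidate_accuracies=all_accs,
        metrics=confusion_metrics(y, chosen),
    )


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Accuracy, per-class recall/F1, macro F1 and geometric mean from the confusion matrix.

    The geometric mean is the per-class recall product to the power
    1/n_classes (for binary problems, sqrt(recall_1 * recall_2)).  A class
    absent from ``y_true`` yields NaN recall with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    support = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recalls = np.where(support > 0, np.diag(cm) / np.maximum(support, 1), np.nan)
    if np.isnan(recalls).any():
        absent = [str(labels[i]) for i in np.flatnonzero(np.isnan(recalls))]
        warnings.warn(f"class(es) {absent} absent from y_true; recall is NaN", stacklevel=2)
        gmean = float("nan")
    else:
        gmean = float(np.prod(recalls) ** (1.0 / recalls.size))
    f1_per_class = f1_score(y_true, y_pred, labels=labels, average=None, zero_division=0)
    return {
        "labels": [str(l) for l in labels],
        "confusion_matrix": cm.tolist(),
        "accuracy": float(np.trace(cm) / cm.sum()),
        "recall_per_class": [float(r) for r in recalls],
        "geometric_mean": gmean,
        "f1_per_class": [float(f) for f in f1_per_class],
        "f1_macro": float(f1_score(y_true, y_pred, labels=labels, average="macro",
                                   zero_division=0)),
    }


def tknn_classify(
    X: np.ndarray,
    y: np.ndarray,
    *,
    scheme: str = "kfold10",
    seed: int = 0,
    groups: np.ndarray | None = None,
    n_splits: int = 10,
) -> tuple[FinalResult, OutcomePool, VotedPool]:
    """Convenience wrapper: folds -> 30 outcomes -> 28 votes -> final choice."""
    cv = make_cv(y, scheme, seed=seed, groups=groups, n_splits=n_splits)
    pool = parameter_outcomes(X, y, cv)
    voted = iterative_majority_vote(pool, y)
    return select_final(pool, voted, y), pool, voted
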