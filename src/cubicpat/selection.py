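"""CWINCA: cumulative-weighted iterative NCA feature selection.

Three stages:

1. :func:`nca_weights` learns one nonnegative relevance weight per feature
   with a diagonal neighborhood component analysis: stochastic nearest
   neighbors under the weighted L1 distance ``d_w(i, j) = sum_r w_r**2
   |x_ir - x_jr|``, softmax neighbor probabilities ``p_ij ∝ exp(-d_ij)``,
   and the regularized leave-one-out objective

       F(w) = sum_i sum_{j in class(i)} p_ij  -  lambda * sum_r w_r**2,

   maximized with L-BFGS from ``w = 1``.  The quadratic penalty (default
   ``lambda = 1/n_samples``) shrinks irrelevant weights toward zero and also
   auto-scales the kernel: on raw count features the exponential kernel
   starts saturated, and the penalty first contracts all weights until the
   softmax becomes sensitive, after which the data term differentiates the
   features.
2. :func:`cumulative_weight_range` turns the descending-sorted, normalized
   weights into a search range [sv, fv]: the smallest prefix sizes whose
   cumulative weight reaches 0.75 and 0.99.
3. :func:`iterative_select` greedily evaluates every prefix size in the
   range with a cross-validated classifier (default: 1-NN, 10-fold
   stratified CV) and keeps the smallest prefix achieving the maximum
   accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "FeatureWeights",
    "SelectionRange",
    "SelectionResult",
    "nca_weights",
    "cumulative_weight_range",
    "kfold_knn_evaluator",
    "iterative_select",
    "select_features",
]


@dataclass
class FeatureWeights:
    """Per-feature NCA relevance weights and their descending ranking."""

    w: np.ndarray        # nonnegative, one per feature
    idx: np.ndarray      # 0-based feature indices, descending weight, stable ties

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.idx = np.asarray(self.idx, dtype=np.int64)
        if self.w.ndim != 1 or self.idx.shape != self.w.shape:
            raise ValueError("w and idx must be 1-D and the same length")


@dataclass
class SelectionRange:
    """Prefix-size search range [sv, fv] (inclusive, 1-based counts)."""

    sv: int
    fv: int

    def __post_init__(self) -> None:
        if not 1 <= self.sv <= self.fv:
            raise ValueError(f"invalid selection range sv={self.sv}, fv={self.fv}")


@dataclass
class SelectionResult:
    sv: int
    fv: int
    accuracy_trace: np.ndarray
    best_count: int
    best_accuracy: float
    selected_indices: np.ndarray  # 0-based original feature indices, ranked
    ranking: np.ndarray = field(default=None, repr=False)  # full descending ranking

    def to_dict(self) -> dict:
        return {
            "sv": int(self.sv),
            "fv": int(self.fv),
            "best_count": int(self.best_count),
            "best_accuracy": float(self.best_accuracy),
            "selected_indices": [int(i) for i in self.selected_indices],
            "accuracy_trace": [float(a) for a in self.accuracy_trace],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            sv=d["sv"],
            fv=d["fv"],
            accuracy_trace=np.asarray(d["accuracy_trace"], dtype=float),
            best_count=d["best_count"],
            best_accuracy=d["best_accuracy"],
            selected_indices=np.asarray(d["selected_indices"], dtype=np.int64),
        )


def _nca_value_grad(
    u: np.ndarray,
    X: np.ndarray,
    same: np.ndarray,
    lam: float,
    chunk: int,
) -> tuple[float, np.ndarray]:
    """Negative objective and gradient of diagonal NCA at weight vector u."""
    n_samples, n_feat = X.shape
    w2 = u * u
    total = 0.0
    data_grad = np.zeros(n_feat)
    for start in range(0, n_samples, chunk):
        stop = min(start + chunk, n_samples)
        block = slice(start, stop)
        # D: (c, N, d) absolute feature differences for this chunk of anchors
        D = np.abs(X[block][:, None, :] - X[None, :, :])
        dist = D @ w2  # (c, N)
        rows = np.arange(start, stop)
        dist[rows - start, rows] = np.inf  # exclude self
        # stable softmax over neighbors
        shift = dist.min(axis=1, keepdims=True)
        shift[~np.isfinite(shift)] = 0.0
        p = np.exp(-(dist - shift))
        p[rows - start, rows] = 0.0
        denom = p.sum(axis=1, keepdims=True)
        denom[denom == 0.0] = 1.0
        p /= denom
        m = same[block]
        p_i = (p * m).sum(axis=1)  # probability of a same-class neighbor
        total += p_i.sum()
        # dF/dw2_r = sum_i [ p_i * sum_k p_ik D_ikr - sum_{j in class} p_ij D_ijr ]
        data_grad += np.einsum("cn,cnd->d", p * p_i[:, None], D)
        data_grad -= np.einsum("cn,cnd->d", p * m, D)
    value = total - lam * float(w2.sum())
    grad = 2.0 * u * data_grad - 2.0 * lam * u
    return -value, -grad


def nca_weights(
    X: np.ndarray,
    y: np.ndarray,
    *,
    standardize: bool = False,
    regularization: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    chunk_elements: int = 20_000_000,
) -> FeatureWeights:
    """Learn per-feature NCA relevance weights.

    Parameters
    ----------
    standardize
        Z-score columns before fitting (off by default; raw features are
        used as-is).
    regularization
        Quadratic weight penalty lambda; default ``1 / n_samples``.
    max_iter, tol
        L-BFGS iteration cap and gradient tolerance.

    Constant (zero-variance) columns get weight exactly 0.  The fit is
    deterministic: initialization is ``w = 1`` and the solver has no
    random component.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    n_samples, n_feat = X.shape
    if y.shape[0] != n_samples:
        raise ValueError("X and y disagree on the number of samples")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("NCA requires >= 2 classes")

    variable = X.std(axis=0) > 0
    Xv = X[:, variable]
    weights = np.zeros(n_feat)
    if Xv.shape[1] > 0:
        if standardize:
            Xv = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
        lam = (1.0 / n_samples) if regularization is None else float(regularization)
        same = (y[:, None] == y[None, :]) & ~np.eye(n_samples, dtype=bool)
        chunk = max(1, int(chunk_elements / max(1, n_samples * Xv.shape[1])))
        res = minimize(
            _nca_value_grad,
            x0=np.ones(Xv.shape[1]),
            args=(Xv, same.astype(float), lam, chunk),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": max_iter, "gtol": tol, "ftol": tol * 1e-3},
        )
        # weights enter the distance squared; report magnitudes, clipped at 0
        weights[variable] = np.maximum(np.abs(res.x), 0.0)
    idx = np.argsort(-weights, kind="stable")
    return FeatureWeights(w=weights, idx=idx)


def cumulative_weight_range(
    fw: FeatureWeights, t_low: float = 0.75, t_high: float = 0.99
) -> SelectionRange:
    """Prefix sizes at which the normalized cumulative weight reaches the thresholds."""
    if not 0 < t_low <= t_high <= 1:
        raise ValueError("thresholds must satisfy 0 < t_low <= t_high <= 1")
    w_sorted = fw.w[fw.idx]
    total = w_sorted.sum()
    if total <= 0:
        raise ValueError("all NCA weights are zero; cumulative-weight range is undefined")
    cum = np.cumsum(w_sorted) / total
    eps = 1e-12  # guard exact-threshold cases against float summation error
    sv = int(np.argmax(cum >= t_low - eps)) + 1
    fv = int(np.argmax(cum >= t_high - eps)) + 1
    return SelectionRange(sv=sv, fv=fv)


def kfold_knn_evaluator(
    *,
    n_neighbors: int = 1,
    metric: str = "euclidean",
    n_splits: int = 10,
    seed: int = 0,
) -> Callable[[np.ndarray, np.ndarray], float]:
    """CV-accuracy evaluator used inside the selection loop.

    kNN (default 1-NN, Euclidean) scored by out-of-fold accuracy under
    stratified k-fold CV with a fixed shuffle seed.
    """

    def evaluate(Xa: np.ndarray, y: np.ndarray) -> float:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        clf = KNeighborsClassifier(n_neighbors=n_neighbors, metric=metric)
        pred = cross_val_predict(clf, Xa, y, cv=cv)
        return float(accuracy_score(y, pred))

    return evaluate


def iterative_select(
    X: np.ndarray,
    y: np.ndarray,
    fw: FeatureWeights,
    sel_range: SelectionRange,
    evaluator: Callable[[np.ndarray, np.ndarray], float] | None = None,
    *,
    seed: int = 0,
) -> SelectionResult:
    """Greedy prefix search: evaluate top-a features for every a in [sv, fv].

    Returns the smallest prefix achieving the maximum CV accuracy (first
    maximum on ties).  Selected sets are nested by construction: the set
    for a is a prefix of the set for a + 1.
    """
    X = np.asarray(X)
    if sel_range.fv > X.shape[1]:
        raise ValueError(
            f"selection range fv={sel_range.fv} exceeds feature count {X.shape[1]}"
        )
    if evaluator is None:
        evaluator = kfold_knn_evaluator(seed=seed)
    counts = np.arange(sel_range.sv, sel_range.fv + 1)
    trace = np.empty(counts.size, dtype=float)
    Xr = X[:, fw.idx[: sel_range.fv]]  # gather once, slice prefixes
    for i, a in enumerate(counts):
        try:
            trace[i] = evaluator(Xr[:, :a], y)
        except Exception as exc:
            raise RuntimeError(f"selection evaluator failed at feature count a={a}") from exc
    best_i = int(np.argmax(trace))  # first maximum on ties -> smallest count
    best_count = int(counts[best_i])
    return SelectionResult(
        sv=sel_range.sv,
        fv=sel_range.fv,
        accuracy_trace=trace,
        best_count=best_count,
        best_accuracy=float(trace[best_i]),
        selected_indices=fw.idx[:best_count].copy(),
        ranking=fw.idx.copy(),
    )


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    *,
    t_low: float = 0.75,
    t_high: float = 0.99,
    standardize: bool = False,
    evaluator: Callable[[np.ndarray, np.ndarray], float] | None = None,
    seed: int = 0,
    **nca_kwargs,
) -> SelectionResult:
    """Full CWINCA pass: weights -> cumulative range -> greedy prefix search."""
    fw = nca_weights(X, y, standardize=standardize, **nca_kwargs)
    rng = cumulative_weight_range(fw, t_low=t_low, t_high=t_high)
    return iterative_select(X, y, fw, rng, evaluator, seed=seed)
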