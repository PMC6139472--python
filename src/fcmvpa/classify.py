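"""Connectivity-feature MVPA: ranking, incremental LOOCV SVM, permutation null.

Subjects are classified (CTRL vs PP) from their 120 edge-strength
features with a linear soft-margin SVM (cost C = 1, raw r values, no
standardization by default).  Classification is repeated while growing
the number of included features from 1 to all, following a fixed feature
ordering; the default ordering ranks edges by descending absolute
two-sample t statistic between groups (ties broken by edge index), with
an unbiased per-fold ("nested") variant available.  Significance of the
accuracy curve is assessed against a permutation null: group labels are
shuffled (class counts preserved) and the whole procedure — ranking
included — is recomputed per permutation.

The LOOCV inner loop uses an SMO solver for the linear C-SVC (same dual
formulation as libsvm: box constraints, unregularized bias via the
equality constraint), jit-compiled and driven from a precomputed Gram
matrix that is updated incrementally as features are added.  The
``backend="sklearn"`` option routes every fit through
``sklearn.svm.SVC`` instead; the two agree to numerical tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "CohortFeatureMatrix",
    "FeatureRanking",
    "ClassificationCurve",
    "rank_features",
    "loocv_accuracy",
    "incremental_curve",
    "permutation_null",
    "find_peak",
    "edge_report",
]

GROUPS = ("CTRL", "PP")


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class CohortFeatureMatrix:
    """Subjects x features matrix with group labels and the edge index map."""

    X: np.ndarray  # (n_subjects, n_features)
    labels: np.ndarray  # str array, entries in GROUPS
    edge_pairs: tuple[tuple[int, int], ...]
    edge_names: tuple[str, ...]
    subject_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ValueError("X must be subjects x features with one label per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing/non-finite entries")
        if self.X.shape[1] != len(self.edge_pairs) or len(self.edge_pairs) != len(
            self.edge_names
        ):
            raise ValueError("edge map length must match the feature count")
        unknown = set(np.unique(self.labels)) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}")
        for g in GROUPS:
            if np.sum(self.labels == g) < 2:
                raise ValueError(f"group {g} needs at least 2 subjects")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def y_signed(self) -> np.ndarray:
        """+1 for the lexicographically later class (sklearn convention), -1 otherwise."""
        classes = np.sort(np.unique(self.labels))
        return np.where(self.labels == classes[-1], 1.0, -1.0)


@dataclass
class FeatureRanking:
    """A permutation of the feature indices plus the statistic that ordered it."""

    order: np.ndarray  # best-first permutation of range(n_features)
    statistic: np.ndarray  # per-feature ranking statistic (signed t by default)
    method: str
    degenerate: tuple[int, ...] = ()  # zero-variance edges ranked by the |t|=inf rule

    def __post_init__(self) -> None:
        order = np.asarray(self.order)
        if sorted(order.tolist()) != list(range(len(order))):
            raise ValueError("order must be a permutation of the feature indices")
        self.order = order


@dataclass
class ClassificationCurve:
    """LOOCV accuracy as a function of the number of included features."""

    k: np.ndarray
    accuracy: np.ndarray
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    n_permutations: int = 0
    peak_k: int = 0
    peak_accuracy: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_k == 0:
            self.peak_k, self.peak_accuracy = find_peak(self.accuracy)

    def to_frame(self) -> pd.DataFrame:
        d = {"k": self.k, "accuracy": self.accuracy}
        if self.null_mean is not None:
            d["null_mean"] = self.null_mean
            d["null_sd"] = self.null_sd
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# Feature ranking
# ---------------------------------------------------------------------------


def _two_sample_t(X: np.ndarray, y_signed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per column (positive-class mean first).

    Returns (t, degenerate_mask); zero pooled variance with unequal means
    gives signed infinity (such edges rank on top and are flagged), with
    equal means t = 0.
    """
    a, b = X[y_signed > 0], X[y_signed < 0]
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    degenerate = denom == 0
    t[degenerate & (diff != 0)] = np.sign(diff[degenerate & (diff != 0)]) * np.inf
    t[degenerate & (diff == 0)] = 0.0
    return t, degenerate


def rank_features(
    data: CohortFeatureMatrix, method: str = "ttest", C: float = 1.0
) -> FeatureRanking:
    """Order features best-first for the incremental classification.

    ``ttest`` (default): descending absolute two-sample t statistic between
    groups.  ``svm_weight``: descending absolute weight of a linear SVM
    trained on all features.  Ties break toward the lower edge index
    (stable sort).  Zero within-group-variance edges have infinite |t|,
    rank on top, and are flagged in ``degenerate``.
    """
    y = data.y_signed
    if method == "ttest":
        stat, degen = _two_sample_t(data.X, y)
        key = np.abs(stat)
    elif method == "svm_weight":
        from sklearn.svm import SVC

        w = SVC(kernel="linear", C=C).fit(data.X, y).coef_.ravel()
        stat, degen = w, np.zeros(len(w), dtype=bool)
        key = np.abs(stat)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    order = np.argsort(-key, kind="stable")
    return FeatureRanking(
        order=order,
        statistic=stat,
        method=method,
        degenerate=tuple(int(i) for i in np.flatnonzero(degen)),
    )


# ---------------------------------------------------------------------------
# Linear C-SVC via SMO on a precomputed Gram matrix
# ---------------------------------------------------------------------------


@njit(cache=True)
def _smo_solve(K, y, C, tol, max_iter):  # pragma: no cover - jitted
    """libsvm-style SMO for the binary C-SVC dual on kernel matrix K."""
    n = K.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)  # grad_i = sum_j y_i y_j K_ij alpha_j - 1
    for _ in range(max_iter):
        # maximal violating pair
        g_max = -1e300
        g_min = 1e300
        i_up = -1
        j_low = -1
        for t in range(n):
            yg = -y[t] * grad[t]
            in_up = (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0)
            in_low = (y[t] < 0 and alpha[t] < C) or (y[t] > 0 and alpha[t] > 0)
            if in_up and yg > g_max:
                g_max = yg
                i_up = t
            if in_low and yg < g_min:
                g_min = yg
                j_low = t
        if i_up < 0 or j_low < 0 or g_max - g_min < tol:
            break
        i, j = i_up, j_low
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad <= 1e-12:
            quad = 1e-12
        step = (g_max - g_min) / quad  # step in the y_i*alpha_i direction
        # box bounds on the step for both multipliers
        if y[i] > 0:
            lo_i, hi_i = -alpha[i], C - alpha[i]
        else:
            lo_i, hi_i = alpha[i] - C, alpha[i]
        if y[j] > 0:
            lo_j, hi_j = alpha[j] - C, alpha[j]
        else:
            lo_j, hi_j = -alpha[j], C - alpha[j]
        lo = max(lo_i, lo_j)
        hi = min(hi_i, hi_j)
        if step < lo:
            step = lo
        elif step > hi:
            step = hi
        if step == 0.0:
            break
        d_i = y[i] * step
        d_j = -y[j] * step
        alpha[i] += d_i
        alpha[j] += d_j
        for t in range(n):
            grad[t] += y[t] * (y[i] * K[t, i] * d_i + y[j] * K[t, j] * d_j)
    # bias from the free support vectors (fallback: midpoint of the bounds)
    b_sum = 0.0
    n_free = 0
    for t in range(n):
        if 1e-8 < alpha[t] < C - 1e-8:
            s = 0.0
            for u in range(n):
                s += alpha[u] * y[u] * K[t, u]
            b_sum += y[t] - s
            n_free += 1
    if n_free > 0:
        b = b_sum / n_free
    else:
        g_max = -1e300
        g_min = 1e300
        for t in range(n):
            yg = -y[t] * grad[t]
            in_up = (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0)
            in_low = (y[t] < 0 and alpha[t] < C) or (y[t] > 0 and alpha[t] > 0)
            if in_up and yg > g_max:
                g_max = yg
            if in_low and yg < g_min:
                g_min = yg
        b = (g_max + g_min) / 2.0
    return alpha, b


@njit(cache=True)
def _loocv_gram(G, y, C, tol, max_iter):  # pragma: no cover - jitted
    """Leave-one-out predictions (+1/-1) from a full precomputed Gram matrix."""
    n = G.shape[0]
    preds = np.empty(n)
    Ksub = np.empty((n - 1, n - 1))
    ysub = np.empty(n - 1)
    for f in range(n):
        r = 0
        for a in range(n):
            if a == f:
                continue
            c = 0
            for bcol in range(n):
                if bcol == f:
                    continue
                Ksub[r, c] = G[a, bcol]
                c += 1
            ysub[r] = y[a]
            r += 1
        alpha, b = _smo_solve(Ksub, ysub, C, tol, max_iter)
        dec = b
        r = 0
        for a in range(n):
            if a == f:
                continue
            dec += alpha[r] * ysub[r] * G[f, a]
            r += 1
        preds[f] = 1.0 if dec > 0 else -1.0
    return preds


def _loocv_preds_sklearn(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    from sklearn.svm import SVC

    n = len(y)
    preds = np.empty(n)
    for f in range(n):
        mask = np.ones(n, dtype=bool)
        mask[f] = False
        clf = SVC(kernel="linear", C=C).fit(X[mask], y[mask])
        preds[f] = clf.predict(X[f : f + 1])[0]
    return preds


_SMO_TOL = 1e-3  # libsvm's default stopping tolerance
_SMO_MAX_ITER = 200_000


def loocv_accuracy(
    data: CohortFeatureMatrix,
    ranking: FeatureRanking,
    k: int,
    C: float = 1.0,
    standardize: bool = False,
    backend: str = "smo",
) -> float:
    """LOOCV accuracy of the linear SVM on the top-``k`` ranked features."""
    if not 1 <= k <= data.n_features:
        raise ValueError(f"k must lie in [1, {data.n_features}]")
    y = data.y_signed
    Xk = data.X[:, ranking.order[:k]]
    preds = _loocv_predict(Xk, y, C, standardize, backend)
    return float(np.mean(preds == y))


def _loocv_predict(
    Xk: np.ndarray, y: np.ndarray, C: float, standardize: bool, backend: str
) -> np.ndarray:
    if standardize:
        # training-fold statistics only, so the generic per-fold path
        n = len(y)
        preds = np.empty(n)
        for f in range(n):
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            mu = Xk[mask].mean(axis=0)
            sd = Xk[mask].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Z = (Xk - mu) / sd
            if backend == "smo":
                G = Z @ Z.T
                preds[f] = _loocv_gram(
                    np.ascontiguousarray(G), y, C, _SMO_TOL, _SMO_MAX_ITER
                )[f]
            else:
                clf_preds = _loocv_preds_sklearn(Z, y, C)
                preds[f] = clf_preds[f]
        return preds
    if backend == "smo":
        G = np.ascontiguousarray(Xk @ Xk.T)
        return _loocv_gram(G, y, C, _SMO_TOL, _SMO_MAX_ITER)
    if backend == "sklearn":
        return _loocv_preds_sklearn(Xk, y, C)
    raise ValueError(f"unknown backend {backend!r}")


def incremental_curve(
    data: CohortFeatureMatrix,
    ranking: FeatureRanking | None = None,
    C: float = 1.0,
    backend: str = "smo",
    ranking_method: str = "ttest",
    nested: bool = False,
) -> ClassificationCurve:
    """LOOCV accuracy for every feature count k = 1..n_features.

    With ``nested=True`` the ranking is recomputed on each training fold
    (no selection bias); otherwise the supplied whole-cohort ``ranking``
    fixes the feature order for every fold.
    """
    y = data.y_signed
    n, F = data.n_subjects, data.n_features
    if nested:
        acc = _nested_curve(data, C, backend, ranking_method)
        return ClassificationCurve(k=np.arange(1, F + 1), accuracy=acc)
    if ranking is None:
        ranking = rank_features(data, method=ranking_method, C=C)
    Xo = data.X[:, ranking.order]
    acc = np.empty(F)
    if backend == "smo":
        G = np.zeros((n, n))
        for k in range(1, F + 1):
            col = Xo[:, k - 1]
            G += np.outer(col, col)
            preds = _loocv_gram(np.ascontiguousarray(G), y, C, _SMO_TOL, _SMO_MAX_ITER)
            acc[k - 1] = np.mean(preds == y)
    else:
        for k in range(1, F + 1):
            preds = _loocv_predict(Xo[:, :k], y, C, False, backend)
            acc[k - 1] = np.mean(preds == y)
    return ClassificationCurve(k=np.arange(1, F + 1), accuracy=acc)


def _nested_curve(
    data: CohortFeatureMatrix, C: float, backend: str, ranking_method: str
) -> np.ndarray:
    y = data.y_signed
    n, F = data.n_subjects, data.n_features
    correct = np.zeros(F)
    for f in range(n):
        mask = np.ones(n, dtype=bool)
        mask[f] = False
        sub = CohortFeatureMatrix(
            X=data.X[mask],
            labels=data.labels[mask],
            edge_pairs=data.edge_pairs,
            edge_names=data.edge_names,
        )
        order = rank_features(sub, method=ranking_method, C=C).order
        Xo = data.X[:, order]
        Xtr, ytr = Xo[mask], y[mask]
        if backend == "smo":
            for k in range(1, F + 1):
                alpha, b = _smo_solve(
                    np.ascontiguousarray(Xtr[:, :k] @ Xtr[:, :k].T),
                    ytr,
                    C,
                    _SMO_TOL,
                    _SMO_MAX_ITER,
                )
                dec = float(alpha * ytr @ (Xtr[:, :k] @ Xo[f, :k])) + b
                correct[k - 1] += (1.0 if dec > 0 else -1.0) == y[f]
        else:
            from sklearn.svm import SVC

            for k in range(1, F + 1):
                clf = SVC(kernel="linear", C=C).fit(Xtr[:, :k], ytr)
                correct[k - 1] += clf.predict(Xo[f : f + 1, :k])[0] == y[f]
    return correct / n


# ---------------------------------------------------------------------------
# Permutation null, peak, report
# ---------------------------------------------------------------------------


def permutation_null(
    data: CohortFeatureMatrix,
    ranking_method: str = "ttest",
    n_perm: int = 2000,
    seed: int = 0,
    C: float = 1.0,
    backend: str = "smo",
    return_curves: bool = False,
):
    """Per-k mean and sd of the accuracy curve under shuffled labels.

    Labels are permuted preserving class counts and the feature ranking is
    recomputed inside every permutation (a null that shares the selection
    step with the observed analysis).  Fully seeded and reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, data.n_features))
    for p in range(n_perm):
        labels_p = data.labels[rng.permutation(data.n_subjects)]
        data_p = CohortFeatureMatrix(
            X=data.X,
            labels=labels_p,
            edge_pairs=data.edge_pairs,
            edge_names=data.edge_names,
        )
        ranking_p = rank_features(data_p, method=ranking_method, C=C)
        curves[p] = incremental_curve(data_p, ranking_p, C=C, backend=backend).accuracy
    null_mean = curves.mean(axis=0)
    null_sd = curves.std(axis=0, ddof=1) if n_perm >= 2 else np.zeros(data.n_features)
    if return_curves:
        return null_mean, null_sd, curves
    return null_mean, null_sd


def find_peak(accuracy: Sequence[float]) -> tuple[int, float]:
    """(peak_k, peak_accuracy): the maximum, smallest k on ties (1-based)."""
    acc = np.asarray(accuracy, dtype=float)
    if acc.size == 0:
        raise ValueError("curve is empty")
    idx = int(np.argmax(acc))  # argmax returns the first maximum
    return idx + 1, float(acc[idx])


def edge_report(
    data: CohortFeatureMatrix,
    ranking: FeatureRanking,
    peak_k: int,
    tie_tol: float = 0.0,
) -> pd.DataFrame:
    """Per-edge group-mean r values for the features included at the peak.

    One row per included feature, in ranking order: rank, edge name,
    plain within-group averages of subject r, and a direction flag
    (``CTRL>PP``, ``PP>CTRL``, or ``tie``).
    """
    if not 1 <= peak_k <= data.n_features:
        raise ValueError(f"peak_k must lie in [1, {data.n_features}]")
    ctrl = data.X[data.labels == "CTRL"]
    pp = data.X[data.labels == "PP"]
    rows = []
    for rank, feat in enumerate(ranking.order[:peak_k], start=1):
        m_ctrl = float(ctrl[:, feat].mean())
        m_pp = float(pp[:, feat].mean())
        if abs(m_ctrl - m_pp) <= tie_tol:
            direction = "tie"
        else:
            direction = "CTRL>PP" if m_ctrl > m_pp else "PP>CTRL"
        rows.append(
            {
                "rank": rank,
                "edge": data.edge_names[feat],
                "edge_index": int(feat),
                "mean_r_CTRL": m_ctrl,
                "mean_r_PP": m_pp,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
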