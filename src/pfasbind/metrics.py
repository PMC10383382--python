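"""Statistical validation metrics for classification and regression QSAR.

Classification block: sensitivity, specificity, precision, accuracy,
F-measure, Matthews correlation, Cohen's kappa, geometric means (all
percentage metrics on the 0–100 scale, to match how such tables are
conventionally printed), plus ROC/AUROC and Wilks' lambda with its F
transform.  Regression block: R², leave-one-out Q², MAE and its
95%-trimmed variant, and Roy's scaled rm² predictivity metrics.  An
applicability-domain check (standardization approach) and a seeded
y-randomization test round out the battery.

Metrics whose denominator vanishes are reported as NaN and listed in an
``undefined`` field rather than silently set to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


# ---------------------------------------------------------------------------
# confusion matrix and derived metrics


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = "H"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    observed: Sequence[str], predicted: Sequence[str], positive: str = "H"
) -> ConfusionMatrix:
    """Exact 2x2 confusion counts from paired label vectors."""
    obs = list(observed)
    pred = list(predicted)
    if len(obs) != len(pred):
        raise ValueError(f"length mismatch: {len(obs)} observed vs {len(pred)} predicted")
    tp = sum(1 for o, p in zip(obs, pred) if o == positive and p == positive)
    fn = sum(1 for o, p in zip(obs, pred) if o == positive and p != positive)
    fp = sum(1 for o, p in zip(obs, pred) if o != positive and p == positive)
    tn = sum(1 for o, p in zip(obs, pred) if o != positive and p != positive)
    return ConfusionMatrix(tp, fp, tn, fn, positive)


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """The eight confusion-matrix metrics, percentages on the 0–100 scale.

    ``g_means`` is the geometric mean of sensitivity and specificity (in
    %); ``mcc`` and ``kappa`` are unitless in [-1, 1].  Undefined
    metrics (zero denominator) come back as NaN with their names listed
    under ``'undefined'``.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    n = cm.total
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity") * 100
    spec = ratio(tn, tn + fp, "specificity") * 100
    prec = ratio(tp, tp + fp, "precision") * 100
    acc = (tp + tn) / n * 100
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        undefined.append("f_measure")
        f_meas = math.nan
    else:
        f_meas = 2.0 / (1.0 / prec + 1.0 / sens)  # harmonic mean, % scale
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    pra = (tp + tn) / n
    pre = ((tp + fp) * (tp + fn) + (tn + fp) * (tn + fn)) / n**2
    if pre == 1.0:
        undefined.append("kappa")
        kappa = math.nan
    else:
        kappa = (pra - pre) / (1.0 - pre)
    g_means = math.sqrt(sens * spec) if not (math.isnan(sens) or math.isnan(spec)) else math.nan
    if math.isnan(g_means) and "sensitivity" not in undefined and "specificity" not in undefined:
        undefined.append("g_means")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "accuracy": acc,
        "f_measure": f_meas,
        "mcc": mcc,
        "kappa": kappa,
        "g_means": g_means,
        "n": n,
        "undefined": undefined,
    }


# ---------------------------------------------------------------------------
# ROC


def roc_auc(
    scores: Sequence[float], observed: Sequence[str], positive: str = "H"
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (threshold sweep) and trapezoidal AUROC.

    Higher scores must indicate the positive class (negate discriminant
    scores where low means positive).  Raises for single-class input.
    """
    y = np.asarray([1 if o == positive else 0 for o in observed])
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _thr = _sk_roc_curve(y, s)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# Wilks' lambda


def wilks_lambda(X, y) -> tuple[float, float, tuple[int, int]]:
    """Wilks' lambda det(W)/det(B+W) for two groups, with its F transform.

    ``F = ((1 - lambda)/lambda) * ((n - p - 1)/p)`` on ``(p, n - p - 1)``
    degrees of freedom (the standard two-group transformation).
    """
    Xa = np.atleast_2d(np.asarray(X, dtype=float))
    ya = np.asarray(y)
    groups = sorted(set(ya.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    n, p = Xa.shape
    grand = Xa.mean(axis=0)
    T = (Xa - grand).T @ (Xa - grand)
    W = np.zeros((p, p))
    for g in groups:
        Xg = Xa[ya == g]
        mg = Xg.mean(axis=0)
        W += (Xg - mg).T @ (Xg - mg)
    det_T = np.linalg.det(T)
    if det_T == 0:
        raise np.linalg.LinAlgError("total scatter matrix is singular")
    lam = float(np.linalg.det(W) / det_T)
    df1, df2 = p, n - p - 1
    if lam <= 0:
        raise np.linalg.LinAlgError("within scatter matrix is singular")
    F = (1.0 - lam) / lam * (df2 / df1)
    return lam, float(F), (df1, df2)


def generic_f_ratio(s1: float, sigma1: float, s2: float, sigma2: float) -> float:
    """Generic two-sample variance-ratio statistic (s²/σ² over s²/σ²)."""
    return (s1**2 / sigma1**2) / (s2**2 / sigma2**2)


# ---------------------------------------------------------------------------
# regression metrics


def regression_metrics(
    y_obs: Sequence[float],
    y_pred: Sequence[float],
    y_train_mean: Optional[float] = None,
) -> dict:
    """R², MAE and the 95%-trimmed MAE.

    R² is computed against the training-set mean (``y_train_mean``
    defaults to the mean of ``y_obs``).  ``mae95`` recomputes the MAE
    after discarding the ``ceil(5% n)`` largest absolute errors.
    """
    o = np.asarray(y_obs, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("y_obs and y_pred must be equal-length 1-D with n >= 2")
    ybar = float(o.mean()) if y_train_mean is None else float(y_train_mean)
    ss_tot = float(np.sum((o - ybar) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in observed response")
    r2 = 1.0 - float(np.sum((o - p) ** 2)) / ss_tot
    err = np.abs(o - p)
    mae = float(err.mean())
    n_drop = math.ceil(0.05 * len(o))
    kept = np.sort(err)[: len(o) - n_drop]
    mae95 = float(kept.mean()) if len(kept) else math.nan
    return {"r2": r2, "mae": mae, "mae95": mae95, "n": len(o)}


def q2_loo(X, y, fit: Optional[Callable] = None) -> float:
    """Leave-one-out cross-validated Q².

    ``Q² = 1 - PRESS / sum((y - ybar)²)`` with ``ybar`` the full-set
    mean.  Without a ``fit`` argument the exact hat-matrix shortcut for
    linear least squares is used (``e_loo = e / (1 - h_ii)``); passing a
    ``fit(X, y) -> model`` callable runs naive refits per fold.
    """
    Xa = np.atleast_2d(np.asarray(X, dtype=float))
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n < 3:
        raise ValueError("need n >= 3 for leave-one-out")
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in response")
    if fit is None:
        if n <= p + 1:
            raise ValueError("need n > p + 1 for least-squares leave-one-out")
        A = np.column_stack([np.ones(n), Xa])
        if np.linalg.matrix_rank(A) < p + 1:
            raise np.linalg.LinAlgError("rank-deficient descriptor matrix")
        beta, *_ = np.linalg.lstsq(A, ya, rcond=None)
        resid = ya - A @ beta
        h = np.einsum("ij,ij->i", A @ np.linalg.pinv(A.T @ A), A)
        press = float(np.sum((resid / (1.0 - h)) ** 2))
    else:
        press = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            model = fit(Xa[mask], ya[mask])
            pred_i = float(np.atleast_1d(model.predict(Xa[i:i + 1]))[0])
            press += (ya[i] - pred_i) ** 2
    return 1.0 - press / ss_tot


def _minmax_scale(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (v - lo) / (hi - lo)


def rm2_metrics(y_obs: Sequence[float], y_pred: Sequence[float]) -> dict:
    """Roy's scaled rm² predictivity metrics.

    Both vectors are min–max scaled by the observed range, then
    ``rm² = r²(1 - sqrt(r² - r0²))`` with ``r0²`` the zero-intercept
    determination coefficient (and the primed variant with the roles of
    observed and predicted swapped).  Reports the mean ``rm2_bar`` and
    absolute difference ``delta_rm2``.
    """
    o_raw = np.asarray(y_obs, dtype=float)
    p_raw = np.asarray(y_pred, dtype=float)
    if o_raw.shape != p_raw.shape or len(o_raw) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    lo, hi = float(o_raw.min()), float(o_raw.max())
    if hi == lo:
        raise ValueError("constant observed response")
    o = _minmax_scale(o_raw, lo, hi)
    p = _minmax_scale(p_raw, lo, hi)
    if np.std(p) == 0:
        raise ValueError("constant predictions")

    r = float(np.corrcoef(o, p)[0, 1])
    r2 = r * r
    k = float(np.sum(o * p) / np.sum(p * p))
    kprime = float(np.sum(o * p) / np.sum(o * o))
    r02 = 1.0 - float(np.sum((o - k * p) ** 2) / np.sum((o - o.mean()) ** 2))
    r02p = 1.0 - float(np.sum((p - kprime * o) ** 2) / np.sum((p - p.mean()) ** 2))
    rm2 = r2 * (1.0 - math.sqrt(max(r2 - r02, 0.0)))
    rm2p = r2 * (1.0 - math.sqrt(max(r2 - r02p, 0.0)))
    return {
        "rm2": rm2,
        "rm2_prime": rm2p,
        "rm2_bar": (rm2 + rm2p) / 2.0,
        "delta_rm2": abs(rm2 - rm2p),
        "r2": r2,
        "r02": r02,
        "r02_prime": r02p,
        "k": k,
        "k_prime": kprime,
    }


# ---------------------------------------------------------------------------
# applicability domain


@dataclass
class ADResult:
    inside: np.ndarray
    max_abs_z: np.ndarray
    outlier_descriptors: list[list[str]]
    zero_variance_columns: list[str] = field(default_factory=list)


def applicability_domain(
    X_train, X_query, n_sd: float = 3.0, names: Optional[Sequence[str]] = None
) -> ADResult:
    """Standardization-based applicability domain check.

    A query compound is outside the domain when any descriptor deviates
    from the training mean by more than ``n_sd`` training standard
    deviations.  Zero-variance training columns cannot be standardized;
    they are excluded from the check and flagged in the result.
    """
    Xt = np.atleast_2d(np.asarray(X_train, dtype=float))
    Xq = np.atleast_2d(np.asarray(X_query, dtype=float))
    if Xt.shape[1] != Xq.shape[1]:
        raise ValueError("training and query descriptor counts differ")
    p = Xt.shape[1]
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=1)
    usable = sd > 0
    zero_var = [names[j] for j in range(p) if not usable[j]]
    z = np.zeros_like(Xq)
    z[:, usable] = (Xq[:, usable] - mean[usable]) / sd[usable]
    abs_z = np.abs(z)
    max_abs = abs_z.max(axis=1) if p else np.zeros(Xq.shape[0])
    outliers = [
        [names[j] for j in range(p) if usable[j] and abs_z[i, j] > n_sd]
        for i in range(Xq.shape[0])
    ]
    inside = np.array([len(o) == 0 for o in outliers])
    return ADResult(inside, max_abs, outliers, zero_var)


# ---------------------------------------------------------------------------
# y-randomization


def y_randomization(
    X, y, task: str = "regress", n_permutations: int = 100, seed: int = 0
) -> dict:
    """Seeded response-scrambling test.

    Permutes the response, refits, and reports the null distribution of
    the headline metric (R² for regression, Wilks' lambda for
    classification) next to the unpermuted value.
    """
    Xa = np.atleast_2d(np.asarray(X, dtype=float))
    ya = np.asarray(y)
    rng = np.random.default_rng(seed)

    def metric(yy) -> float:
        if task == "regress":
            A = np.column_stack([np.ones(len(yy)), Xa])
            beta, *_ = np.linalg.lstsq(A, np.asarray(yy, float), rcond=None)
            pred = A @ beta
            return regression_metrics(yy, pred)["r2"]
        if task == "classify":
            lam, _, _ = wilks_lambda(Xa, yy)
            return lam
        raise ValueError("task must be 'regress' or 'classify'")

    observed = metric(ya)
    null = np.array([metric(rng.permutation(ya)) for _ in range(n_permutations)])
    return {"observed": observed, "null": null, "task": task, "seed": seed}
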