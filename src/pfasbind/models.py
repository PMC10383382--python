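"""Classification and regression QSAR models for albumin binding.

Two frozen reference models reproduce the published albumin-binding
equations:

* the discriminant function
  ``dP = -14.668 + 33.651*Eig12_AEA_bo + 0.378*DECC + 30.405*X4A``,
  where scores *below* the potency threshold are classed high-affinity
  (H) and scores above it low-affinity (L); and
* the PLS-derived regression
  ``EC50[mM] = 24.427 - 23.551*PDI - 0.862*GATS8v - 0.607*MATS8m - 4.388*QED``.

Alongside them the module provides the fitting machinery the study
workflow rests on: two-class Fisher discriminant analysis, ordinary
least squares, NIPALS PLS1, seeded genetic-algorithm descriptor
selection, descriptor-pool pretreatment, and the exhaustive
double-cross-validation procedure used for datasets too small to split
into fixed training and test sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics


# ---------------------------------------------------------------------------
# model containers


def _align(X, names: Sequence[str]) -> np.ndarray:
    """Coerce X to an array in the model's declared descriptor order."""
    if isinstance(X, pd.DataFrame):
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor column(s): {missing}")
        return X[list(names)].to_numpy(dtype=float)
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    if arr.shape[1] != len(names):
        raise ValueError(f"expected {len(names)} descriptor columns, got {arr.shape[1]}")
    return arr


@dataclass
class DiscriminantModel:
    """Linear two-class discriminant with a decision threshold.

    The discriminant score is ``intercept + X @ coefficients``.  Scores
    at or below ``threshold`` are assigned the positive (high-affinity,
    'H') class, scores above it 'L' — the published sign convention for
    the binding discriminant.
    """

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    threshold: float = 0.0
    positive_class: str = "H"
    negative_class: str = "L"
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.descriptor_names) != len(self.coefficients):
            raise ValueError("one coefficient per descriptor required")

    def score(self, X) -> np.ndarray:
        Xa = _align(X, self.descriptor_names)
        return self.intercept + Xa @ np.asarray(self.coefficients)

    def predict(self, X) -> np.ndarray:
        s = self.score(X)
        return np.where(s <= self.threshold, self.positive_class, self.negative_class)

    def calibrate_threshold(self, X, y: Sequence[str]) -> "DiscriminantModel":
        """Set the threshold at the midpoint of the two class-mean scores."""
        s = self.score(X)
        y = np.asarray(y)
        m_pos = s[y == self.positive_class].mean()
        m_neg = s[y == self.negative_class].mean()
        return DiscriminantModel(
            self.descriptor_names, self.coefficients, self.intercept,
            threshold=float((m_pos + m_neg) / 2.0),
            positive_class=self.positive_class, negative_class=self.negative_class,
            stats=dict(self.stats),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "discriminant",
                "descriptor_names": list(self.descriptor_names),
                "coefficients": list(self.coefficients),
                "intercept": self.intercept,
                "threshold": self.threshold,
                "positive_class": self.positive_class,
                "negative_class": self.negative_class,
                "stats": self.stats,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscriminantModel":
        d = json.loads(text)
        return cls(
            tuple(d["descriptor_names"]), tuple(d["coefficients"]), d["intercept"],
            d.get("threshold", 0.0), d.get("positive_class", "H"),
            d.get("negative_class", "L"), d.get("stats", {}),
        )


@dataclass
class RegressionModel:
    """Linear regression model (MLR or PLS collapsed to linear form)."""

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    kind: str = "MLR"
    n_latent: Optional[int] = None
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.descriptor_names) != len(self.coefficients):
            raise ValueError("one coefficient per descriptor required")
        if self.kind not in ("MLR", "PLS"):
            raise ValueError(f"kind must be MLR or PLS, got {self.kind!r}")
        if self.n_latent is not None and self.n_latent > len(self.descriptor_names):
            raise ValueError("latent variables cannot exceed descriptor count")

    def predict(self, X) -> np.ndarray:
        Xa = _align(X, self.descriptor_names)
        return self.intercept + Xa @ np.asarray(self.coefficients)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "descriptor_names": list(self.descriptor_names),
                "coefficients": list(self.coefficients),
                "intercept": self.intercept,
                "n_latent": self.n_latent,
                "stats": self.stats,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RegressionModel":
        d = json.loads(text)
        return cls(
            tuple(d["descriptor_names"]), tuple(d["coefficients"]), d["intercept"],
            d.get("kind", "MLR"), d.get("n_latent"), d.get("stats", {}),
        )


def save_model(model, path: str | Path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path: str | Path):
    d = json.loads(Path(path).read_text())
    cls = DiscriminantModel if d.get("kind") == "discriminant" else RegressionModel
    return cls.from_json(json.dumps(d))


# ---------------------------------------------------------------------------
# frozen reference models


def reference_eq1() -> DiscriminantModel:
    """The frozen binding-affinity discriminant model.

    Coefficients and intercept are serialized constants of the published
    model.  The potency threshold was not printed; it defaults to 0 and
    can be recalibrated on data via :meth:`DiscriminantModel.calibrate_threshold`
    (midpoint of class-mean scores).
    """
    return DiscriminantModel(
        descriptor_names=("Eig12_AEA_bo", "DECC", "X4A"),
        coefficients=(33.651, 0.378, 30.405),
        intercept=-14.668,
        threshold=0.0,
        stats={"wilks_lambda": 0.26, "F": 10.45, "df": [3, 12]},
    )


def reference_eq2() -> RegressionModel:
    """The frozen PLS-derived EC50 regression model (coefficients in mM)."""
    return RegressionModel(
        descriptor_names=("PDI", "GATS8v", "MATS8m", "QED"),
        coefficients=(-23.551, -0.862, -0.607, -4.388),
        intercept=24.427,
        kind="PLS",
        n_latent=3,
        stats={"r2": 0.802, "q2_loo": 0.691, "rm2_loo_bar": 0.594, "mae": 0.205},
    )


# ---------------------------------------------------------------------------
# fitting


def _names_for(X, fallback_n: int) -> tuple[str, ...]:
    if isinstance(X, pd.DataFrame):
        return tuple(str(c) for c in X.columns)
    return tuple(f"x{i}" for i in range(fallback_n))


def fit_lda(X, y: Sequence[str], positive_class: str = "H") -> DiscriminantModel:
    """Two-class Fisher discriminant analysis.

    The discriminant direction is chosen so the positive class takes the
    *lower* scores; the threshold sits at the midpoint of the class-mean
    scores.  Wilks' lambda and its F statistic are reported in
    ``model.stats``.  A singular within-class scatter raises with a hint
    to prune the descriptor set.
    """
    Xa = np.atleast_2d(np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float))
    ya = np.asarray(y)
    classes = sorted(set(ya))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if Xa.shape[0] <= Xa.shape[1]:
        raise ValueError("need more samples than descriptors")
    neg = [c for c in classes if c != positive_class]
    if positive_class not in classes or len(neg) != 1:
        raise ValueError(f"positive class {positive_class!r} not among labels {classes}")
    negative_class = neg[0]
    Xp = Xa[ya == positive_class]
    Xn = Xa[ya == negative_class]
    mp, mn = Xp.mean(axis=0), Xn.mean(axis=0)
    Sw = (Xp - mp).T @ (Xp - mp) + (Xn - mn).T @ (Xn - mn)
    try:
        w = np.linalg.solve(Sw, mn - mp)  # positive class scores low
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular; prune collinear or constant descriptors"
        ) from exc
    lam, F, dfs = _metrics.wilks_lambda(Xa, ya)
    model = DiscriminantModel(
        _names_for(X, Xa.shape[1]),
        tuple(float(c) for c in w),
        intercept=0.0,
        positive_class=positive_class,
        negative_class=negative_class,
        stats={"wilks_lambda": lam, "F": F, "df": list(dfs)},
    )
    return model.calibrate_threshold(Xa if not isinstance(X, pd.DataFrame) else X, ya)


def fit_mlr(X, y) -> RegressionModel:
    """Ordinary least squares with intercept.

    Requires full column rank and more rows than columns; raises a
    ``ValueError`` on rank deficiency (e.g. duplicated columns).
    """
    Xa = np.atleast_2d(np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float))
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than descriptors ({p})")
    A = np.column_stack([np.ones(n), Xa])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("descriptor matrix is rank deficient (collinear or constant columns)")
    beta, *_ = np.linalg.lstsq(A, ya, rcond=None)
    resid = ya - A @ beta
    return RegressionModel(
        _names_for(X, p),
        tuple(float(b) for b in beta[1:]),
        float(beta[0]),
        kind="MLR",
        stats={"rss": float(resid @ resid), "n": n},
    )


def fit_pls(X, y, n_lv: int, scale: bool = True) -> RegressionModel:
    """PLS1 regression by NIPALS, collapsed to a linear predictor.

    Descriptors are autoscaled by default (centered-only with
    ``scale=False``); the response is centered.  With ``n_lv`` equal to
    the column count on full-rank data the predictions coincide with
    ordinary least squares.
    """
    Xa = np.atleast_2d(np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float))
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if not 1 <= n_lv <= p:
        raise ValueError(f"n_lv must be in [1, {p}], got {n_lv}")
    x_mean = Xa.mean(axis=0)
    x_std = Xa.std(axis=0, ddof=1) if scale else np.ones(p)
    x_std = np.where(x_std == 0, 1.0, x_std)
    y_mean = float(ya.mean())
    E = (Xa - x_mean) / x_std
    f = ya - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt == 0:
            break
        P[:, a] = E.T @ t / tt
        q[a] = float(f @ t) / tt
        W[:, a] = w
        E = E - np.outer(t, P[:, a])
        f = f - q[a] * t
    B_scaled = W @ np.linalg.solve(P.T @ W, np.eye(n_lv)) @ q
    coef = B_scaled / x_std
    intercept = y_mean - float(coef @ x_mean)
    return RegressionModel(
        _names_for(X, p),
        tuple(float(c) for c in coef),
        float(intercept),
        kind="PLS",
        n_latent=n_lv,
        stats={"scaled": scale, "n": n},
    )


def predict(model, X) -> np.ndarray:
    """Apply a fitted or frozen model; deterministic linear scoring."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# descriptor-pool pretreatment


@dataclass
class PretreatResult:
    kept: list[int]
    dropped: dict[int, str]

    def reduce(self, X):
        if isinstance(X, pd.DataFrame):
            return X.iloc[:, self.kept]
        return np.asarray(X)[:, self.kept]


def pretreat(
    X, y=None, variance_threshold: float = 1e-4, correlation_threshold: float = 0.95
) -> PretreatResult:
    """Drop near-constant and redundant descriptor columns.

    Columns with variance below ``variance_threshold`` are removed.  From
    each pair with ``|r| > correlation_threshold``, the member less
    correlated with the response ``y`` is removed (the later column when
    no response is given).  Returns kept indices plus a reason per
    dropped column.
    """
    Xa = np.atleast_2d(np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float))
    p = Xa.shape[1]
    dropped: dict[int, str] = {}
    variances = Xa.var(axis=0)
    for j in range(p):
        if variances[j] < variance_threshold:
            dropped[j] = f"variance {variances[j]:.3g} < {variance_threshold}"
    alive = [j for j in range(p) if j not in dropped]
    if y is not None:
        ya = np.asarray(y, dtype=float)
        ry = {
            j: abs(np.corrcoef(Xa[:, j], ya)[0, 1]) if variances[j] > 0 else 0.0
            for j in alive
        }
    else:
        ry = {j: -j for j in alive}  # no response: prefer earlier columns
    for a_idx in range(len(alive)):
        ja = alive[a_idx]
        if ja in dropped:
            continue
        for jb in alive[a_idx + 1:]:
            if jb in dropped:
                continue
            r = abs(np.corrcoef(Xa[:, ja], Xa[:, jb])[0, 1])
            if r > correlation_threshold:
                loser = ja if ry[ja] < ry[jb] else jb
                dropped[loser] = f"|r|={r:.3f} with column {jb if loser == ja else ja}"
                if loser == ja:
                    break
    kept = [j for j in range(p) if j not in dropped]
    return PretreatResult(kept, dropped)


# ---------------------------------------------------------------------------
# genetic-algorithm descriptor selection


@dataclass
class GAConfig:
    """Seeded GA over fixed-size descriptor subsets.

    Defaults are conventional small-pool settings: population 50, 100
    generations, one-point (subset-preserving) crossover at rate 0.8,
    per-gene mutation 0.05, elitism 1.
    """

    subset_size: int = 4
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subset_size", "population_size", "generations", "elitism"):
            if getattr(self, name) <= 0 and name != "elitism":
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.crossover_rate <= 1 or not 0 <= self.mutation_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")


def _fitness_function(kind: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if kind == "mlr":
        def fit_q2(Xs: np.ndarray, y: np.ndarray) -> float:
            try:
                return _metrics.q2_loo(Xs, y)
            except (ValueError, np.linalg.LinAlgError):
                return -np.inf
        return fit_q2
    if kind == "lda":
        def fit_lambda(Xs: np.ndarray, y: np.ndarray) -> float:
            try:
                lam, _, _ = _metrics.wilks_lambda(Xs, np.asarray(y))
            except (ValueError, np.linalg.LinAlgError):
                return -np.inf
            return 1.0 - lam
        return fit_lambda
    raise ValueError(f"unknown model kind {kind!r} (use 'mlr' or 'lda')")


def ga_select(
    X_pool, y, kind: str = "mlr", cfg: Optional[GAConfig] = None
) -> list[tuple[tuple[int, ...], float]]:
    """Rank fixed-size descriptor subsets by a cross-validated fitness.

    Fitness is leave-one-out Q2 for regression subsets and ``1 - Wilks'
    lambda`` for discriminant subsets.  The run is fully determined by
    ``cfg.seed``.  Returns evaluated subsets sorted by decreasing
    fitness (column indices into the pool).
    """
    cfg = cfg or GAConfig()
    Xa = np.atleast_2d(np.asarray(X_pool, dtype=float) if not isinstance(X_pool, pd.DataFrame) else X_pool.to_numpy(float))
    ya = np.asarray(y)
    p = Xa.shape[1]
    k = cfg.subset_size
    if k > p:
        raise ValueError(f"subset size {k} exceeds pool size {p}")
    fitness = _fitness_function(kind)
    cache: dict[tuple[int, ...], float] = {}

    def evaluate(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = fitness(Xa[:, list(subset)], ya)
        return cache[subset]

    if k == p:
        only = tuple(range(p))
        return [(only, evaluate(only))]

    rng = np.random.default_rng(cfg.seed)
    pop = [
        tuple(sorted(int(x) for x in rng.choice(p, size=k, replace=False)))
        for _ in range(cfg.population_size)
    ]

    def crossover(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
        shared = sorted(set(a) & set(b))
        rest = sorted(set(a) ^ set(b))
        need = k - len(shared)
        pick = rng.choice(len(rest), size=need, replace=False) if need else []
        return tuple(sorted(shared + [rest[i] for i in pick]))

    def mutate(ind: tuple[int, ...]) -> tuple[int, ...]:
        genes = list(ind)
        outside = [j for j in range(p) if j not in ind]
        for g in range(k):
            if outside and rng.random() < cfg.mutation_rate:
                swap = int(rng.integers(len(outside)))
                genes[g], outside[swap] = outside[swap], genes[g]
        return tuple(sorted(genes))

    for _gen in range(cfg.generations):
        scored = sorted(pop, key=evaluate, reverse=True)
        next_pop = scored[: cfg.elitism]
        while len(next_pop) < cfg.population_size:
            # binary tournament selection
            i, j = rng.integers(cfg.population_size, size=2)
            parent_a = min(scored[i], scored[j], key=lambda s: -evaluate(s))
            i, j = rng.integers(cfg.population_size, size=2)
            parent_b = min(scored[i], scored[j], key=lambda s: -evaluate(s))
            child = crossover(parent_a, parent_b) if rng.random() < cfg.crossover_rate else parent_a
            next_pop.append(mutate(child))
        pop = next_pop
    for ind in pop:
        evaluate(ind)
    return sorted(cache.items(), key=lambda kv: kv[1], reverse=True)


# ---------------------------------------------------------------------------
# exhaustive double cross-validation


@dataclass
class DCVConfig:
    """Configuration of the small-dataset double cross-validation.

    ``validation_size`` compounds are held out per split (default 3,
    the study setting); all ``C(n, validation_size)`` splits are
    enumerated unless ``max_splits`` caps them, in which case a seeded
    subsample of splits is drawn.  The optimal model is selected by mean
    absolute error on the held-out compounds, ties broken by higher
    leave-one-out Q2 on the training part.
    """

    validation_size: int = 3
    max_splits: Optional[int] = None
    selection_rule: str = "mae"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.validation_size < 1:
            raise ValueError("validation_size must be >= 1")
        if self.selection_rule not in ("mae", "q2"):
            raise ValueError("selection_rule must be 'mae' or 'q2'")


@dataclass
class SplitResult:
    val_indices: tuple[int, ...]
    subset: tuple[int, ...]
    model: RegressionModel
    val_mae: float
    train_q2: float


@dataclass
class DCVResult:
    splits: list[SplitResult]
    best: SplitResult
    consensus: np.ndarray
    n_splits_enumerated: int


def double_cross_validate(
    X,
    y,
    cfg: Optional[DCVConfig] = None,
    select: Optional[Callable[[np.ndarray, np.ndarray], Sequence[int]]] = None,
    fit: Callable = fit_mlr,
) -> DCVResult:
    """Exhaustive double cross-validation for small datasets.

    For every held-out validation subset the remaining compounds are
    (optionally) run through descriptor selection, a model is fitted and
    scored on the held-out compounds.  Returns every split's model
    ranked per the selection rule, the optimal model, and the consensus
    (mean) prediction per compound over the splits that held it out.
    """
    cfg = cfg or DCVConfig()
    Xa = np.atleast_2d(np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float))
    ya = np.asarray(y, dtype=float)
    n = Xa.shape[0]
    if cfg.validation_size >= n:
        raise ValueError("validation_size must be smaller than the dataset")
    all_splits = list(combinations(range(n), cfg.validation_size))
    n_enumerated = len(all_splits)
    if cfg.max_splits is not None and n_enumerated > cfg.max_splits:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(n_enumerated, size=cfg.max_splits, replace=False)
        all_splits = [all_splits[i] for i in sorted(idx)]

    results: list[SplitResult] = []
    pred_sum = np.zeros(n)
    pred_count = np.zeros(n)
    for val in all_splits:
        train = [i for i in range(n) if i not in val]
        Xt, yt = Xa[train], ya[train]
        subset = tuple(select(Xt, yt)) if select is not None else tuple(range(Xa.shape[1]))
        model = fit(Xt[:, list(subset)], yt)
        preds = model.predict(Xa[np.array(val)][:, list(subset)])
        mae = float(np.mean(np.abs(ya[list(val)] - preds)))
        try:
            q2 = _metrics.q2_loo(Xt[:, list(subset)], yt)
        except (ValueError, np.linalg.LinAlgError):
            q2 = -np.inf
        results.append(SplitResult(tuple(val), subset, model, mae, q2))
        for i, pr in zip(val, preds):
            pred_sum[i] += pr
            pred_count[i] += 1

    if cfg.selection_rule == "mae":
        results.sort(key=lambda r: (r.val_mae, -r.train_q2))
    else:
        results.sort(key=lambda r: (-r.train_q2, r.val_mae))
    with np.errstate(invalid="ignore"):
        consensus = np.where(pred_count > 0, pred_sum / np.maximum(pred_count, 1), np.nan)
    return DCVResult(results, results[0], consensus, n_enumerated)
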