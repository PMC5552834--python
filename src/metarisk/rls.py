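"""Regularised least-squares (ridge) binary risk classification.

Provides primal/dual fitting with an unpenalised intercept, closed-form
leave-one-out predictions through the regularised hat matrix, greedy forward
feature selection driven by the LOO squared error, and a cross-validated
panel-size sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "RLSConfig",
    "RLSModel",
    "GreedySelection",
    "PanelSweep",
    "fit_rls",
    "predict",
    "loo_predictions",
    "greedy_rls_select",
    "sweep_panel_size",
]

DEFAULT_LAMBDA_GRID = tuple(float(2.0 ** k) for k in range(-15, 16))


@dataclass(frozen=True)
class RLSConfig:
    lam: float = 1.0
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0; got {self.lam}")
        grid = tuple(float(g) for g in self.lambda_grid)
        if not grid:
            raise ValueError("lambda grid must be non-empty")
        if any(g <= 0 for g in grid):
            raise ValueError("lambda grid values must be strictly positive")
        if list(grid) != sorted(grid):
            raise ValueError("lambda grid must be sorted ascending")
        object.__setattr__(self, "lambda_grid", grid)


@dataclass
class RLSModel:
    feature_names: list
    weights: np.ndarray
    intercept_value: float
    lam: float
    train_score_sd: float
    degenerate_scores: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != len(self.feature_names):
            raise ValueError(
                f"{self.weights.size} weights for {len(self.feature_names)} features")

    def to_json(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "intercept_value": self.intercept_value,
            "lambda": self.lam,
            "train_score_sd": self.train_score_sd,
            "degenerate_scores": self.degenerate_scores,
        }

    @classmethod
    def from_json(cls, payload) -> "RLSModel":
        return cls(
            feature_names=list(payload["feature_names"]),
            weights=np.asarray(payload["weights"], dtype=float),
            intercept_value=float(payload["intercept_value"]),
            lam=float(payload["lambda"]),
            train_score_sd=float(payload["train_score_sd"]),
            degenerate_scores=bool(payload.get("degenerate_scores", False)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RLSModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


@dataclass
class GreedySelection:
    ordered_features: list
    ordered_indices: list
    criterion_path: list
    lam: float

    def __post_init__(self) -> None:
        if len(set(self.ordered_indices)) != len(self.ordered_indices):
            raise ValueError("selected features must be distinct")
        if len(self.criterion_path) != len(self.ordered_features):
            raise ValueError("criterion path length mismatch")


def _as_pm1(y) -> np.ndarray:
    """Accept 0/1 or +/-1 labels; return +/-1 float vector."""
    y = np.asarray(y, dtype=float).ravel()
    vals = set(np.unique(y))
    if vals <= {0.0, 1.0}:
        y = np.where(y > 0, 1.0, -1.0)
    elif not vals <= {-1.0, 1.0}:
        raise ValueError(f"labels must be 0/1 or -1/+1; found {sorted(vals)}")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return y


def _solve_weights(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge weights, primal or dual depending on which system is smaller."""
    n, p = X.shape
    if lam == 0:
        try:
            return np.linalg.solve(X.T @ X, X.T @ y)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular system at lambda=0 (collinear features); "
                "use lambda > 0") from exc
    if p <= n:
        A = X.T @ X + lam * np.eye(p)
        return cho_solve(cho_factor(A, lower=True), X.T @ y)
    G = X @ X.T + lam * np.eye(n)
    alpha = cho_solve(cho_factor(G, lower=True), y)
    return X.T @ alpha


def fit_rls(X, y, config: RLSConfig | None = None,
            feature_names=None) -> RLSModel:
    """Fit ridge regression on +/-1 labels.

    The intercept (when enabled) is left unpenalised, implemented by centring
    ``X`` and ``y`` and back-solving.
    """
    config = config or RLSConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_pm1(y)
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    if config.intercept:
        mu, ybar = X.mean(axis=0), y.mean()
        w = _solve_weights(X - mu, y - ybar, config.lam)
        intercept = float(ybar - mu @ w)
    else:
        w = _solve_weights(X, y, config.lam)
        intercept = 0.0
    scores = X @ w + intercept
    sd = float(np.std(scores, ddof=1)) if scores.size > 1 else 0.0
    return RLSModel(feature_names=list(feature_names), weights=w,
                    intercept_value=intercept, lam=config.lam,
                    train_score_sd=sd, degenerate_scores=not sd > 0)


def predict(model: RLSModel, X, feature_names=None) -> np.ndarray:
    """Linear risk scores ``X @ w + b``; higher score = higher predicted risk.

    When ``feature_names`` is given (or ``X`` is a DataFrame) columns are
    aligned to the model by name; a mismatch raises with the offending names.
    """
    if hasattr(X, "columns"):  # DataFrame
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if feature_names is not None:
        missing = [n for n in model.feature_names if n not in feature_names]
        extra = [n for n in feature_names if n not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {missing}, unexpected {extra}")
        order = [feature_names.index(n) for n in model.feature_names]
        X = X[:, order]
    elif X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {len(model.feature_names)}")
    return X @ model.weights + model.intercept_value


def _augmented(X: np.ndarray, lam: float, intercept: bool):
    """Design matrix and penalty diagonal with an unpenalised intercept column."""
    n = X.shape[0]
    if intercept:
        A = np.column_stack([np.ones(n), X])
        pen = np.concatenate([[0.0], np.full(X.shape[1], lam)])
    else:
        A = X
        pen = np.full(X.shape[1], lam)
    return A, pen


def _hat_and_scores(X: np.ndarray, y: np.ndarray, lam: float, intercept: bool):
    A, pen = _augmented(X, lam, intercept)
    M = A.T @ A + np.diag(pen)
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular system; use lambda > 0") from exc
    H = A @ Minv @ A.T
    return H, H @ y


def loo_predictions(X, y, config: RLSConfig | None = None) -> np.ndarray:
    """Closed-form leave-one-out predictions via the regularised hat matrix.

    ``loo_i = (score_i - H_ii * y_i) / (1 - H_ii)`` equals the prediction for
    sample i from a model trained without sample i.
    """
    config = config or RLSConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) <= {0.0, 1.0}:
        y = np.where(y > 0, 1.0, -1.0)  # classification convention
    if y.size < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    H, yhat = _hat_and_scores(X, y, config.lam, config.intercept)
    h = np.diag(H)
    if np.any(h >= 1 - 1e-10):
        raise ValueError(
            "leverage H_ii >= 1: system too ill-conditioned for closed-form "
            "LOO; increase lambda")
    return (yhat - h * y) / (1 - h)


def greedy_rls_select(X, y, config: RLSConfig | None = None, k: int = 1,
                      feature_names=None) -> GreedySelection:
    """Greedy forward selection minimising the LOO mean squared error.

    Starting from the empty set (plus the unpenalised intercept when enabled),
    each step adds the feature whose inclusion gives the lowest closed-form
    LOO MSE at the fixed ``config.lam``; ties break to the lowest feature
    index.  Incremental rank-one updates make each step O(n * m * p) while
    remaining exactly equivalent to refitting every candidate model.
    """
    config = config or RLSConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_pm1(y)
    n, p = X.shape
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]; got {k}")
    if config.lam <= 0:
        raise ValueError("greedy selection requires lambda > 0")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    lam = config.lam

    if config.intercept:
        A = np.ones((n, 1))
        Minv = np.array([[1.0 / n]])
        h = np.full(n, 1.0 / n)
        resid = y - y.mean()
    else:
        A = np.empty((n, 0))
        Minv = np.empty((0, 0))
        h = np.zeros(n)
        resid = y.copy()

    remaining = list(range(p))
    chosen: list[int] = []
    path: list[float] = []
    for _ in range(k):
        C = X[:, remaining]                      # n x p_rem candidates
        if A.shape[1]:
            U = A.T @ C                          # m x p_rem
            W = Minv @ U
            R = C - A @ W
        else:
            W = np.empty((0, C.shape[1]))
            R = C
        s = lam + np.einsum("ij,ij->j", C, R)
        rty = R.T @ y
        with np.errstate(divide="ignore", invalid="ignore"):
            resid_new = resid[:, None] - R * (rty / s)[None, :]
            h_new = h[:, None] + R * R / s[None, :]
            loo_resid = resid_new / (1.0 - h_new)
            mse = np.mean(loo_resid ** 2, axis=0)
        mse = np.where(np.isfinite(mse) & (s > 1e-12), mse, np.inf)
        j = int(np.argmin(mse))                  # first occurrence = lowest index
        feat = remaining[j]
        r, sj, wj = R[:, j].copy(), float(s[j]), W[:, j].copy()
        # block-inverse update of (A'A + penalty)^-1 for the augmented column
        m = Minv.shape[0]
        Mnew = np.empty((m + 1, m + 1))
        Mnew[:m, :m] = Minv + np.outer(wj, wj) / sj
        Mnew[:m, m] = -wj / sj
        Mnew[m, :m] = -wj / sj
        Mnew[m, m] = 1.0 / sj
        Minv = Mnew
        A = np.column_stack([A, X[:, feat]])
        h = h + r * r / sj
        resid = resid - r * (float(rty[j]) / sj)
        chosen.append(feat)
        remaining.pop(j)
        path.append(float(mse[j]))
    return GreedySelection(
        ordered_features=[feature_names[i] for i in chosen],
        ordered_indices=chosen,
        criterion_path=path,
        lam=lam,
    )


@dataclass
class PanelSweep:
    k_values: np.ndarray
    mean_auc: np.ndarray
    rep_auc: np.ndarray          # repetitions x k
    best_k: int                  # smallest k within one SE of the maximum


def sweep_panel_size(X, y, config: RLSConfig, k_max: int, cv_plan,
                     ) -> PanelSweep:
    """Cross-validated AUC of the k-feature greedy panel for k = 1..k_max.

    Selection is repeated inside each training fold; AUC per k is computed
    from the pooled out-of-fold scores of each repetition.  ``cv_plan`` is a
    :class:`metarisk.crossval.CVPlan` (its ``outer_folds``, ``repetitions``
    and ``seed`` are used).
    """
    from .crossval import stratified_folds  # local import avoids a cycle
    from .evaluation import auc as _auc

    X = np.asarray(X, dtype=float)
    y = _as_pm1(y)
    y01 = (y > 0).astype(int)
    n = y.size
    if not 1 <= k_max <= X.shape[1]:
        raise ValueError(f"k_max must be in [1, {X.shape[1]}]")
    rep_auc = np.empty((cv_plan.repetitions, k_max))
    for r in range(cv_plan.repetitions):
        folds = stratified_folds(y01, cv_plan.outer_folds, cv_plan.seed + r)
        scores = np.empty((n, k_max))
        for f in range(cv_plan.outer_folds):
            te = folds == f
            tr = ~te
            sel = greedy_rls_select(X[tr], y[tr], config, k_max)
            for k in range(1, k_max + 1):
                cols = sel.ordered_indices[:k]
                model = fit_rls(X[tr][:, cols], y[tr], config)
                scores[te, k - 1] = X[te][:, cols] @ model.weights + model.intercept_value
        for k in range(k_max):
            rep_auc[r, k] = _auc(scores[:, k], y01)
    mean_auc = rep_auc.mean(axis=0)
    k_star = int(np.argmax(mean_auc))
    if cv_plan.repetitions > 1:
        se = float(rep_auc[:, k_star].std(ddof=1) / np.sqrt(cv_plan.repetitions))
    else:
        se = 0.0
    within = np.flatnonzero(mean_auc >= mean_auc[k_star] - se)
    return PanelSweep(k_values=np.arange(1, k_max + 1), mean_auc=mean_auc,
                      rep_auc=rep_auc, best_k=int(within[0] + 1))
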