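"""Repeated nested stratified cross-validation.

The outer folds estimate prediction performance; the inner folds (run only on
outer-training samples) pick the ridge penalty from the grid; greedy marker
selection, when enabled, runs on outer-training data only.  Each repetition
draws a fresh stratified split from its own seed (``plan.seed + r``) so any
repetition is reproducible in isolation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, design_matrix
from .rls import RLSConfig, RLSModel, fit_rls, greedy_rls_select
from .evaluation import auc as _auc

__all__ = [
    "CVPlan",
    "NestedCVResult",
    "MarkerPanel",
    "ValidationResult",
    "stratified_folds",
    "nested_cv",
    "panel_union",
    "external_validation",
]


@dataclass(frozen=True)
class CVPlan:
    outer_folds: int = 10
    inner_folds: int = 10
    repetitions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def stratified_folds(outcome, n_folds: int, seed) -> np.ndarray:
    """Stratified fold ids: within each class, fold sizes differ by <= 1.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  The partition
    is exhaustive and disjoint.  ``n_folds == n_samples`` yields a
    leave-one-out partition; otherwise ``n_folds`` may not exceed the minority
    class count.
    """
    y = np.asarray(outcome).ravel()
    n = y.size
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds sample count {n}")
    if n_folds != n and n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds minority class count {counts.min()}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if n_folds == n:  # leave-one-out partition
        return rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        start = int(rng.integers(n_folds))  # rotate so no fold is always larger
        folds[idx] = (np.arange(idx.size) + start) % n_folds
    return folds


def _center(X_tr, y_tr, X_te, intercept: bool):
    if intercept:
        mu, ybar = X_tr.mean(axis=0), y_tr.mean()
        return X_tr - mu, y_tr - ybar, X_te - mu, float(ybar)
    return X_tr, y_tr, X_te, 0.0


def _ridge_sweep_scores(X_tr, y_tr, X_te, grid, intercept: bool) -> np.ndarray:
    """Test scores for every penalty on the grid from one eigendecomposition.

    Uses the primal (p <= n) or dual (p > n) formulation, whichever gives the
    smaller eigenproblem.  Returns an (n_te, n_lambda) array.
    """
    Xc, yc, Xtc, ybar = _center(X_tr, y_tr, X_te, intercept)
    grid = np.asarray(grid, dtype=float)
    n, p = Xc.shape
    if p <= n:
        e, V = np.linalg.eigh(Xc.T @ Xc)
        b = V.T @ (Xc.T @ yc)
        coef = b[:, None] / (e[:, None] + grid[None, :])
        return (Xtc @ V) @ coef + ybar
    e, V = np.linalg.eigh(Xc @ Xc.T)
    b = V.T @ yc
    alpha = b[:, None] / (e[:, None] + grid[None, :])
    return (Xtc @ Xc.T @ V) @ alpha + ybar


def _select_lambda(X, y01, grid, n_folds, rng, intercept: bool,
                   criterion: str = "auc") -> float:
    """Inner-CV penalty choice: grid value maximising pooled out-of-fold AUC
    (or minimising squared error); ties resolve to the smallest penalty."""
    y_pm = np.where(y01 > 0, 1.0, -1.0)
    folds = stratified_folds(y01, n_folds, rng)
    oof = np.empty((y01.size, len(grid)))
    for f in range(n_folds):
        te = folds == f
        oof[te] = _ridge_sweep_scores(X[~te], y_pm[~te], X[te], grid, intercept)
    if criterion == "auc":
        quality = np.array([_auc(oof[:, j], y01) for j in range(len(grid))])
        best = int(np.argmax(quality))  # first occurrence = smallest lambda
    elif criterion == "mse":
        err = np.mean((y_pm[:, None] - oof) ** 2, axis=0)
        best = int(np.argmin(err))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return float(grid[best])


def _modal_lambda(lams) -> float:
    counts = Counter(lams)
    top = max(counts.values())
    return min(lam for lam, c in counts.items() if c == top)


@dataclass
class NestedCVResult:
    model_spec: str
    sample_ids: list
    outcome: np.ndarray
    feature_names: list
    scores: np.ndarray            # repetitions x n out-of-fold scores
    fold_assignments: np.ndarray  # repetitions x n
    fold_lambdas: np.ndarray      # repetitions x outer_folds
    aucs: np.ndarray              # per-repetition pooled-OOF AUC
    selections: list | None = None
    select_k: int | None = None
    selection_scope: str | None = None

    def mean_scores(self) -> np.ndarray:
        """Per-sample out-of-fold score averaged over repetitions."""
        return self.scores.mean(axis=0)

    def scores_frame(self) -> pd.DataFrame:
        reps, n = self.scores.shape
        return pd.DataFrame({
            "sample_id": np.tile(self.sample_ids, reps),
            "repetition": np.repeat(np.arange(reps), n),
            "fold": self.fold_assignments.ravel(),
            "score": self.scores.ravel(),
        })

    def to_json(self) -> dict:
        return {
            "model_spec": self.model_spec,
            "sample_ids": list(self.sample_ids),
            "outcome": np.asarray(self.outcome).astype(int).tolist(),
            "feature_names": list(self.feature_names),
            "scores": self.scores.tolist(),
            "fold_assignments": self.fold_assignments.tolist(),
            "fold_lambdas": self.fold_lambdas.tolist(),
            "aucs": self.aucs.tolist(),
            "selections": self.selections,
            "select_k": self.select_k,
            "selection_scope": self.selection_scope,
        }

    @classmethod
    def from_json(cls, payload) -> "NestedCVResult":
        return cls(
            model_spec=payload["model_spec"],
            sample_ids=payload["sample_ids"],
            outcome=np.asarray(payload["outcome"], dtype=int),
            feature_names=payload["feature_names"],
            scores=np.asarray(payload["scores"], dtype=float),
            fold_assignments=np.asarray(payload["fold_assignments"], dtype=int),
            fold_lambdas=np.asarray(payload["fold_lambdas"], dtype=float),
            aucs=np.asarray(payload["aucs"], dtype=float),
            selections=payload.get("selections"),
            select_k=payload.get("select_k"),
            selection_scope=payload.get("selection_scope"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def load(cls, path) -> "NestedCVResult":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def nested_cv(table: CohortTable, feature_set, config: RLSConfig,
              plan: CVPlan, select_k: int | None = None,
              selection_scope: str = "full", criterion: str = "auc",
              model_spec: str = "custom",
              fold_standardise: bool = False) -> NestedCVResult:
    """Repeated nested stratified cross-validation of an RLS model.

    Per repetition: a fresh stratified outer split; per outer fold the inner
    CV picks the grid penalty maximising pooled inner out-of-fold AUC, greedy
    selection (when ``select_k`` is set) runs on the outer-training data only,
    the model is refit on the outer-training set, and the outer-test samples
    are scored.  The per-repetition AUC comes from the pooled out-of-fold
    scores.

    When selection is enabled the reported per-repetition feature list is
    greedy selection with the repetition's modal penalty run on
    ``selection_scope``: ``"full"`` (entire cohort; default) or
    ``"outer-union"`` (union of the per-outer-fold selections).
    """
    if selection_scope not in ("full", "outer-union"):
        raise ValueError(f"unknown selection_scope {selection_scope!r}")
    X, names = design_matrix(table, feature_set,
                             standardise=not fold_standardise)
    y01 = table.outcome.to_numpy().astype(int)
    y_pm = np.where(y01 > 0, 1.0, -1.0)
    n = y01.size
    grid = np.asarray(config.lambda_grid, dtype=float)

    scores = np.empty((plan.repetitions, n))
    fold_assign = np.empty((plan.repetitions, n), dtype=int)
    fold_lambdas = np.empty((plan.repetitions, plan.outer_folds))
    aucs = np.empty(plan.repetitions)
    selections: list | None = [] if select_k else None

    for r in range(plan.repetitions):
        rng = np.random.default_rng(plan.seed + r)
        folds = stratified_folds(y01, plan.outer_folds, rng)
        fold_assign[r] = folds
        fold_selections = []
        for f in range(plan.outer_folds):
            te = folds == f
            tr = ~te
            X_tr, X_te = X[tr], X[te]
            if fold_standardise:
                mu = X_tr.mean(axis=0)
                sd = X_tr.std(axis=0, ddof=1)
                sd[sd == 0] = 1.0
                X_tr = (X_tr - mu) / sd
                X_te = (X_te - mu) / sd
            lam = _select_lambda(X_tr, y01[tr], grid, plan.inner_folds, rng,
                                 config.intercept, criterion)
            fold_lambdas[r, f] = lam
            fold_cfg = RLSConfig(lam=lam, lambda_grid=config.lambda_grid,
                                 intercept=config.intercept)
            cols = slice(None)
            if select_k:
                sel = greedy_rls_select(X_tr, y_pm[tr], fold_cfg, select_k)
                cols = sel.ordered_indices
                fold_selections.append([names[i] for i in cols])
            model = fit_rls(X_tr[:, cols], y_pm[tr], fold_cfg)
            scores[r, te] = X_te[:, cols] @ model.weights + model.intercept_value
        aucs[r] = _auc(scores[r], y01)
        if select_k:
            lam = _modal_lambda(fold_lambdas[r])
            rep_cfg = RLSConfig(lam=lam, lambda_grid=config.lambda_grid,
                                intercept=config.intercept)
            if selection_scope == "full":
                sel = greedy_rls_select(X, y_pm, rep_cfg, select_k)
                selections.append([names[i] for i in sel.ordered_indices])
            else:
                union: list = []
                for fs in fold_selections:
                    union.extend(f for f in fs if f not in union)
                selections.append(union)

    return NestedCVResult(
        model_spec=model_spec,
        sample_ids=table.sample_ids,
        outcome=y01,
        feature_names=names,
        scores=scores,
        fold_assignments=fold_assign,
        fold_lambdas=fold_lambdas,
        aucs=aucs,
        selections=selections,
        select_k=select_k,
        selection_scope=selection_scope if select_k else None,
    )


@dataclass
class MarkerPanel:
    per_repetition: list
    union: list                    # (feature, selection frequency), sorted

    @property
    def feature_names(self) -> list:
        return [name for name, _ in self.union]

    def to_json(self) -> dict:
        return {"per_repetition": self.per_repetition,
                "union": [[n, f] for n, f in self.union]}

    @classmethod
    def from_json(cls, payload) -> "MarkerPanel":
        return cls(per_repetition=payload["per_repetition"],
                   union=[(n, float(f)) for n, f in payload["union"]])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def panel_union(result: NestedCVResult) -> MarkerPanel:
    """Union of per-repetition selections with selection frequencies."""
    if result.selections is None:
        raise ValueError("selection was not enabled in this run")
    reps = len(result.selections)
    counts: Counter = Counter()
    for sel in result.selections:
        counts.update(set(sel))
    union = sorted(((name, c / reps) for name, c in counts.items()),
                   key=lambda item: (-item[1], item[0]))
    return MarkerPanel(per_repetition=result.selections, union=union)


@dataclass
class ValidationResult:
    scores: np.ndarray
    averaged_model: RLSModel
    rep_lambdas: np.ndarray


def external_validation(train: CohortTable, valid: CohortTable, feature_set,
                        config: RLSConfig, plan: CVPlan) -> ValidationResult:
    """Transfer a marker set to an external cohort by parameter averaging.

    Per repetition one model is trained on the full training cohort (penalty
    chosen by that repetition's inner CV on the full cohort); the
    repetition-wise weights and intercepts are averaged into a single linear
    model which scores the validation samples once.  Validation columns are
    put on the training scale (training mean/SD), so the caller must supply
    the validation cohort imputed but *not* re-standardised to itself.
    """
    feature_set = list(feature_set)
    missing = [f for f in feature_set
               if f not in valid.features.columns
               and f not in valid.covariates.columns]
    if missing:
        raise ValueError(f"features not measured in validation cohort: {missing}")
    X_tr, names = design_matrix(train, feature_set, standardise=False)
    X_va, _ = design_matrix(valid, feature_set, standardise=False)
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("constant training column in feature set")
    X_tr = (X_tr - mu) / sd
    X_va = (X_va - mu) / sd
    y01 = train.outcome.to_numpy().astype(int)
    y_pm = np.where(y01 > 0, 1.0, -1.0)
    grid = np.asarray(config.lambda_grid, dtype=float)

    weights = np.zeros((plan.repetitions, X_tr.shape[1]))
    intercepts = np.zeros(plan.repetitions)
    lams = np.zeros(plan.repetitions)
    for r in range(plan.repetitions):
        rng = np.random.default_rng(plan.seed + r)
        lam = _select_lambda(X_tr, y01, grid, plan.inner_folds, rng,
                             config.intercept)
        model = fit_rls(X_tr, y_pm,
                        RLSConfig(lam=lam, lambda_grid=config.lambda_grid,
                                  intercept=config.intercept), names)
        weights[r] = model.weights
        intercepts[r] = model.intercept_value
        lams[r] = lam

    w_bar = weights.mean(axis=0)
    b_bar = float(intercepts.mean())
    train_scores = X_tr @ w_bar + b_bar
    sd_scores = float(np.std(train_scores, ddof=1))
    averaged = RLSModel(feature_names=names, weights=w_bar,
                        intercept_value=b_bar, lam=float(lams.mean()),
                        train_score_sd=sd_scores,
                        degenerate_scores=not sd_scores > 0)
    return ValidationResult(scores=X_va @ w_bar + b_bar,
                            averaged_model=averaged, rep_lambdas=lams)
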