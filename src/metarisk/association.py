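"""Per-metabolite logistic association screening.

Implements maximum-likelihood logistic regression by iteratively reweighted
least squares with Wald inference, Storey/BH q-values and the baseline
group-comparison tests (Fisher's exact, Welch's t, including the
summary-statistics form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, CohortError

__all__ = [
    "LogisticFit",
    "AssociationResult",
    "ConvergenceError",
    "logistic_fit",
    "feature_association",
    "qvalues",
    "association_screen",
    "screen_frame",
    "baseline_characteristics",
    "welch_from_summary",
]

SEPARATION_COEF_BOUND = 15.0  # |coef| beyond this on standardised data => separation


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separation: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def logistic_fit(predictors, outcome, add_intercept: bool = True,
                 max_iter: int = 100, tol_score: float = 1e-8,
                 tol_loglik: float = 1e-10) -> LogisticFit:
    """Fit a logistic regression by Newton-Raphson (IRLS).

    Converges when ``max |score| < tol_score`` or the relative log-likelihood
    change drops below ``tol_loglik``.  Quasi-complete separation (coefficients
    running away past :data:`SEPARATION_COEF_BOUND` with a still-improving
    likelihood) is flagged on the result rather than raised; genuine
    non-convergence raises :class:`ConvergenceError`.
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(outcome)) == X.shape[1]:
        X = X.T
    y = np.asarray(outcome, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"shape mismatch: {X.shape[0]} rows vs {y.size} outcomes")
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0} or classes.size < 2:
        raise ValueError("outcome must contain both classes coded 0/1")
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
    sd = X.std(axis=0)
    if np.any(sd[1:] == 0) if add_intercept else np.any(sd == 0):
        raise ValueError("constant predictor column besides the intercept")

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    separation = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        w = mu * (1 - mu)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        ll = _loglik(X, y, beta)
        if np.max(np.abs(beta)) > SEPARATION_COEF_BOUND and ll >= ll_old:
            separation = True
            break
        if np.max(np.abs(score)) < tol_score:
            ll_old = ll
            break
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol_loglik * (abs(ll_old) + 1e-12):
            ll_old = ll
            break
        ll_old = ll
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info) if separation else np.linalg.inv(info)
    return LogisticFit(coef=beta, cov=cov, loglik=_loglik(X, y, beta),
                       n_iter=it, converged=not separation,
                       separation=separation)


def _loglik(X, y, beta) -> float:
    eta = X @ beta
    # numerically stable log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class AssociationResult:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float = np.nan
    adjustment_set: tuple = ()
    separation: bool = False
    error: str | None = None

    @property
    def significant(self) -> bool:
        return bool(self.q_value < 0.05)


def feature_association(table: CohortTable, feature: str,
                        adjustment_set=()) -> AssociationResult:
    """Per-SD odds ratio of one feature, optionally covariate-adjusted.

    The feature is assumed standardised so ``exp(coef)`` is a per-SD OR.
    Adjustment covariates must be fully observed (apply
    :func:`metarisk.preprocess.exclude_missing_covariates` first).
    """
    adjustment_set = tuple(adjustment_set)
    if feature not in table.features.columns:
        raise CohortError(f"unknown feature: {feature!r}")
    cols = [table.features[feature].to_numpy(dtype=float)]
    for cov in adjustment_set:
        if cov not in table.covariates.columns:
            raise CohortError(f"unknown covariate: {cov!r}")
        vals = table.covariates[cov].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise CohortError(
                f"covariate {cov!r} has missing values; exclude those samples first")
        cols.append(vals)
    X = np.column_stack(cols)
    if np.isnan(X[:, 0]).any():
        raise CohortError(f"feature {feature!r} has missing values; impute first")
    fit = logistic_fit(X, table.outcome.to_numpy())
    coef, se = fit.coef[1], fit.se[1]
    z = coef / se if se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(z)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return AssociationResult(
        feature=feature,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p_value=p,
        adjustment_set=adjustment_set,
        separation=fit.separation,
    )


def qvalues(p_values, method: str = "storey", lambda_: float = 0.5) -> np.ndarray:
    """FDR q-values from a vector of p-values.

    ``method="storey"`` uses the plug-in null-proportion estimate
    ``pi0 = #{p > lambda} / (m * (1 - lambda))`` at a fixed ``lambda`` (0.5),
    clipped to ``[1/m, 1]``; ``method="bh"`` forces ``pi0 = 1`` which makes
    the result identical to Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        pi0 = np.sum(p > lambda_) / (m * (1 - lambda_))
        pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    else:
        raise ValueError(f"unknown method: {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # step-up monotonisation
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def association_screen(table: CohortTable, adjustment_sets=((),),
                       q_threshold: float = 0.05,
                       q_method: str = "storey") -> dict:
    """Screen every feature against the outcome for each adjustment set.

    Returns a dict mapping each adjustment set (tuple) to a list of
    :class:`AssociationResult`.  Per-feature fit failures are recorded on the
    result (``error`` field) and excluded from the q-value computation; the
    screen continues.
    """
    screens = {}
    for adj in adjustment_sets:
        adj = tuple(adj)
        sub = table
        if adj:
            from .preprocess import exclude_missing_covariates
            sub = exclude_missing_covariates(table, adj)
        results = []
        for name in sub.features.columns:
            try:
                results.append(feature_association(sub, name, adj))
            except (ValueError, CohortError, ConvergenceError) as exc:
                results.append(AssociationResult(
                    feature=name, odds_ratio=np.nan, ci_low=np.nan,
                    ci_high=np.nan, p_value=np.nan, adjustment_set=adj,
                    error=str(exc)))
        ok = [r for r in results if r.error is None]
        if ok:
            q = qvalues([r.p_value for r in ok], method=q_method)
            for r, qv in zip(ok, q):
                r.q_value = float(qv)
        screens[adj] = results
    return screens


def screen_frame(results, q_threshold: float = 0.05) -> pd.DataFrame:
    """Tabulate one screen's results, labelling direction and significance."""
    rows = []
    for r in results:
        direction = ""
        if r.error is None and np.isfinite(r.odds_ratio):
            direction = "positive" if r.odds_ratio > 1 else "negative"
        rows.append({
            "feature": r.feature, "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value, "q_value": r.q_value,
            "significant": bool(r.q_value < q_threshold) if r.error is None else False,
            "direction": direction,
            "adjustment_set": ",".join(r.adjustment_set),
            "separation": r.separation,
            "error": r.error or "",
        })
    frame = pd.DataFrame(rows)
    return frame.sort_values("p_value", kind="stable").reset_index(drop=True)


def welch_from_summary(n1: int, mean1: float, sem1: float,
                       n2: int, mean2: float, sem2: float) -> tuple[float, float]:
    """Welch two-sample t-test from per-group (n, mean, SEM) summaries.

    Returns ``(t, p)`` with Welch-Satterthwaite degrees of freedom.
    """
    res = stats.ttest_ind_from_stats(
        mean1=mean1, std1=sem1 * np.sqrt(n1), nobs1=n1,
        mean2=mean2, std2=sem2 * np.sqrt(n2), nobs2=n2,
        equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _fisher_p(counts: np.ndarray, seed: int, n_draws: int) -> float:
    if counts.shape == (2, 2):
        return float(stats.fisher_exact(counts)[1])
    # r x c exact test by Monte-Carlo over tables with fixed margins:
    # p = P(table at most as probable as the observed one)
    dist = stats.random_table(counts.sum(axis=1), counts.sum(axis=0))
    logp_obs = dist.logpmf(counts)
    rng = np.random.default_rng(seed)
    draws = dist.rvs(n_draws, random_state=rng)
    logp = dist.logpmf(draws)
    return float((np.sum(logp <= logp_obs + 1e-9) + 1) / (n_draws + 1))


def baseline_characteristics(table: CohortTable, variables: dict | None = None,
                             seed: int = 0, n_draws: int = 100_000
                             ) -> pd.DataFrame:
    """Compare covariates between progressors and non-progressors.

    ``variables`` maps covariate name to ``"categorical"`` (Fisher's exact;
    2x2 exact, r x c by seeded Monte-Carlo with ``n_draws`` tables) or
    ``"continuous"`` (Welch's t).  Defaults to treating covariates with <= 5
    distinct observed values as categorical.  Single-level variables are
    skipped with a note.
    """
    y = table.outcome.to_numpy()
    if variables is None:
        variables = {}
        for name in table.covariates.columns:
            nuniq = table.covariates[name].dropna().nunique()
            variables[name] = "categorical" if nuniq <= 5 else "continuous"
    rows = []
    for name, kind in variables.items():
        col = table.covariates[name]
        mask = col.notna().to_numpy()
        vals, grp = col[mask], y[mask]
        row = {"variable": name, "test": None, "statistic": np.nan,
               "p_value": np.nan, "note": ""}
        if vals.nunique() < 2:
            row["note"] = "skipped: single observed level"
        elif kind == "categorical":
            counts = pd.crosstab(vals, grp).to_numpy()
            row["test"] = "fisher"
            row["p_value"] = _fisher_p(counts, seed=seed, n_draws=n_draws)
        elif kind == "continuous":
            a, b = vals[grp == 0], vals[grp == 1]
            res = stats.ttest_ind(b, a, equal_var=False)
            row["test"] = "welch"
            row["statistic"] = float(res.statistic)
            row["p_value"] = float(res.pvalue)
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {name!r}")
        rows.append(row)
    return pd.DataFrame(rows)
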