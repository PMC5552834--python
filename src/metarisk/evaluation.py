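"""Discrimination statistics: ROC/AUC, DeLong inference, risk-probability
conversion, discrimination slope and integrated discrimination improvement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "DeLongComparison",
    "RiskEvalReport",
    "auc",
    "roc_curve",
    "mean_auc_ci",
    "delong_test",
    "delong_ci",
    "risk_probabilities",
    "discrimination_slope",
    "idi",
    "idi_nri_equivalence_check",
    "risk_eval_report",
]


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    vals = set(np.unique(labels))
    if vals <= {-1, 1} and -1 in vals:
        labels = (labels > 0).astype(int)
    if not set(np.unique(labels)) == {0, 1}:
        raise ValueError("labels must contain both classes (0/1)")
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    return scores[labels == 1], scores[labels == 0]


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2."""
    pos, neg = _split(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m = pos.size
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * neg.size))


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float = np.nan
    ci_high: float = np.nan


def roc_curve(scores, labels) -> ROCResult:
    """ROC curve over the unique score thresholds (descending), plus (0,0)."""
    pos, neg = _split(scores, labels)
    scores = np.asarray(scores, dtype=float).ravel()
    labels01 = np.asarray(labels).ravel()
    labels01 = (labels01 > 0).astype(int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels01[order]
    # collapse tied thresholds
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / pos.size]
    fpr = np.r_[0.0, fp / neg.size]
    thresholds = np.r_[np.inf, s[distinct]]
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=area)


def mean_auc_ci(auc_values) -> tuple[float, float, float]:
    """Mean with empirical 2.5th/97.5th percentile bounds."""
    vals = np.asarray(auc_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 AUC values")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(vals.mean()), float(lo), float(hi)


def _structural_components(scores, labels):
    """DeLong V10 (per positive) and V01 (per negative) placement components."""
    pos, neg = _split(scores, labels)
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


def delong_test(scores_a, scores_b, labels) -> DeLongComparison:
    """DeLong's test for two correlated (paired) ROC curves."""
    v10a, v01a = _structural_components(scores_a, labels)
    v10b, v01b = _structural_components(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    var = max(float(var), 0.0)
    diff = auc_a - auc_b
    if var == 0:
        if abs(diff) > 1e-12:
            raise ValueError("zero DeLong variance with unequal AUCs")
        return DeLongComparison(auc_a, auc_b, 0.0, 0.0, 1.0)
    z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongComparison(auc_a, auc_b, var, float(z), min(p, 1.0))


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong-variance Wald interval, truncated to [0, 1]."""
    v10, v01 = _structural_components(scores, labels)
    a = float(v10.mean())
    if v10.size > 1 and v01.size > 1:
        var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    else:
        var = 0.0
    half = stats.norm.ppf(0.5 + level / 2) * np.sqrt(max(var, 0.0))
    return a, float(max(a - half, 0.0)), float(min(a + half, 1.0))


def risk_probabilities(scores, score_sd: float) -> np.ndarray:
    """Map linear risk scores to probabilities: sigmoid(score / SD).

    The map is strictly increasing so ranking statistics (AUC) are unchanged.
    """
    if not score_sd > 0:
        raise ValueError(f"score_sd must be > 0; got {score_sd}")
    scores = np.asarray(scores, dtype=float)
    return 1.0 / (1.0 + np.exp(-scores / score_sd))


def discrimination_slope(probabilities, labels) -> float:
    """Mean risk probability in progressors minus that in non-progressors."""
    pos, neg = _split(probabilities, labels)
    return float(pos.mean() - neg.mean())


def idi(ds_new: float, ds_old: float) -> float:
    """Integrated discrimination improvement as % improvement in DS."""
    if ds_old == 0:
        raise ValueError("reference discrimination slope is 0")
    return 100.0 * (ds_new - ds_old) / ds_old


def idi_nri_equivalence_check(probabilities_old, probabilities_new, labels,
                              grid_size: int = 10_000) -> tuple[float, float]:
    """Absolute IDI vs the cut-off-integrated net reclassification improvement.

    ``idi_direct = DS_new - DS_old``; ``nri_integral`` averages
    ``dTPR(c) - dFPR(c)`` over a uniform midpoint grid of probability
    cut-offs ``c``; the two agree as the grid is refined.
    """
    p_old = np.asarray(probabilities_old, dtype=float)
    p_new = np.asarray(probabilities_new, dtype=float)
    labels = np.asarray(labels).ravel()
    idi_direct = (discrimination_slope(p_new, labels)
                  - discrimination_slope(p_old, labels))
    # number of midpoint cut-offs (i + 0.5)/G strictly below p equals
    # ceil(p * G - 0.5) clipped to [0, G]
    def frac_above(p):
        return np.clip(np.ceil(p * grid_size - 0.5), 0, grid_size) / grid_size

    case = labels == 1
    d_tpr = frac_above(p_new[case]).mean() - frac_above(p_old[case]).mean()
    d_fpr = frac_above(p_new[~case]).mean() - frac_above(p_old[~case]).mean()
    return float(idi_direct), float(d_tpr - d_fpr)


@dataclass
class RiskEvalReport:
    model_name: str
    reference_name: str
    ds_model: float
    ds_reference: float
    idi_percent: float
    mean_prob_progressors: float
    mean_prob_non_progressors: float
    delong: DeLongComparison | None = None

    def to_json(self) -> dict:
        payload = {
            "model": self.model_name,
            "reference": self.reference_name,
            "ds_model": self.ds_model,
            "ds_reference": self.ds_reference,
            "idi_percent": self.idi_percent,
            "mean_prob_progressors": self.mean_prob_progressors,
            "mean_prob_non_progressors": self.mean_prob_non_progressors,
        }
        if self.delong is not None:
            payload["delong"] = {
                "auc_model": self.delong.auc_a,
                "auc_reference": self.delong.auc_b,
                "z": self.delong.z,
                "p_value": self.delong.p_value,
            }
        return payload


def risk_eval_report(model_name, scores, sd, reference_name, ref_scores,
                     ref_sd, labels) -> RiskEvalReport:
    """DS/IDI/DeLong comparison of a model against a reference on paired scores."""
    probs = risk_probabilities(scores, sd)
    ref_probs = risk_probabilities(ref_scores, ref_sd)
    ds_model = discrimination_slope(probs, labels)
    ds_ref = discrimination_slope(ref_probs, labels)
    pos, neg = _split(probs, labels)
    return RiskEvalReport(
        model_name=model_name,
        reference_name=reference_name,
        ds_model=ds_model,
        ds_reference=ds_ref,
        idi_percent=idi(ds_model, ds_ref),
        mean_prob_progressors=float(pos.mean()),
        mean_prob_non_progressors=float(neg.mean()),
        delong=delong_test(scores, ref_scores, labels),
    )
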