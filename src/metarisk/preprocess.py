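"""Data preparation: minimum imputation, standardisation, panel merging and
covariate-missingness exclusion."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, CohortError

__all__ = [
    "StandardisationParams",
    "impute_minimum",
    "standardise",
    "apply_standardisation",
    "merge_panels",
    "exclude_missing_covariates",
]


@dataclass
class StandardisationParams:
    """Per-feature location/scale learned on a training cohort."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0][0]
            raise ValueError(f"non-positive SD for feature {bad!r}")

    def to_json(self) -> dict:
        return {"mean": self.mean.to_dict(), "sd": self.sd.to_dict()}

    @classmethod
    def from_json(cls, payload) -> "StandardisationParams":
        return cls(mean=pd.Series(payload["mean"], dtype=float),
                   sd=pd.Series(payload["sd"], dtype=float))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "StandardisationParams":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def impute_minimum(table: CohortTable) -> CohortTable:
    """Replace each feature's missing cells by its minimum observed value."""
    features = table.features.copy()
    for name in features.columns:
        col = features[name]
        if col.isna().all():
            raise ValueError(f"feature {name!r} has no observed values")
        if col.isna().any():
            features[name] = col.fillna(col.min())
    return table.with_features(features)


def standardise(table: CohortTable,
                ) -> tuple[CohortTable, StandardisationParams]:
    """Scale every feature to zero mean and unit sample SD (n-1 denominator).

    Requires imputation to have been applied; raises on remaining missing
    values or constant features.
    """
    features = table.features
    if features.isna().any().any():
        bad = features.columns[features.isna().any()][0]
        raise ValueError(f"feature {bad!r} still has missing values; impute first")
    mean = features.mean()
    sd = features.std(ddof=1)
    if (sd <= 0).any():
        bad = sd.index[sd <= 0][0]
        raise ValueError(f"feature {bad!r} is constant; SD undefined")
    params = StandardisationParams(mean=mean, sd=sd)
    return table.with_features((features - mean) / sd), params


def apply_standardisation(table: CohortTable,
                          params: StandardisationParams) -> CohortTable:
    """Apply previously learned location/scale to (e.g. external) data."""
    missing = [n for n in table.features.columns if n not in params.mean.index]
    if missing:
        raise ValueError(f"no standardisation parameters for features: {missing}")
    mean = params.mean[table.features.columns]
    sd = params.sd[table.features.columns]
    return table.with_features((table.features - mean) / sd)


def merge_panels(targeted: CohortTable, untargeted: CohortTable) -> CohortTable:
    """Column-concatenate two panels measured on the same samples.

    Covariates and outcome are taken from the first table.
    """
    a, b = targeted.features.index, untargeted.features.index
    if not a.equals(b):
        differing = next((x, y) for x, y in zip(a, b) if x != y) \
            if len(a) == len(b) else (len(a), len(b))
        raise CohortError(f"sample mismatch between panels: {differing}")
    overlap = set(targeted.features.columns) & set(untargeted.features.columns)
    if overlap:
        raise CohortError(f"duplicate feature name across panels: {sorted(overlap)[0]!r}")
    if untargeted.n_features == 0:
        return targeted.copy()
    features = pd.concat([targeted.features, untargeted.features], axis=1)
    meta = pd.concat([targeted.feature_meta, untargeted.feature_meta], axis=0)
    return CohortTable(
        features=features,
        covariates=targeted.covariates.copy(),
        outcome=targeted.outcome.copy(),
        feature_meta=meta,
    )


def exclude_missing_covariates(table: CohortTable, covariates) -> CohortTable:
    """Keep only samples with all listed covariates observed (per-analysis)."""
    covariates = list(covariates)
    if not covariates:
        return table.copy()
    unknown = [c for c in covariates if c not in table.covariates.columns]
    if unknown:
        raise CohortError(f"unknown covariate names: {unknown}")
    keep = table.covariates[covariates].notna().all(axis=1)
    if not keep.any():
        raise CohortError("no samples remain after covariate exclusion")
    subset = table.features.index[keep]
    retained_outcome = table.outcome.loc[subset]
    if retained_outcome.nunique() < 2:
        raise CohortError("only one outcome class remains after exclusion")
    return table.subset_samples(subset)
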