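"""Cohort data container shared by every stage of the pipeline.

A :class:`CohortTable` bundles the samples x features intensity matrix with
the clinical covariate table, the binary progression outcome and per-feature
metadata.  Missing values are encoded as ``NaN`` in both the feature matrix
and the covariate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "design_matrix"]


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class CohortTable:
    """Samples x features matrix plus covariates, outcome and feature metadata.

    Attributes
    ----------
    features:
        ``DataFrame`` indexed by sample id, one float column per feature.
        ``NaN`` marks a missing measurement.
    covariates:
        ``DataFrame`` indexed by sample id. Continuous covariates are floats,
        categorical ones are numerically encoded (e.g. 0/1). ``NaN`` missing.
    outcome:
        Integer ``Series`` (0 = non-progressor, 1 = progressor), same index.
    feature_meta:
        ``DataFrame`` indexed by feature name with columns ``panel``
        (``"targeted"`` | ``"untargeted"``) and ``identified`` (``"yes"`` |
        ``"no"``).
    """

    features: pd.DataFrame
    covariates: pd.DataFrame
    outcome: pd.Series
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(
                {"panel": "untargeted", "identified": "yes"},
                index=self.features.columns,
            )
        self.feature_meta.index.name = "feature"
        self.features.columns.name = "feature"
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.features)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            dup = pd.Index(self.sample_ids)
            name = dup[dup.duplicated()][0]
            raise CohortError(f"duplicate sample id: {name!r}")
        if len(self.covariates) != n or len(self.outcome) != n:
            raise CohortError(
                f"row mismatch: {n} feature rows, {len(self.covariates)} "
                f"covariate rows, {len(self.outcome)} outcome values"
            )
        if not (self.covariates.index.equals(self.features.index)
                and self.outcome.index.equals(self.features.index)):
            raise CohortError("sample ids differ between tables")
        if self.features.columns.duplicated().any():
            name = self.features.columns[self.features.columns.duplicated()][0]
            raise CohortError(f"duplicate feature name: {name!r}")
        values = set(pd.unique(self.outcome.dropna()))
        if not values <= {0, 1}:
            raise CohortError(f"outcome must be binary 0/1, found {sorted(values)}")
        if len(values) < 2:
            raise CohortError("outcome must contain both classes")
        if not self.feature_meta.index.equals(self.features.columns):
            raise CohortError("feature_meta index does not match feature columns")

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.features.index)

    @property
    def feature_names(self) -> list:
        return list(self.features.columns)

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_progressors(self) -> int:
        return int(self.outcome.sum())

    def copy(self) -> "CohortTable":
        return CohortTable(
            features=self.features.copy(),
            covariates=self.covariates.copy(),
            outcome=self.outcome.copy(),
            feature_meta=self.feature_meta.copy(),
        )

    def with_features(self, features: pd.DataFrame,
                      feature_meta: pd.DataFrame | None = None) -> "CohortTable":
        """Return a copy with the feature matrix (and optionally meta) replaced."""
        meta = feature_meta
        if meta is None:
            meta = self.feature_meta.reindex(features.columns)
        return CohortTable(
            features=features,
            covariates=self.covariates.copy(),
            outcome=self.outcome.copy(),
            feature_meta=meta,
        )

    def subset_samples(self, ids) -> "CohortTable":
        return CohortTable(
            features=self.features.loc[ids],
            covariates=self.covariates.loc[ids],
            outcome=self.outcome.loc[ids],
            feature_meta=self.feature_meta.copy(),
        )


def design_matrix(table: CohortTable, names, standardise: bool = True):
    """Assemble a dense model matrix from feature and covariate columns.

    ``names`` may mix metabolite features and (numerically encoded) clinical
    covariates.  Every requested column must be fully observed; the caller is
    expected to have imputed features and excluded samples with missing
    covariates beforehand.  With ``standardise=True`` (default) each column is
    scaled to zero mean / unit sample SD (n-1) so that regularisation treats
    metabolites and covariates on the same per-SD scale.

    Returns ``(X, names)`` with ``X`` a float ndarray of shape
    ``(n_samples, len(names))``.
    """
    names = list(names)
    if not names:
        raise CohortError("empty column list for design matrix")
    cols = []
    for name in names:
        if name in table.features.columns:
            col = table.features[name]
        elif name in table.covariates.columns:
            col = table.covariates[name]
        else:
            raise CohortError(f"unknown feature/covariate name: {name!r}")
        col = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
        if np.isnan(col).any():
            raise CohortError(
                f"column {name!r} has missing values; impute features or "
                "exclude samples with missing covariates first"
            )
        cols.append(col)
    X = np.column_stack(cols)
    if standardise:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            bad = names[int(np.argmin(sd))]
            raise CohortError(f"constant column {bad!r} cannot be standardised")
        X = (X - mu) / sd
    return X, names
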