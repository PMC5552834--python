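"""Cohort TSV/CSV round-tripping.

A cohort is stored as two delimited text files — features and
covariates+outcome — plus an optional JSON sidecar carrying the generating
config and feature metadata.  Missing values are written as empty fields;
``NA`` is also accepted on read.  The delimiter is auto-detected from the
file extension (``.csv`` = comma, anything else = tab).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, CohortError

__all__ = ["write_cohort", "read_cohort"]

OUTCOME_COLUMN = "progressor"
_NA_VALUES = ["", "NA"]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_cohort(table: CohortTable, features_path, covariates_path,
                 sidecar_path=None, config=None) -> None:
    table.features.to_csv(features_path, sep=_sep(features_path),
                          index_label="sample_id", na_rep="")
    cov = table.covariates.copy()
    cov[OUTCOME_COLUMN] = table.outcome
    cov.to_csv(covariates_path, sep=_sep(covariates_path),
               index_label="sample_id", na_rep="")
    if sidecar_path is not None:
        payload = {
            "feature_meta": {
                name: {"panel": row["panel"], "identified": row["identified"]}
                for name, row in table.feature_meta.iterrows()
            },
        }
        if config is not None:
            payload["config"] = config.to_json() if hasattr(config, "to_json") \
                else config
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _read_indexed(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_sep(path), index_col=0,
                        na_values=_NA_VALUES, keep_default_na=False)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise CohortError(f"duplicated sample id {dup!r} in {path}")
    return frame


def read_cohort(features_path, covariates_path, sidecar_path=None,
                categorical_maps: dict | None = None) -> CohortTable:
    """Read a cohort written by :func:`write_cohort`.

    ``categorical_maps`` optionally maps covariate name -> {label: code} for
    string-coded categories (e.g. ``{"family_history": {"no": 0, "yes": 1}}``).
    """
    features = _read_indexed(features_path)
    cov = _read_indexed(covariates_path)
    if OUTCOME_COLUMN not in cov.columns:
        raise CohortError(
            f"covariate file {covariates_path} lacks a {OUTCOME_COLUMN!r} column")
    if not features.index.equals(cov.index):
        a, b = set(features.index), set(cov.index)
        odd = sorted(a.symmetric_difference(b))
        raise CohortError(f"sample id mismatch between files: {odd[:5]}")

    for name in features.columns:
        try:
            features[name] = pd.to_numeric(features[name])
        except (ValueError, TypeError) as exc:
            bad = features[name][pd.to_numeric(features[name],
                                               errors="coerce").isna()
                                 & features[name].notna()]
            raise CohortError(
                f"non-numeric value in feature column {name!r}, sample "
                f"{bad.index[0]!r}: {bad.iloc[0]!r}") from exc

    outcome = cov.pop(OUTCOME_COLUMN).astype(int)
    if categorical_maps:
        for name, mapping in categorical_maps.items():
            if name in cov.columns:
                cov[name] = cov[name].map(
                    lambda v, m=mapping: m.get(v, v) if pd.notna(v) else np.nan)
    for name in cov.columns:
        cov[name] = pd.to_numeric(cov[name], errors="coerce") \
            if cov[name].dtype == object else cov[name]

    meta = None
    if sidecar_path is not None and Path(sidecar_path).exists():
        with open(sidecar_path) as fh:
            payload = json.load(fh)
        meta_map = payload.get("feature_meta", {})
        if meta_map:
            meta = pd.DataFrame.from_dict(meta_map, orient="index")
            meta = meta.reindex(features.columns)
            meta["panel"] = meta["panel"].fillna("untargeted")
            meta["identified"] = meta["identified"].fillna("yes")
    return CohortTable(features=features, covariates=cov,
                       outcome=outcome, feature_meta=meta)
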