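"""Pipeline orchestration: config schema, model-spec resolution, stage
execution and report assembly."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, CohortError
from .synthetic import SyntheticConfig, generate_cohort, generate_validation_cohort
from .preprocess import (impute_minimum, standardise, exclude_missing_covariates)
from .association import association_screen, screen_frame
from .rls import RLSConfig
from .crossval import (CVPlan, NestedCVResult, nested_cv, panel_union,
                       external_validation)
from .evaluation import (auc, mean_auc_ci, delong_test, risk_probabilities,
                         discrimination_slope, idi, delong_ci)
from .io import read_cohort, write_cohort

__all__ = [
    "ModelSpec",
    "resolve_model_spec",
    "run_pipeline",
    "benchmark_marker_sets",
    "CLINICAL_REFERENCE",
    "CLINICAL_PLUS_GLUCOSE",
    "CLINICAL_EXTENDED",
]

# default clinical reference covariates; two extended variants
CLINICAL_REFERENCE = ("sex", "age", "bmi", "fasting_insulin", "family_history")
CLINICAL_PLUS_GLUCOSE = CLINICAL_REFERENCE + ("fasting_glucose",)
CLINICAL_EXTENDED = CLINICAL_PLUS_GLUCOSE + (
    "total_cholesterol", "hdl_cholesterol", "triacylglycerols",
    "sbp", "dbp", "waist")

MODEL_NAMES = ("clinical-only", "metabolome-only", "combined",
               "panel-only", "panel+clinical", "custom")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    feature_names: tuple
    covariate_names: tuple

    @property
    def columns(self) -> list:
        return list(self.feature_names) + list(self.covariate_names)

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError(f"model {self.name!r} resolves to an empty feature set")


def resolve_model_spec(name: str, table: CohortTable, panel=None,
                       custom_features=(), custom_covariates=(),
                       clinical=CLINICAL_REFERENCE) -> ModelSpec:
    """Resolve a named model family to concrete cohort columns."""
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
    clinical = tuple(c for c in clinical if c in table.covariates.columns)
    features: tuple = ()
    covariates: tuple = ()
    if name == "clinical-only":
        covariates = clinical
    elif name == "metabolome-only":
        features = tuple(table.feature_names)
    elif name == "combined":
        features = tuple(table.feature_names)
        covariates = clinical
    elif name in ("panel-only", "panel+clinical"):
        if panel is None:
            raise ValueError(f"model {name!r} requires a selected panel")
        features = tuple(panel)
        if name == "panel+clinical":
            covariates = clinical
    else:  # custom
        features = tuple(custom_features)
        covariates = tuple(custom_covariates)
    missing = [c for c in features if c not in table.features.columns]
    missing += [c for c in covariates if c not in table.covariates.columns]
    if missing:
        raise CohortError(f"model {name!r} references unknown columns: {missing}")
    return ModelSpec(name=name, feature_names=features, covariate_names=covariates)


# ---------------------------------------------------------------------------
# config schema

_SCHEMA = {
    "seed": int,
    "outdir": str,
    "synthetic": dict,
    "cohort": dict,
    "association": dict,
    "crossval": dict,
    "selection": dict,
    "models": list,
    "validation": dict,
    "clinical_covariates": list,
}


def _validate_config(cfg: dict) -> dict:
    unknown = sorted(set(cfg) - set(_SCHEMA))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    for key, typ in _SCHEMA.items():
        if key in cfg and not isinstance(cfg[key], typ):
            raise ValueError(f"config key {key!r} must be {typ.__name__}")
    if "synthetic" not in cfg and "cohort" not in cfg:
        raise ValueError("config needs a 'synthetic' or 'cohort' section")
    for model in cfg.get("models", []):
        if model not in MODEL_NAMES:
            raise ValueError(f"unknown model {model!r} in config")
    return cfg


def _plan_from_config(cfg: dict, seed: int) -> CVPlan:
    cv = cfg.get("crossval", {})
    return CVPlan(outer_folds=cv.get("outer_folds", 10),
                  inner_folds=cv.get("inner_folds", 10),
                  repetitions=cv.get("repetitions", 10),
                  seed=cv.get("seed", seed))


def _rls_config(cfg: dict) -> RLSConfig:
    cv = cfg.get("crossval", {})
    grid = cv.get("lambda_grid")
    if grid:
        return RLSConfig(lambda_grid=tuple(sorted(float(g) for g in grid)))
    return RLSConfig()


def _model_comparison(result: NestedCVResult, reference: NestedCVResult) -> dict:
    """AUC summary plus DeLong/DS/IDI against the reference model.

    Paired DeLong/DS use each sample's out-of-fold score averaged over
    repetitions; risk probabilities scale each averaged score vector by its
    own SD before the sigmoid.
    """
    scores = result.mean_scores()
    ref_scores = reference.mean_scores()
    y = result.outcome
    probs = risk_probabilities(scores, float(np.std(scores, ddof=1)))
    ref_probs = risk_probabilities(ref_scores, float(np.std(ref_scores, ddof=1)))
    ds = discrimination_slope(probs, y)
    ds_ref = discrimination_slope(ref_probs, y)
    mean_auc, lo, hi = mean_auc_ci(result.aucs) if result.aucs.size > 1 else (
        float(result.aucs[0]),) * 3
    comparison = delong_test(scores, ref_scores, y)
    return {
        "model": result.model_spec,
        "reference": reference.model_spec,
        "mean_auc": round(mean_auc, 2),
        "auc_ci": [round(lo, 2), round(hi, 2)],
        "delong_p": comparison.p_value,
        "ds": round(ds, 4),
        "ds_reference": round(ds_ref, 4),
        "idi_percent": round(idi(ds, ds_ref), 1),
    }


def benchmark_marker_sets(table: CohortTable, named_sets: dict,
                          config: RLSConfig, plan: CVPlan,
                          clinical=CLINICAL_REFERENCE) -> pd.DataFrame:
    """Nested-CV AUC of each named marker set combined with the clinical
    covariates; unresolvable sets are skipped with a warning row."""
    rows = []
    for name, markers in named_sets.items():
        missing = [m for m in markers if m not in table.features.columns]
        if missing:
            rows.append({"set": name, "mean_auc": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "note": f"skipped: unknown markers {missing}"})
            continue
        spec = resolve_model_spec("custom", table, custom_features=markers,
                                  custom_covariates=clinical)
        result = nested_cv(table, spec.columns, config, plan,
                           model_spec=f"benchmark:{name}")
        if result.aucs.size > 1:
            mean, lo, hi = mean_auc_ci(result.aucs)
        else:
            mean = lo = hi = float(result.aucs[0])
        rows.append({"set": name, "mean_auc": mean, "ci_low": lo,
                     "ci_high": hi, "note": ""})
    return pd.DataFrame(rows, columns=["set", "mean_auc", "ci_low",
                                       "ci_high", "note"])


# ---------------------------------------------------------------------------
# full pipeline


def _load_or_generate(cfg: dict, seed: int) -> tuple[CohortTable, SyntheticConfig | None]:
    if "cohort" in cfg:
        paths = cfg["cohort"]
        table = read_cohort(paths["features"], paths["covariates"],
                            sidecar_path=paths.get("sidecar"))
        return table, None
    syn = dict(cfg.get("synthetic", {}))
    syn.setdefault("seed", seed)
    if "planted_effects" in syn:
        syn["planted_effects"] = [tuple(e) for e in syn["planted_effects"]]
    known = {f.name for f in SyntheticConfig.__dataclass_fields__.values()}
    unknown = sorted(set(syn) - known)
    if unknown:
        raise ValueError(f"unknown synthetic config keys: {unknown}")
    config = SyntheticConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in syn.items()})
    return generate_cohort(config), config


def run_pipeline(config_path, outdir=None) -> dict:
    """Execute the configured stages end to end and write the report bundle.

    Writes association TSV, per-model nested-CV JSON + score TSV, the marker
    panel JSON, a comparison report JSON, a human-readable summary and a run
    log (config hash, seeds, stage wall-times).  Raises before any
    computation on a schema violation; a stage failure preserves the outputs
    written so far.
    """
    with open(config_path) as fh:
        raw = fh.read()
    cfg = _validate_config(yaml.safe_load(raw) or {})
    seed = cfg.get("seed", 0)
    out = Path(outdir or cfg.get("outdir", "metarisk_out"))
    out.mkdir(parents=True, exist_ok=True)
    log = {"config_hash": hashlib.sha256(raw.encode()).hexdigest(),
           "seed": seed, "stages": {}}

    def _stage(name):
        log["stages"][name] = {"start": time.time()}
        return time.time()

    def _done(name, t0, **info):
        log["stages"][name].update(wall_seconds=round(time.time() - t0, 3), **info)
        with open(out / "log.json", "w") as fh:
            json.dump(log, fh, indent=1)

    clinical = tuple(cfg.get("clinical_covariates", CLINICAL_REFERENCE))

    t0 = _stage("cohort")
    table, syn_config = _load_or_generate(cfg, seed)
    write_cohort(table, out / "features.tsv", out / "covariates.tsv",
                 out / "cohort.json", config=syn_config)
    _done("cohort", t0, n_samples=table.n_samples, n_features=table.n_features)

    t0 = _stage("preprocess")
    table = impute_minimum(table)
    table, params = standardise(table)
    clinical_present = tuple(c for c in clinical if c in table.covariates.columns)
    table = exclude_missing_covariates(table, clinical_present)
    params.save(out / "standardisation.json")
    _done("preprocess", t0, n_samples_after_exclusion=table.n_samples)

    t0 = _stage("association")
    assoc_cfg = cfg.get("association", {})
    adjustment_sets = [tuple(s) for s in assoc_cfg.get(
        "adjustment_sets", [[], list(clinical_present)])]
    screens = association_screen(table, adjustment_sets,
                                 q_method=assoc_cfg.get("q_method", "storey"))
    for adj, results in screens.items():
        tag = "unadjusted" if not adj else "adjusted"
        screen_frame(results).to_csv(out / f"association_{tag}.tsv",
                                     sep="\t", index=False)
    _done("association", t0)

    plan = _plan_from_config(cfg, seed)
    rls_config = _rls_config(cfg)
    model_names = cfg.get("models", ["clinical-only", "metabolome-only",
                                     "combined"])
    sel_cfg = cfg.get("selection", {})
    select_k = sel_cfg.get("select_k", 5)

    results: dict[str, NestedCVResult] = {}
    panel = None
    for name in model_names:
        t0 = _stage(f"crossval:{name}")
        if name in ("panel-only", "panel+clinical") and panel is None:
            sel_result = nested_cv(
                table, list(table.feature_names), rls_config, plan,
                select_k=select_k,
                selection_scope=sel_cfg.get("scope", "full"),
                model_spec="selection")
            panel = panel_union(sel_result)
            panel.save(out / "panel.json")
        spec = resolve_model_spec(
            name, table, panel=panel.feature_names if panel else None,
            clinical=clinical_present)
        res = nested_cv(table, spec.columns, rls_config, plan, model_spec=name)
        results[name] = res
        res.save(out / f"nestedcv_{name.replace('+', '_plus_')}.json")
        res.scores_frame().to_csv(
            out / f"scores_{name.replace('+', '_plus_')}.tsv",
            sep="\t", index=False)
        _done(f"crossval:{name}", t0,
              mean_auc=float(np.mean(res.aucs)))

    t0 = _stage("report")
    reference_name = "clinical-only" if "clinical-only" in results \
        else model_names[0]
    reference = results[reference_name]
    report = {"reference": reference_name, "models": []}
    for name, res in results.items():
        if name == reference_name:
            mean, lo, hi = mean_auc_ci(res.aucs) if res.aucs.size > 1 else (
                float(res.aucs[0]),) * 3
            report["models"].append({"model": name, "mean_auc": round(mean, 2),
                                     "auc_ci": [round(lo, 2), round(hi, 2)]})
        else:
            report["models"].append(_model_comparison(res, reference))
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    lines = [f"reference model: {reference_name}"]
    for entry in report["models"]:
        line = (f"{entry['model']:<16} AUC {entry['mean_auc']:.2f} "
                f"(95% CI {entry['auc_ci'][0]:.2f}, {entry['auc_ci'][1]:.2f})")
        if "delong_p" in entry:
            line += (f"  DeLong p={entry['delong_p']:.3g}  DS={entry['ds']:.2f}"
                     f"  IDI={entry['idi_percent']:.1f}%")
        lines.append(line)
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    _done("report", t0)
    return report
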