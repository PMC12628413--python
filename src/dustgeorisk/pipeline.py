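"""Pipeline orchestration: indices -> ecological risk -> health risk ->
statistics -> multivariate -> classifiers, from one config, with
consolidated CSV/JSON reporting.

All numbers are serialized at full precision; display rounding (two
decimals for indices, three significant figures for risks) is applied
only in the human-readable summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import supervised_models as sm
from .data_io import (ConcentrationTable, get_reference_set,
                      load_concentration_table)
from .ecological_risk import eco_risk_report
from .group_statistics import (bartlett_sphericity, descriptives,
                               group_comparison_table, pearson_matrix)
from .health_risk import health_risk_report
from .multivariate import hca, pca_varimax
from .pollution_indices import index_report

log = logging.getLogger("dustgeorisk")


@dataclass
class PipelineConfig:
    input_path: str
    layout: str = "wide"
    background: str = "turekian_wedepohl_shale"
    receptors: tuple[str, ...] = ("child", "adult")
    models: tuple[str, ...] = ("mlr", "dtc", "svm", "plsda")
    seed: int = sm.DEFAULT_SEED
    out_dir: str = "dustgeorisk_out"
    nemerow_denominator: str | int = "n"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("receptors", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return {str(k): _jsonable(v) for k, v in obj.to_dict(orient="index").items()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.to_dict().items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write per-stage CSV plus one consolidated JSON.

    Deterministic given input and seeds.  A stage failure aborts with a
    stage-named error; outputs of completed stages are retained together
    with a manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"config": _jsonable(vars(config))}
    t0 = time.time()

    def stage(name):
        def wrap(fn):
            start = time.time()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.time() - start)
            return result
        return wrap

    table = stage("load")(lambda: load_concentration_table(config.input_path, config.layout))
    if table.n_samples == 0:
        raise RuntimeError("pipeline stage 'load' failed: empty table")
    ref = get_reference_set(config.background)

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path)
        manifest.append(name)

    # --- contamination indices -------------------------------------
    idx = stage("indices")(lambda: index_report(table, ref, config.nemerow_denominator))
    _write("contamination_factor.csv", idx.cf)
    _write("geoaccumulation_index.csv", idx.igeo)
    _write("composite_indices.csv", idx.per_sample)
    _write("composite_indices_groups.csv", idx.group_summary)
    summary["indices"] = {
        "mean_cf": _jsonable(idx.mean_cf),
        "overall": _jsonable(idx.overall),
        "groups": _jsonable(idx.group_summary[["Cdeg", "PLI", "NPI"]]),
    }

    # --- ecological risk -------------------------------------------
    eco = stage("ecorisk")(lambda: eco_risk_report(table, ref))
    _write("ecological_risk.csv", eco.er.assign(RI=eco.ri))
    _write("ecological_risk_summary.csv", eco.summary)
    summary["ecological_risk"] = {
        "ri_mean": float(eco.ri.mean()),
        "ri_max": float(eco.ri.max()),
        "ri_max_sample": str(eco.ri.idxmax()),
        "ri_class_counts": _jsonable(eco.ri_class.value_counts()),
    }

    # --- health risk ------------------------------------------------
    risk = stage("healthrisk")(lambda: health_risk_report(table))
    for receptor in config.receptors:
        _write(f"health_add_{receptor}.csv", risk.adds[receptor])
        _write(f"health_hq_{receptor}.csv", risk.hq[receptor])
        _write(f"health_cr_{receptor}.csv", risk.cr[receptor])
    summary["health_risk"] = {
        r: {
            "max_hi": float(risk.hq[r]["HI"].max()),
            "max_hi_element": str(risk.hq[r]["HI"].idxmax()),
            "max_tcr": float(risk.cr[r]["TCR"].max()),
            "max_tcr_element": str(risk.cr[r]["TCR"].idxmax()),
        }
        for r in config.receptors
    }

    # --- statistics -------------------------------------------------
    desc = stage("stats")(lambda: descriptives(table))
    _write("descriptives.csv", desc)
    comp = stage("stats")(lambda: group_comparison_table(table))
    _write("group_comparisons.csv", comp)
    r, labels = pearson_matrix(table)
    _write("pearson_r.csv", r)
    bart = bartlett_sphericity(table)
    summary["statistics"] = {
        "bartlett": {"chi2": bart.statistic, "df": bart.df[0], "p": bart.p_value},
        "routing": _jsonable(comp[["test", "F", "p_display"]]),
    }

    # --- multivariate ----------------------------------------------
    pca = stage("multivariate")(lambda: pca_varimax(table))
    _write("pca_loadings.csv", pca.loadings)
    summary["multivariate"] = {
        "n_components": pca.n_retained,
        "rotated_ssl": _jsonable(pca.rotated_ssl),
        "explained_pct": _jsonable(pca.explained_pct),
        "cumulative_pct": _jsonable(pca.cumulative_pct),
        "element_clusters_k2": hca(table, "elements").clusters(2),
    }

    # --- supervised models ------------------------------------------
    X, _ = sm.preprocess(table)
    Xraw, _ = sm.preprocess(table, log=False)
    runs = {}
    for model in config.models:
        if model == "mlr":
            runs[model] = stage(model)(lambda: sm.fit_mlr(X, table.groups, seed=config.seed))
        elif model == "dtc":
            runs[model] = stage(model)(lambda: sm.fit_dtc(X, table.groups, seed=config.seed))
        elif model == "svm":
            runs[model] = stage(model)(lambda: sm.fit_svm(X, table.groups, seed=config.seed))
        elif model == "plsda":
            runs[model] = stage(model)(
                lambda: sm.fit_plsda(Xraw, table.groups, n_components=2, seed=config.seed)
            )
        else:
            raise RuntimeError(f"pipeline stage {model!r} failed: unknown model")
    for name, run in runs.items():
        _write(f"confusion_{name}.csv", run.confusion)
        summary.setdefault("classifiers", {})[name] = {
            "accuracy_pct": run.accuracy,
            "validation": run.validation,
            "seed": run.seed,
        }
    if "plsda" in runs:
        summary["classifiers"]["plsda"]["vip"] = _jsonable(runs["plsda"].extras["vip"])
        summary["classifiers"]["plsda"]["x_variance_cum_pct"] = (
            runs["plsda"].extras["x_variance_cum_pct"]
        )
    if "dtc" in runs:
        summary["classifiers"]["dtc"]["relative_importance"] = _jsonable(
            runs["dtc"].extras["relative_importance"]
        )

    (out / "report.json").write_text(json.dumps(_jsonable(summary), indent=1, sort_keys=True))
    manifest.append("report.json")
    # timings live in the manifest, keeping report.json reproducible byte-for-byte
    (out / "manifest.json").write_text(
        json.dumps({"files": manifest, "runtime_s": time.time() - t0}, indent=1)
    )
    return summary
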