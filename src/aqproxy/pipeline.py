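"""End-to-end orchestration: train, impute, report.

``train`` runs preprocessing -> correlation screening -> best-subset
enumeration -> per-class robust bootstrap fits -> QC -> ranking and returns
a :class:`TrainResult` that can be persisted to / reloaded from JSON.
``impute`` applies a trained model set to a (possibly gappy) table in
either traditional (rank-1 only) or adaptive (cascading) mode.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine, imputation, preprocessing, quality
from .core import (
    ALL_CLASSES,
    CandidateModel,
    ClassLabel,
    ConfigError,
    ProxyConfig,
    RankedModelSet,
    TimeTable,
    write_timetable,
)

logger = logging.getLogger("aqproxy.pipeline")


@dataclass
class TrainResult:
    """Everything `train` produced: ranked models, diagnostics, run metadata."""

    config: ProxyConfig
    features: list
    correlations: dict
    ranked: dict                 # ClassLabel -> RankedModelSet
    counts: dict                 # ClassLabel -> {enumerated, accepted, rejected, reasons}
    classes: pd.Series           # ClassLabel per timestamp of the training table
    transformed: TimeTable       # regression-scale table
    hourly: TimeTable            # hourly table before transforms
    seasons: preprocessing.SeasonBoundaries | None = None


def _model_seed(base_seed: int, class_label: ClassLabel, inputs: tuple) -> int:
    """Deterministic, order-independent per-model seed below 2**31."""
    key = f"{base_seed}|{class_label}|{','.join(inputs)}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def fit_class(
    design: pd.DataFrame,
    y: pd.Series,
    skeletons: list[CandidateModel],
    class_label: ClassLabel,
    thresholds,
) -> tuple[RankedModelSet, dict]:
    """Fit, QC, and rank every candidate subset on one class's rows.

    QC (VIF and the Lilliefors residual-normality test) is computed on the
    full-data robust fit; only models that survive are bootstrap-averaged.
    """
    t = thresholds
    fitted: list[CandidateModel] = []
    reasons: dict[str, int] = {}
    for skel in skeletons:
        model = CandidateModel(inputs=skel.inputs)
        cols = list(skel.inputs)
        sub = pd.concat([design[cols], y], axis=1).dropna()
        n = len(sub)
        model.n_fit = n
        if n < t.min_n:
            model.qc.rejected = True
            model.qc.reason = "insufficient data"
        else:
            X, yy = sub[cols], sub.iloc[:, -1]
            try:
                full = engine.fit_robust_ols(X, yy, c=t.tuning_c, min_n=t.min_n)
            except (np.linalg.LinAlgError, ConfigError):
                model.qc.rejected = True
                model.qc.reason = "singular"
            else:
                model.qc = quality.qc_check(
                    full.residuals,
                    X,
                    vif_max=t.vif_max,
                    alpha=t.alpha,
                    mc_reps=t.lilliefors_mc_reps,
                    seed=_model_seed(t.seed, class_label, skel.inputs),
                )
                if not model.qc.rejected:
                    qc = model.qc
                    model = engine.bootstrap_fit(
                        X,
                        yy,
                        reps=t.bootstrap_reps,
                        fraction=t.bootstrap_fraction,
                        seed=_model_seed(t.seed + 1, class_label, skel.inputs),
                        c=t.tuning_c,
                        min_n=t.min_n,
                    )
                    if not model.qc.rejected:  # bootstrap itself may reject
                        model.qc = qc
        if model.rejected:
            reasons[model.qc.reason] = reasons.get(model.qc.reason, 0) + 1
        fitted.append(model)
    ranked = quality.rank_models(fitted, class_label, adjr2_decimals=t.adjr2_decimals)
    counts = {
        "enumerated": len(skeletons),
        "accepted": len(ranked.models),
        "rejected": len(skeletons) - len(ranked.models),
        "reasons": reasons,
    }
    logger.info(
        "class %s: %d enumerated, %d accepted, %d rejected %s",
        class_label, counts["enumerated"], counts["accepted"],
        counts["rejected"], reasons,
    )
    return ranked, counts


def preprocess(table: TimeTable, config: ProxyConfig):
    """Hourly averaging, transforms, and the season x daytype class map."""
    hourly = preprocessing.resample_hourly(table)
    transformed = preprocessing.apply_transforms(hourly, config.specs)
    temp_name = config.temperature_variable
    if temp_name not in hourly.frame.columns:
        raise ConfigError(
            f"temperature variable {temp_name!r} not in table; "
            "season classification impossible"
        )
    daily_temp = hourly.frame[temp_name].resample("1D").mean()
    seasons = preprocessing.fit_thermal_seasons(
        daily_temp, span_days=config.thresholds.lowess_span_days
    )
    classes = preprocessing.assign_classes(transformed, seasons, config.holidays)
    return hourly, transformed, seasons, classes


def train(table: TimeTable, config: ProxyConfig) -> TrainResult:
    """Run the full model-development stage on a raw table."""
    t = config.thresholds
    hourly, transformed, seasons, classes = preprocess(table, config)
    candidates = preprocessing.transformed_candidate_names(config.specs)
    candidates = [c for c in candidates if c in transformed.frame.columns]
    corr = engine.correlation_table(
        transformed, config.output, candidates, min_overlap=t.min_overlap
    )
    features = engine.select_features(
        transformed, config.output, candidates, r_min=t.r_min, min_overlap=t.min_overlap
    )
    skeletons = engine.enumerate_models(features, max_inputs=t.max_inputs)
    y = transformed.frame[config.output]
    ranked: dict = {}
    counts: dict = {}
    for cls in ALL_CLASSES:
        mask = (classes == cls).to_numpy()
        if not mask.any():
            continue
        design_cls = transformed.frame.loc[mask, features]
        ranked[cls], counts[cls] = fit_class(
            design_cls, y[mask], skeletons, cls, t
        )
    return TrainResult(
        config=config,
        features=features,
        correlations={k: float(v) for k, v in corr.items()},
        ranked=ranked,
        counts=counts,
        classes=classes,
        transformed=transformed,
        hourly=hourly,
        seasons=seasons,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_models(result: TrainResult, out_dir) -> Path:
    """Persist ranked model sets + run metadata as JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "output": result.config.output,
        "features": list(result.features),
        "thresholds": vars(result.config.thresholds).copy(),
        "correlations": result.correlations,
        "classes": {
            str(cls): result.ranked[cls].to_dict() for cls in result.ranked
        },
        "counts": {
            str(cls): result.counts[cls] for cls in result.counts
        },
    }
    path = out / "models.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_models(path) -> tuple[dict, dict]:
    """Reload ranked model sets; returns (ranked dict, metadata dict)."""
    p = Path(path)
    if p.is_dir():
        p = p / "models.json"
    payload = json.loads(p.read_text())
    ranked = {
        ClassLabel.parse(key): RankedModelSet.from_dict(d)
        for key, d in payload["classes"].items()
    }
    meta = {k: v for k, v in payload.items() if k != "classes"}
    return ranked, meta


def build_report(result: TrainResult, top_k: int = 10) -> dict:
    """Per-class report: counts, top-K models with coefficients and QC."""
    report = {
        "output": result.config.output,
        "features": list(result.features),
        "thresholds": vars(result.config.thresholds).copy(),
        "classes": {},
    }
    for cls, rset in result.ranked.items():
        rows = []
        for rank, m in enumerate(rset.models[:top_k], start=1):
            rows.append(
                {
                    "rank": rank,
                    "inputs": list(m.inputs),
                    "intercept": m.intercept,
                    "coefficients": m.coefficients,
                    "std_errors": m.std_errors,
                    "p_values": m.p_values,
                    "model_p": m.model_p,
                    "n_fit": m.n_fit,
                    **{k: m.attributes[k] for k in ("adjR2", "MAE", "RMSE")},
                    "max_vif": m.qc.max_vif,
                    "lilliefors_p": m.qc.lilliefors_p,
                }
            )
        report["classes"][str(cls)] = {
            **result.counts[cls],
            "top_models": rows,
        }
    return report


# ---------------------------------------------------------------------------
# Imputation stage
# ---------------------------------------------------------------------------

def impute(
    table: TimeTable,
    config: ProxyConfig,
    ranked: dict,
    mode: str = "adaptive",
):
    """Fill the output variable of a raw table with a trained model set.

    Returns ``(filled_table, records, usage, coverage)`` where
    ``filled_table`` carries the filled output plus ``source`` /
    ``model_rank`` / ``class`` provenance columns.
    """
    if mode not in ("adaptive", "traditional"):
        raise ConfigError(f"unknown imputation mode {mode!r}")
    hourly, transformed, seasons, classes = preprocess(table, config)
    output_raw = hourly.frame[config.output]
    max_rank = 1 if mode == "traditional" else None
    filled, records = imputation.cascade_impute(
        output_raw, transformed.frame, ranked, classes, max_rank=max_rank
    )
    usage = imputation.rank_usage(records, classes)
    cov = imputation.coverage(filled)

    out = pd.DataFrame(index=filled.index)
    out[config.output] = filled
    out["source"] = [r.source for r in records]
    out["model_rank"] = [
        r.model_rank if r.model_rank is not None else np.nan for r in records
    ]
    out["class"] = [str(c) for c in classes]
    return out, records, usage, cov


def write_filled(filled_frame: pd.DataFrame, path) -> None:
    """Write the filled series with provenance columns as CSV."""
    out = filled_frame.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False, na_rep="")
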