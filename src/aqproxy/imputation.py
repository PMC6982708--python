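"""Cascading gap-filler and its diagnostics.

Measured values pass through verbatim; each missing output slot is filled
by the highest-ranked accepted model of its class whose inputs are all
present at that timestamp, exponentiating the log-scale linear predictor
back to the concentration scale. Slots no model can serve stay missing and
are reported, not raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CandidateModel, ClassLabel, ImputationRecord, RankedModelSet, TimeTable

logger = logging.getLogger("aqproxy.imputation")

RANK_BUCKETS = ("1", "2", "3-10", ">10", "unfilled")


@dataclass
class RankUsageSummary:
    """Per class, the fraction of originally-missing slots served per rank bucket."""

    per_class: dict = field(default_factory=dict)  # ClassLabel -> {bucket: fraction}

    def to_frame(self) -> pd.DataFrame:
        rows = {
            str(cls): {b: fr.get(b, 0.0) for b in RANK_BUCKETS}
            for cls, fr in self.per_class.items()
        }
        return pd.DataFrame(rows).T.fillna(0.0)


@dataclass
class DiurnalProfile:
    """Hourly mean and standard deviation of a series within one class."""

    class_label: ClassLabel
    mean: pd.Series = field(default_factory=pd.Series)  # index 0..23
    std: pd.Series = field(default_factory=pd.Series)

    @property
    def peak_hour(self) -> int:
        return int(self.mean.idxmax())


def predict(model: CandidateModel, row: dict | pd.Series) -> float:
    """Back-transformed prediction exp(beta0 + sum beta_i X_i) for one row.

    Inputs must already be on their transformed scale. Any missing input
    yields ``nan`` — the "infeasible" signal, not an exception.
    """
    total = model.intercept
    for name in model.inputs:
        x = row.get(name) if isinstance(row, dict) else row.get(name, np.nan)
        if x is None or not np.isfinite(x):
            return float("nan")
        total += model.coefficients[name] * x
    return float(np.exp(total))


def _feasibility(design: pd.DataFrame, model: CandidateModel) -> pd.Series:
    return design[list(model.inputs)].notna().all(axis=1)


def _batch_predict(design: pd.DataFrame, model: CandidateModel, mask) -> np.ndarray:
    X = design.loc[mask, list(model.inputs)].to_numpy(dtype=float)
    b = np.array([model.coefficients[nm] for nm in model.inputs])
    return np.exp(model.intercept + X @ b)


def cascade_impute(
    output: pd.Series,
    design: pd.DataFrame | TimeTable,
    ranked: dict[ClassLabel, RankedModelSet],
    classes: pd.Series,
    max_rank: int | None = None,
) -> tuple[pd.Series, list[ImputationRecord]]:
    """Fill every fillable gap by cascading down the per-class ranking.

    Parameters
    ----------
    output : pandas.Series
        The measured target on its original (concentration) scale; missing
        slots are the gaps to fill.
    design : DataFrame or TimeTable
        Predictor columns on the transformed (fitting) scale, aligned to
        ``output``.
    ranked : dict
        A :class:`RankedModelSet` per class present in ``classes``.
    classes : pandas.Series of ClassLabel
        Class of each timestamp.
    max_rank : int, optional
        Restrict the cascade to the first ``max_rank`` models (1 reproduces
        the traditional single-best-model proxy).

    Returns the filled series and one :class:`ImputationRecord` per slot.
    """
    if isinstance(design, TimeTable):
        design = design.frame
    filled = output.copy().astype(float)
    source = pd.Series(
        np.where(output.notna(), "measured", "unfilled"), index=output.index
    )
    rank_used = pd.Series(np.nan, index=output.index)
    inputs_used: dict[pd.Timestamp, tuple] = {}

    for cls in classes.unique():
        if cls not in ranked:
            raise KeyError(f"class {cls} present in data but absent in model set")
        cls_mask = (classes == cls).to_numpy()
        remaining = output.isna().to_numpy() & cls_mask
        models = ranked[cls].models
        if max_rank is not None:
            models = models[:max_rank]
        for rank, model in enumerate(models, start=1):
            if not remaining.any():
                break
            feasible = remaining & _feasibility(design, model).to_numpy()
            if not feasible.any():
                continue
            filled.iloc[feasible] = _batch_predict(design, model, feasible)
            source.iloc[feasible] = "model"
            rank_used.iloc[feasible] = rank
            for ts in output.index[feasible]:
                inputs_used[ts] = model.inputs
            remaining &= ~feasible

    records = [
        ImputationRecord(
            timestamp=ts,
            value=float(filled.loc[ts]) if np.isfinite(filled.loc[ts]) else float("nan"),
            source=source.loc[ts],
            model_rank=int(rank_used.loc[ts]) if np.isfinite(rank_used.loc[ts]) else None,
            model_inputs=inputs_used.get(ts, ()),
        )
        for ts in output.index
    ]
    n_unfilled = int((source == "unfilled").sum())
    if n_unfilled:
        logger.info("%d slots could not be served by any accepted model", n_unfilled)
    return filled, records


def traditional_impute(
    output: pd.Series,
    design: pd.DataFrame | TimeTable,
    ranked: dict[ClassLabel, RankedModelSet],
    classes: pd.Series,
) -> tuple[pd.Series, float]:
    """Rank-1-only imputation and its coverage fraction.

    Coverage is (measured + filled) / total slots — the availability the
    single best model per class can provide.
    """
    filled, _ = cascade_impute(output, design, ranked, classes, max_rank=1)
    coverage = float(filled.notna().mean())
    return filled, coverage


def coverage(filled: pd.Series) -> float:
    """Fraction of non-missing slots in a (possibly partially) filled series."""
    return float(filled.notna().mean())


def _bucket(rank: int | None) -> str:
    if rank is None:
        return "unfilled"
    if rank == 1:
        return "1"
    if rank == 2:
        return "2"
    if rank <= 10:
        return "3-10"
    return ">10"


def rank_usage(
    records: list[ImputationRecord], classes: pd.Series
) -> RankUsageSummary:
    """Bucket fractions {1, 2, 3-10, >10, unfilled} per class.

    Fractions are over the originally-missing slots of that class (imputed
    plus unfilled) and sum to 1.
    """
    per_class: dict = {}
    by_ts = {r.timestamp: r for r in records}
    for cls in classes.unique():
        ts_in_class = classes.index[(classes == cls).to_numpy()]
        recs = [by_ts[t] for t in ts_in_class if by_ts[t].source != "measured"]
        if not recs:
            per_class[cls] = {}
            continue
        counts: dict[str, int] = {}
        for r in recs:
            b = _bucket(r.model_rank)
            counts[b] = counts.get(b, 0) + 1
        total = len(recs)
        per_class[cls] = {b: c / total for b, c in counts.items()}
    return RankUsageSummary(per_class=per_class)


def diurnal_profile(
    series: pd.Series, classes: pd.Series, class_label: ClassLabel
) -> DiurnalProfile:
    """Per-hour mean and standard deviation over all timestamps of a class."""
    mask = (classes == class_label).to_numpy()
    sub = series[mask]
    grouped = sub.groupby(sub.index.hour)
    mean = grouped.mean().reindex(range(24))
    std = grouped.std(ddof=0).reindex(range(24))
    return DiurnalProfile(class_label=class_label, mean=mean, std=std)
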