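"""Model rejection, evaluation attributes, and ranking.

A candidate model is rejected when any input's variance inflation factor
reaches the threshold (default 5), when the Lilliefors test finds its
residuals significantly non-normal (p < alpha), or when the fit itself
failed. Accepted models are ranked by adjusted R-squared (descending,
compared at a configurable rounding granularity), then MAE, then RMSE,
then the number of fitted rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .core import CandidateModel, ClassLabel, ConfigError, QCReport, RankedModelSet

logger = logging.getLogger("aqproxy.quality")


def vif(X: pd.DataFrame) -> dict:
    """Variance inflation factor per design column: 1 / (1 - R_p^2).

    Each column is regressed (unweighted least squares, with intercept) on
    the remaining columns; a single-column design has VIF = 1 by definition
    and exact collinearity reports +inf.
    """
    cols = list(X.columns)
    if len(cols) == 1:
        return {cols[0]: 1.0}
    Xv = X.to_numpy(dtype=float)
    out = {}
    n = Xv.shape[0]
    ones = np.ones((n, 1))
    for j, name in enumerate(cols):
        yj = Xv[:, j]
        others = np.delete(Xv, j, axis=1)
        D = np.hstack([ones, others])
        beta, *_ = np.linalg.lstsq(D, yj, rcond=None)
        resid = yj - D @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot <= 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def lilliefors_statistic(sample: np.ndarray) -> float:
    """Sup distance between the ECDF of the z-scored sample and the normal CDF."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ConfigError("zero-variance sample: Lilliefors degenerate")
    z = (x - x.mean()) / sd
    cdf = stats.norm.cdf(z)
    k = np.arange(1, n + 1)
    d_plus = np.max(k / n - cdf)
    d_minus = np.max(cdf - (k - 1) / n)
    return float(max(d_plus, d_minus))


def lilliefors(
    residuals: np.ndarray,
    alpha: float = 0.05,
    mc_reps: int = 0,
    seed: int = 0,
) -> tuple[float, float]:
    """Normality test with estimated mean and variance.

    With ``mc_reps > 0`` the p-value is Monte Carlo: the same statistic on
    ``mc_reps`` seeded standard-normal samples of the same size, with the
    add-one correction ``(1 + #{D_null >= D}) / (mc_reps + 1)``. With
    ``mc_reps = 0`` the fast table approximation is used instead.
    Requires n >= 8; zero-variance residuals are degenerate (fatal).
    """
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ConfigError(f"Lilliefors needs n >= 8, got {x.size}")
    stat = lilliefors_statistic(x)
    if mc_reps and mc_reps > 0:
        rng = np.random.default_rng(seed)
        null = rng.standard_normal((mc_reps, x.size))
        means = null.mean(axis=1, keepdims=True)
        sds = null.std(axis=1, ddof=1, keepdims=True)
        z = np.sort((null - means) / sds, axis=1)
        cdf = stats.norm.cdf(z)
        k = np.arange(1, x.size + 1)
        d_plus = (k / x.size - cdf).max(axis=1)
        d_minus = (cdf - (k - 1) / x.size).max(axis=1)
        d_null = np.maximum(d_plus, d_minus)
        p = float((1 + np.sum(d_null >= stat)) / (mc_reps + 1))
    else:
        _, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
        p = float(p)
    return stat, p


def evaluate(y: np.ndarray, yhat: np.ndarray, p: int) -> dict:
    """Evaluation attributes on the fitting (log) scale.

    adjR2 is the correlation-based form
    ``1 - (1 - corr(y, yhat)^2) * (N - 1) / (N - p - 1)``; MAE and RMSE are
    the usual absolute and quadratic means of the residuals, and the signed
    mean error is reported alongside.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    mask = np.isfinite(y) & np.isfinite(yhat)
    y, yhat = y[mask], yhat[mask]
    n = y.size
    if n < p + 2:
        raise ConfigError(f"evaluate needs >= p+2 complete pairs, got {n}")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ConfigError("constant series: adjR2 undefined")
    r = np.corrcoef(y, yhat)[0, 1]
    adj_r2 = 1.0 - (1.0 - r * r) * (n - 1) / (n - p - 1)
    err = y - yhat
    return {
        "adjR2": float(adj_r2),
        "MAE": float(np.abs(err).mean()),
        "RMSE": float(np.sqrt((err * err).mean())),
        "mean_error": float(err.mean()),
    }


def qc_check(
    fit_residuals: np.ndarray,
    X: pd.DataFrame,
    vif_max: float = 5.0,
    alpha: float = 0.05,
    mc_reps: int = 0,
    seed: int = 0,
) -> QCReport:
    """Combined rejection decision for one fitted model."""
    report = QCReport(vif_per_input=vif(X))
    if report.max_vif >= vif_max:
        report.rejected = True
        report.reason = f"max VIF {report.max_vif:.3g} >= {vif_max:g}"
        return report
    try:
        stat, p = lilliefors(fit_residuals, alpha=alpha, mc_reps=mc_reps, seed=seed)
    except ConfigError as exc:
        report.rejected = True
        report.reason = f"lilliefors degenerate: {exc}"
        return report
    report.lilliefors_stat = stat
    report.lilliefors_p = p
    if p < alpha:
        report.rejected = True
        report.reason = f"residuals non-normal (lilliefors p={p:.4g} < {alpha:g})"
    return report


def rank_models(
    models: list[CandidateModel],
    class_label: ClassLabel,
    adjr2_decimals: int = 2,
) -> RankedModelSet:
    """Order accepted models: adjR2 desc (rounded), MAE asc, RMSE asc, n desc.

    Remaining ties break on lexicographic input names, making the ranking a
    total order, deterministic under any input permutation. An empty
    accepted set is fatal for the class.
    """
    accepted = [m for m in models if not m.rejected]
    if not accepted:
        raise ConfigError(f"class {class_label}: no accepted models")

    def key(m: CandidateModel):
        a = m.attributes
        return (
            -round(a["adjR2"], adjr2_decimals),
            a["MAE"],
            a["RMSE"],
            -m.n_fit,
            m.inputs,
        )

    ordered = sorted(accepted, key=key)
    return RankedModelSet(
        class_label=class_label,
        models=ordered,
        ranking_criteria={
            "order": ["adjR2 desc", "MAE asc", "RMSE asc", "n_fit desc", "inputs"],
            "adjr2_decimals": adjr2_decimals,
        },
    )
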