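"""Feature screening, best-subset enumeration, robust fitting, bootstrap.

The regression core: every subset of 1..max_inputs screened predictors is
fitted to the log-scale response by iteratively reweighted least squares
with the Tukey bisquare weight (tuning constant c = 4.685), standardizing
residuals by a median-absolute-deviation scale and the leverage adjustment
``sqrt(1 - h_i)``. Final coefficients are arithmetic means over five random
80% subsets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CandidateModel, ConfigError, TimeTable

logger = logging.getLogger("aqproxy.engine")

MAX_ITER = 50
COEF_TOL = 1e-6


@dataclass
class RobustFitResult:
    """Converged state of one robust least-squares fit."""

    intercept: float
    coefficients: dict
    std_errors: dict
    p_values: dict
    model_p: float
    residuals: np.ndarray
    final_weights: np.ndarray
    scale: float
    leverages: np.ndarray
    iterations: int
    converged: bool
    n: int
    names: tuple = ()
    intercept_se: float = np.nan
    intercept_p: float = np.nan

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.intercept] + [self.coefficients[k] for k in self.names])


def pearson_r(x: pd.Series, y: pd.Series, min_overlap: int = 24) -> float:
    """Product-moment correlation over pairwise-complete rows.

    Returns ``nan`` (the distinct "undefined" signal) when fewer than
    ``min_overlap`` complete pairs exist or either series is constant.
    """
    mask = x.notna() & y.notna()
    n = int(mask.sum())
    if n < max(min_overlap, 2):
        return float("nan")
    xv = x[mask].to_numpy(dtype=float)
    yv = y[mask].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    return float((xc * yc).sum() / denom)


def correlation_table(
    table: TimeTable, output: str, candidates: list[str], min_overlap: int = 24
) -> pd.Series:
    """|R| of every candidate with the (transformed) output, descending."""
    y = table.frame[output]
    rs = {}
    for name in candidates:
        if name == output or name not in table.frame.columns:
            continue
        rs[name] = pearson_r(table.frame[name], y, min_overlap=min_overlap)
    ser = pd.Series(rs, dtype=float)
    return ser.abs().sort_values(ascending=False, kind="stable")


def select_features(
    table: TimeTable,
    output: str,
    candidates: list[str],
    r_min: float = 0.1,
    min_overlap: int = 24,
) -> list[str]:
    """Keep candidates with |R| >= r_min against the transformed output.

    Sorted by |R| descending, ties broken alphabetically. Zero survivors is
    fatal (the full correlation table is included in the error).
    """
    tab = correlation_table(table, output, candidates, min_overlap=min_overlap)
    order = sorted(
        ((name, r) for name, r in tab.items() if np.isfinite(r) and abs(r) >= r_min),
        key=lambda kv: (-abs(kv[1]), kv[0]),
    )
    selected = [name for name, _ in order]
    if not selected:
        raise ConfigError(
            f"no candidate reached |R| >= {r_min}; correlations:\n{tab.to_string()}"
        )
    logger.info("selected %d/%d candidates", len(selected), len(tab))
    return selected


def enumerate_models(features: list[str], max_inputs: int = 3) -> list[CandidateModel]:
    """All input subsets of size 1..max_inputs, in (size, lexicographic) order."""
    if not features:
        raise ConfigError("cannot enumerate models from an empty feature list")
    skeletons = []
    for k in range(1, min(max_inputs, len(features)) + 1):
        for combo in itertools.combinations(sorted(features), k):
            skeletons.append(CandidateModel(inputs=combo))
    return skeletons


def _hat_diagonal(X: np.ndarray) -> np.ndarray:
    """Leverages h_i of the (unweighted) design, clipped to [0, 1)."""
    q, _ = np.linalg.qr(X)
    h = (q * q).sum(axis=1)
    return np.clip(h, 0.0, 1.0 - 1e-10)


def _mad_scale(e: np.ndarray) -> float:
    """Robust residual scale: median(|e - median(e)|) / 0.6745."""
    return float(np.median(np.abs(e - np.median(e))) / 0.6745)


def bisquare_weight(r: np.ndarray, c: float = 4.685) -> np.ndarray:
    """Tukey bisquare weight: (1 - (r/c)^2)^2 for |r| <= c, else 0."""
    r = np.asarray(r, dtype=float)
    u = r / c
    w = np.where(np.abs(u) <= 1.0, (1.0 - u**2) ** 2, 0.0)
    return w


def _bisquare_psi(r: np.ndarray, c: float) -> np.ndarray:
    """Bisquare influence function psi(r) = r * w(r)."""
    return np.asarray(r, dtype=float) * bisquare_weight(r, c)


def _bisquare_dpsi(r: np.ndarray, c: float) -> np.ndarray:
    """Derivative of the bisquare influence: (1-u^2)(1-5u^2) inside |r|<=c."""
    u = np.asarray(r, dtype=float) / c
    inside = np.abs(u) <= 1.0
    return np.where(inside, (1.0 - u**2) * (1.0 - 5.0 * u**2), 0.0)


def _robust_covariance(
    D: np.ndarray, e: np.ndarray, h: np.ndarray, scale: float, c: float
) -> np.ndarray:
    """M-estimator covariance (Street-Carroll-Ruppert form with Huber's
    small-sample correction), the standard robust-regression inference:

        sigma2 = K^2 * s^2 * sum(psi(u)^2) / (n - p') / mean(psi'(u))^2
        cov    = sigma2 * (X'X)^{-1}

    with u the leverage-adjusted standardized residuals. In the no-outlier
    limit (all weights 1) this reduces to the classical OLS covariance.
    """
    n, pprime = D.shape
    u = e / (scale * np.sqrt(1.0 - h))
    psi = _bisquare_psi(u, c)
    dpsi = _bisquare_dpsi(u, c)
    m_dpsi = dpsi.mean()
    if m_dpsi <= 0:
        m_dpsi = np.finfo(float).tiny
    K = 1.0 + pprime / n * dpsi.var() / m_dpsi**2
    sigma2 = (
        K**2 * scale**2 * float((psi**2).sum()) / max(n - pprime, 1) / m_dpsi**2
    )
    try:
        xtx_inv = np.linalg.inv(D.T @ D)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(D.T @ D)
    return sigma2 * xtx_inv


def fit_robust_ols(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    c: float = 4.685,
    min_n: int = 30,
) -> RobustFitResult:
    """Robust linear fit by IRLS with Tukey bisquare weights.

    Starts from the unweighted least-squares fit. Each iteration computes
    residuals, a MAD/0.6745 scale, standardized adjusted residuals
    ``r_i = e_i / (s * sqrt(1 - h_i))`` with leverages from the design,
    then bisquare weights and a weighted refit, until the maximum relative
    coefficient change falls below 1e-6 or 50 iterations.

    Standard errors use the Street-Carroll-Ruppert M-estimator covariance
    with Huber's small-sample correction (the classical OLS covariance in
    the no-outlier limit); p-values from a t reference with ``N - p - 1``
    degrees of freedom; the model-level p-value from the weighted
    regression F test.
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = tuple(f"x{i + 1}" for i in range(Xv.shape[1]))
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n < max(min_n, p + 2):
        raise ConfigError(f"insufficient data: n={n} < min_n={min_n}")

    D = np.column_stack([np.ones(n), Xv])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError("singular design")
    h = _hat_diagonal(D)
    beta, *_ = np.linalg.lstsq(D, yv, rcond=None)

    w = np.ones(n)
    scale = np.nan
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        e = yv - D @ beta
        scale = _mad_scale(e)
        if scale <= np.finfo(float).eps * max(1.0, float(np.abs(yv).max())):
            # (near-)perfect fit: nothing left to reweight
            w = np.ones(n)
            converged = True
            break
        r = e / (scale * np.sqrt(1.0 - h))
        w = bisquare_weight(r, c=c)
        if w.sum() < D.shape[1]:
            # Degenerate standardization: a gross-outlier start can shift
            # median(e) so far that the centered MAD zeroes every weight.
            # Rescale this iteration by the uncentered MAD, which bounds the
            # standardized residuals of the majority.
            wide = float(np.median(np.abs(e)) / 0.6745)
            if wide > scale:
                scale = wide
                r = e / (scale * np.sqrt(1.0 - h))
                w = bisquare_weight(r, c=c)
        if w.sum() < D.shape[1]:
            raise np.linalg.LinAlgError("all observations downweighted to zero")
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(D * sw[:, None], yv * sw, rcond=None)
        delta = np.max(np.abs(beta_new - beta) / np.maximum(1.0, np.abs(beta_new)))
        beta = beta_new
        if delta < COEF_TOL:
            converged = True
            break
    if not converged:
        logger.warning("IRLS did not converge in %d iterations", MAX_ITER)

    e = yv - D @ beta
    dof = n - p - 1
    if scale > 0 and np.isfinite(scale):
        cov = _robust_covariance(D, e, h, scale, c)
    else:
        # zero-residual fit: classical covariance (which is ~0 anyway)
        sigma2 = float((e * e).sum() / max(dof, 1))
        cov = sigma2 * np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=max(dof, 1))

    # model-level F test on the weighted fit
    wmean = float((w * yv).sum() / w.sum())
    ss_res = float((w * e * e).sum())
    ss_tot = float((w * (yv - wmean) ** 2).sum())
    if p > 0 and ss_tot > ss_res and dof > 0:
        f = ((ss_tot - ss_res) / p) / (ss_res / dof)
        model_p = float(stats.f.sf(f, p, dof))
    else:
        model_p = float("nan")

    return RobustFitResult(
        intercept=float(beta[0]),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        std_errors={nm: float(s) for nm, s in zip(names, se[1:])},
        p_values={nm: float(pv) for nm, pv in zip(names, pvals[1:])},
        model_p=model_p,
        residuals=e,
        final_weights=w,
        scale=scale,
        leverages=h,
        iterations=it,
        converged=converged,
        n=n,
        names=names,
        intercept_se=float(se[0]),
        intercept_p=float(pvals[0]),
    )


def bootstrap_fit(
    X: pd.DataFrame,
    y: pd.Series,
    reps: int = 5,
    fraction: float = 0.8,
    seed: int = 0,
    c: float = 4.685,
    min_n: int = 30,
) -> CandidateModel:
    """Average robust fits over random row-subsamples.

    ``reps`` independent subsets of ``ceil(fraction * N)`` rows are drawn
    without replacement (independently, not as a partition); a robust fit
    runs on each; the returned coefficients, standard errors, and evaluation
    attributes are arithmetic means across subsets, with per-subset records
    retained for dispersion reporting. ``fraction = 1`` reduces to a single
    full-data fit per subset.
    """
    from .quality import evaluate  # local import to avoid a cycle

    names = tuple(X.columns)
    n = len(X)
    rng = np.random.default_rng(seed)
    size = int(np.ceil(fraction * n))
    subsets = []
    model = CandidateModel(inputs=names)
    for rep in range(reps):
        if fraction >= 1.0:
            idx = np.arange(n)
        else:
            idx = rng.choice(n, size=size, replace=False)
        if size < min_n:
            logger.warning("bootstrap subset %d below min_n, skipped", rep)
            continue
        Xs, ys = X.iloc[idx], y.iloc[idx]
        try:
            fit = fit_robust_ols(Xs, ys, c=c, min_n=min_n)
        except (np.linalg.LinAlgError, ConfigError) as exc:
            logger.warning("bootstrap subset %d failed: %s", rep, exc)
            continue
        yhat = fit.intercept + Xs.to_numpy() @ fit.beta[1:]
        attrs = evaluate(ys.to_numpy(), yhat, p=len(names))
        subsets.append(
            {
                "intercept": fit.intercept,
                "coefficients": fit.coefficients,
                "std_errors": fit.std_errors,
                "p_values": fit.p_values,
                "model_p": fit.model_p,
                "n": fit.n,
                "attributes": attrs,
                "converged": fit.converged,
            }
        )
    if not subsets:
        model.qc.rejected = True
        model.qc.reason = "insufficient data"
        return model

    def _mean(key):
        return float(np.mean([s[key] for s in subsets]))

    def _mean_map(key):
        return {
            nm: float(np.mean([s[key][nm] for s in subsets])) for nm in names
        }

    model.intercept = _mean("intercept")
    model.coefficients = _mean_map("coefficients")
    model.std_errors = _mean_map("std_errors")
    model.p_values = _mean_map("p_values")
    model.model_p = _mean("model_p")
    model.n_fit = n
    model.attributes = {
        k: float(np.mean([s["attributes"][k] for s in subsets]))
        for k in subsets[0]["attributes"]
    }
    model.subsets = subsets
    return model
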