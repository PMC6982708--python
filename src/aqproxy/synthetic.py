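"""Synthetic hourly air-quality data with the structure the method assumes.

Predictors are exponentiated correlated Gaussian processes with additive
harmonic (diurnal/weekly) mean structure on the log scale, so that the log
transform exactly normalizes them; the output is a log-linear function of a
known input subset plus Gaussian noise. A daily-sinusoid temperature drives
the thermal-season classification and a uniform angular wind direction
exercises the trigonometric decomposition. Gaps are missing-at-random
contiguous blocks whose starts are independent of the masked values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigError, TimeTable, VariableSpec

DEFAULT_PREDICTORS = (
    "acc_mode", "nox", "traffic", "ldsa", "no2",
    "co", "o3", "pm25", "pm10", "wspeed",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic record.

    Defaults emulate a two-year hourly urban record: ten log-normal
    pollutant-like predictors with exchangeable log-scale correlation 0.4,
    diurnal + weekly harmonics on the traffic-like variables, a true
    three-input log-linear output model with noise sd 0.25 (giving an
    adjusted R-squared near 0.9 for the true model), an annual temperature
    sinusoid crossing both season thresholds, and MAR block gaps: 30% on
    the output, 15% on predictors.
    """

    start: str = "2017-01-01"
    end: str = "2018-12-31"
    predictors: tuple = DEFAULT_PREDICTORS
    output: str = "bc"
    true_inputs: tuple = ("acc_mode", "nox", "traffic")
    intercept: float = -0.5
    true_coefficients: tuple = (0.5, 0.3, 0.2)
    noise_sd: float = 0.25
    correlation: float | np.ndarray = 0.4
    diurnal_amplitude: float = 0.6   # log scale, traffic-like predictors
    weekly_amplitude: float = 0.2
    temperature_mean: float = 5.0
    temperature_amplitude: float = 12.0
    temperature_phase_day: int = 28  # day-of-year of the annual minimum
    temperature_noise_sd: float = 2.0
    gap_spec: dict = field(default_factory=dict)  # name -> (block_len, fraction)
    output_gap: tuple = (72, 0.30)
    predictor_gap: tuple = (48, 0.15)
    seed: int = 0

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    def correlation_matrix(self) -> np.ndarray:
        k = self.n_predictors
        if np.isscalar(self.correlation):
            corr = np.full((k, k), float(self.correlation))
            np.fill_diagonal(corr, 1.0)
        else:
            corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ConfigError("correlation matrix must be symmetric k x k")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ConfigError("correlation matrix must be positive definite")
        return corr

    def variable_specs(self) -> list[VariableSpec]:
        specs = [VariableSpec(self.output, role="output", transform="log")]
        for name in self.predictors:
            specs.append(VariableSpec(name, role="candidate", transform="log"))
        specs.append(VariableSpec("temp", role="candidate", transform="identity"))
        specs.append(VariableSpec("wdir", role="candidate", transform="wind_direction"))
        return specs


def _harmonic_mean_structure(cfg: GeneratorConfig, hours: pd.DatetimeIndex) -> np.ndarray:
    """Log-scale additive diurnal + weekly cycles, phased per predictor."""
    h = hours.hour.to_numpy(dtype=float)
    dow = hours.dayofweek.to_numpy(dtype=float) + h / 24.0
    mu = np.zeros((len(hours), cfg.n_predictors))
    for j in range(cfg.n_predictors):
        phase = 2 * np.pi * j / max(cfg.n_predictors, 1)
        mu[:, j] = cfg.diurnal_amplitude * np.sin(2 * np.pi * (h - 8) / 24 + phase)
        mu[:, j] += cfg.weekly_amplitude * np.cos(2 * np.pi * dow / 7 + phase)
    return mu


def generate(cfg: GeneratorConfig) -> tuple[TimeTable, TimeTable]:
    """Generate an hourly table and its pre-masking truth table.

    Returns ``(table, truth)``: identical except that ``table`` carries the
    MAR block gaps of ``cfg.gap_spec`` (defaulting to ``output_gap`` on the
    output and ``predictor_gap`` on every predictor).
    """
    rng = np.random.default_rng(cfg.seed)
    hours = pd.date_range(cfg.start, pd.Timestamp(cfg.end) + pd.Timedelta(hours=23), freq="1h")
    n = len(hours)
    corr = cfg.correlation_matrix()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, cfg.n_predictors)) @ chol.T
    log_x = _harmonic_mean_structure(cfg, hours) + z

    if len(cfg.true_inputs) != len(cfg.true_coefficients):
        raise ConfigError("true_inputs and true_coefficients must align")
    pred_index = {name: j for j, name in enumerate(cfg.predictors)}
    log_y = np.full(n, cfg.intercept)
    for name, beta in zip(cfg.true_inputs, cfg.true_coefficients):
        log_y += beta * log_x[:, pred_index[name]]
    log_y += cfg.noise_sd * rng.standard_normal(n)

    doy = hours.dayofyear.to_numpy(dtype=float) + hours.hour.to_numpy() / 24.0
    temp = (
        cfg.temperature_mean
        - cfg.temperature_amplitude * np.cos(2 * np.pi * (doy - cfg.temperature_phase_day) / 365.25)
        + cfg.temperature_noise_sd * rng.standard_normal(n)
    )
    wdir = rng.uniform(0.0, 360.0, size=n)

    frame = pd.DataFrame(np.exp(log_x), index=hours, columns=list(cfg.predictors))
    frame[cfg.output] = np.exp(log_y)
    frame["temp"] = temp
    frame["wdir"] = wdir
    truth = TimeTable(frame.copy(), meta={"generator": "aqproxy.synthetic"})

    gap_spec = dict(cfg.gap_spec)
    if not gap_spec:
        gap_spec[cfg.output] = cfg.output_gap
        for name in cfg.predictors:
            gap_spec[name] = cfg.predictor_gap
    table = inject_mar_gaps(truth, gap_spec, seed=int(rng.integers(2**31)))
    return table, truth


def inject_mar_gaps(table: TimeTable, gap_spec: dict, seed: int = 0) -> TimeTable:
    """Mask contiguous blocks per variable, independent of the values (MAR).

    ``gap_spec`` maps variable name to ``(block_length, missing_fraction)``;
    block starts are drawn uniformly (independently of the data) until the
    realized missing fraction reaches the request, so for series of 1000+
    points the realized fraction lands within about two percent.
    """
    out = table.copy()
    rng = np.random.default_rng(seed)
    n = len(out)
    for name, (block_len, fraction) in gap_spec.items():
        if not 0 <= fraction < 1:
            raise ConfigError(f"{name}: missing fraction must be in [0, 1)")
        if fraction == 0 or name not in out.frame.columns:
            continue
        target = int(round(fraction * n))
        mask = np.zeros(n, dtype=bool)
        # cap the loop defensively; overlaps make each draw add <= block_len
        for _ in range(100 * max(1, target // max(block_len, 1))):
            if mask.sum() >= target:
                break
            start = int(rng.integers(0, max(n - block_len, 1)))
            mask[start : start + block_len] = True
        col = out.frame[name].to_numpy(dtype=float)
        col[mask] = np.nan
        out.frame[name] = col
    return out
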