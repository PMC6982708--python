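"""Domain types, delimited-text I/O, and configuration parsing.

The universal in/out currency of the package is the :class:`TimeTable`:
a timestamped multivariate numeric table with explicit missing values
(``NaN``), a declared timezone label carried as metadata, and strictly
increasing, duplicate-free timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("aqproxy")

SEASONS = ("winter", "spring", "summer", "autumn")
DAYTYPES = ("workday", "weekend")
TRANSFORMS = ("log", "identity", "wind_direction")
ROLES = ("output", "candidate", "excluded")

DEFAULT_MISSING_MARKERS = ("", "NA", "NaN", "nan")


class ConfigError(ValueError):
    """Raised for invalid configuration or malformed input files."""


@dataclass
class TimeTable:
    """Timestamped multivariate series with explicit missing values.

    Parameters
    ----------
    frame : pandas.DataFrame
        Numeric columns indexed by a strictly increasing, duplicate-free
        :class:`~pandas.DatetimeIndex` (timezone-naive).
    tz_label : str
        Declared timezone of the timestamps, carried as metadata only
        (no conversion logic).
    meta : dict
        Free-form provenance notes.
    """

    frame: pd.DataFrame
    tz_label: str = "UTC+2"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ConfigError("TimeTable requires a DatetimeIndex")
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique()
            raise ConfigError(f"duplicate timestamps: {list(dups[:10])}")
        if not idx.is_monotonic_increasing:
            self.frame = self.frame.sort_index()
        self.frame = self.frame.astype(float)
        self.frame.index.name = "timestamp"

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def copy(self) -> "TimeTable":
        return TimeTable(self.frame.copy(), self.tz_label, dict(self.meta))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class VariableSpec:
    """Role, transform, and units metadata for one variable."""

    name: str
    role: str = "candidate"
    transform: str = "identity"
    units: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"{self.name}: unknown role {self.role!r}")
        if self.transform not in TRANSFORMS:
            raise ConfigError(f"{self.name}: unknown transform {self.transform!r}")


class ClassLabel(NamedTuple):
    """One of the eight season x daytype strata."""

    season: str
    daytype: str

    def __str__(self) -> str:  # used as JSON/report key
        return f"{self.season}/{self.daytype}"

    @classmethod
    def parse(cls, text: str) -> "ClassLabel":
        season, daytype = text.split("/")
        return cls(season, daytype)


ALL_CLASSES = tuple(ClassLabel(s, d) for s in SEASONS for d in DAYTYPES)


@dataclass
class QCReport:
    """Model-rejection diagnostics: multicollinearity and residual normality."""

    vif_per_input: dict = field(default_factory=dict)
    lilliefors_stat: float = np.nan
    lilliefors_p: float = np.nan
    rejected: bool = False
    reason: str = ""

    @property
    def max_vif(self) -> float:
        return max(self.vif_per_input.values(), default=1.0)

    def to_dict(self) -> dict:
        return {
            "vif_per_input": dict(self.vif_per_input),
            "lilliefors_stat": self.lilliefors_stat,
            "lilliefors_p": self.lilliefors_p,
            "rejected": self.rejected,
            "reason": self.reason,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCReport":
        return cls(
            vif_per_input=dict(d.get("vif_per_input", {})),
            lilliefors_stat=d.get("lilliefors_stat", np.nan),
            lilliefors_p=d.get("lilliefors_p", np.nan),
            rejected=d.get("rejected", False),
            reason=d.get("reason", ""),
        )


@dataclass
class CandidateModel:
    """One input-variable subset with fitted coefficients and diagnostics.

    The response is modelled on its transformed (log) scale:
    ``Y = beta0 + sum_i beta_i X_i + eps`` with 1 <= p <= 3 inputs; the
    prediction on the original concentration scale is
    ``exp(beta0 + sum_i beta_i X_i)``.
    """

    inputs: tuple
    intercept: float = np.nan
    coefficients: dict = field(default_factory=dict)
    std_errors: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    model_p: float = np.nan
    n_fit: int = 0
    attributes: dict = field(default_factory=dict)  # adjR2, MAE, RMSE, mean_error
    qc: QCReport = field(default_factory=QCReport)
    subsets: list = field(default_factory=list)  # per-bootstrap-subset records

    def __post_init__(self) -> None:
        self.inputs = tuple(self.inputs)

    @property
    def p(self) -> int:
        return len(self.inputs)

    @property
    def rejected(self) -> bool:
        return self.qc.rejected

    def to_dict(self) -> dict:
        return {
            "inputs": list(self.inputs),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "std_errors": dict(self.std_errors),
            "p_values": dict(self.p_values),
            "model_p": self.model_p,
            "n_fit": int(self.n_fit),
            "attributes": dict(self.attributes),
            "qc": self.qc.to_dict(),
            "subsets": list(self.subsets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CandidateModel":
        return cls(
            inputs=tuple(d["inputs"]),
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            std_errors=dict(d["std_errors"]),
            p_values=dict(d["p_values"]),
            model_p=d.get("model_p", np.nan),
            n_fit=int(d["n_fit"]),
            attributes=dict(d["attributes"]),
            qc=QCReport.from_dict(d.get("qc", {})),
            subsets=list(d.get("subsets", [])),
        )


@dataclass
class RankedModelSet:
    """Accepted models for one class, ordered best (rank 1) to worst."""

    class_label: ClassLabel
    models: list = field(default_factory=list)
    ranking_criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(m.rejected for m in self.models):
            raise ValueError("RankedModelSet must not contain rejected models")

    def __len__(self) -> int:
        return len(self.models)

    def to_dict(self) -> dict:
        return {
            "class_label": str(self.class_label),
            "ranking_criteria": dict(self.ranking_criteria),
            "models": [m.to_dict() for m in self.models],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RankedModelSet":
        return cls(
            class_label=ClassLabel.parse(d["class_label"]),
            models=[CandidateModel.from_dict(m) for m in d["models"]],
            ranking_criteria=dict(d.get("ranking_criteria", {})),
        )


@dataclass(frozen=True)
class ImputationRecord:
    """Per-timestamp provenance of a filled value."""

    timestamp: pd.Timestamp
    value: float
    source: str  # measured | model | unfilled
    model_rank: int | None = None
    model_inputs: tuple = ()

    def __post_init__(self) -> None:
        if self.source == "measured" and self.model_rank is not None:
            raise ValueError("measured records carry no model rank")
        if self.source == "model" and (self.model_rank is None or self.model_rank < 1):
            raise ValueError("model records need a positive rank")


@dataclass
class Thresholds:
    """Tunable screening/fitting/QC settings with their published defaults."""

    r_min: float = 0.1            # minimum |Pearson R| to keep a candidate
    vif_max: float = 5.0          # multicollinearity rejection threshold
    alpha: float = 0.05           # residual-normality rejection level
    max_inputs: int = 3           # best-subset size cap
    bootstrap_reps: int = 5       # number of random subsets
    bootstrap_fraction: float = 0.8
    min_n: int = 30               # minimum complete rows to fit a model
    seed: int = 0
    min_overlap: int = 24         # pairwise-complete rows needed for a correlation
    lowess_span_days: int = 60    # season-smoothing window
    adjr2_decimals: int = 2       # ranking granularity for adjR2 ties
    lilliefors_mc_reps: int = 0   # 0 -> table approximation
    tuning_c: float = 4.685       # Tukey bisquare tuning constant

    def __post_init__(self) -> None:
        if self.max_inputs < 1:
            raise ConfigError("max_inputs must be >= 1")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ConfigError("bootstrap_fraction must be in (0, 1]")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")


@dataclass
class ProxyConfig:
    """Full run configuration: variables, thresholds, calendar, seed."""

    specs: list
    thresholds: Thresholds = field(default_factory=Thresholds)
    holidays: frozenset = field(default_factory=frozenset)
    timestamp_column: str = "timestamp"
    temperature_variable: str = "temp"

    def __post_init__(self) -> None:
        outputs = [s for s in self.specs if s.role == "output"]
        if len(outputs) != 1:
            raise ConfigError(
                f"exactly one output variable required, found {len(outputs)}"
            )

    @property
    def output(self) -> str:
        return next(s.name for s in self.specs if s.role == "output")

    @property
    def candidates(self) -> list[str]:
        return [s.name for s in self.specs if s.role == "candidate"]

    def spec_for(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        return VariableSpec(name=name, role="excluded")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_timetable(
    path,
    config: Sequence[VariableSpec] | None = None,
    missing_markers: Iterable[str] = DEFAULT_MISSING_MARKERS,
    timestamp_column: str = "timestamp",
    tz_label: str = "UTC+2",
) -> TimeTable:
    """Read a CSV with a header row and one timestamp column into a TimeTable.

    Unparseable numeric cells become missing; rows are re-sorted by time.
    Duplicate timestamps and a missing timestamp column are fatal.
    """
    df = pd.read_csv(
        path,
        na_values=list(missing_markers),
        keep_default_na=True,
        skipinitialspace=True,
    )
    if timestamp_column not in df.columns:
        raise ConfigError(
            f"{path}: timestamp column {timestamp_column!r} not found "
            f"(columns: {list(df.columns)})"
        )
    ts = pd.to_datetime(df[timestamp_column], errors="raise")
    data = df.drop(columns=[timestamp_column])
    if config is not None:
        wanted = [s.name for s in config if s.role != "excluded"]
        keep = [c for c in data.columns if c in wanted]
        data = data[keep]
    data = data.apply(pd.to_numeric, errors="coerce")
    data.index = pd.DatetimeIndex(ts)
    if data.index.has_duplicates:
        dups = data.index[data.index.duplicated()].unique()
        raise ConfigError(f"{path}: duplicate timestamps {list(dups[:10])}")
    return TimeTable(data.sort_index(), tz_label=tz_label)


def write_timetable(table: TimeTable, path) -> None:
    """Write a TimeTable as CSV: ISO-8601 timestamps, empty cell for missing."""
    out = table.frame.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_holidays(source=None) -> frozenset:
    """Load a holiday date set from a plain-text list (one ISO date per line).

    ``source`` may be a path, an iterable of date strings/dates, or ``None``
    for the bundled Finnish 2017-2018 list.
    """
    if source is None:
        text = (
            resources.files("aqproxy").joinpath("data/holidays_fi_2017_2018.txt")
        ).read_text()
        lines = text.splitlines()
    elif isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = [str(x) for x in source]
    dates = set()
    for line in lines:
        line = line.split("#", 1)[0].strip()
        if line:
            dates.add(pd.Timestamp(line).date())
    return frozenset(dates)


def load_config(path) -> ProxyConfig:
    """Parse a YAML run configuration.

    Required keys: ``output`` and ``candidates``. Optional: ``transforms``
    (map variable -> log|identity|wind_direction; default log for the output,
    identity otherwise), ``thresholds`` (any Thresholds field), ``holidays``
    (path or inline date list; default bundled Finnish list),
    ``timestamp_column``.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    if "output" not in raw:
        raise ConfigError(f"{path}: no output variable declared")
    transforms = dict(raw.get("transforms", {}))
    output = str(raw["output"])
    specs = [
        VariableSpec(
            name=output,
            role="output",
            transform=transforms.get(output, "log"),
        )
    ]
    for name in raw.get("candidates", []):
        specs.append(
            VariableSpec(
                name=str(name),
                role="candidate",
                transform=transforms.get(str(name), "identity"),
            )
        )
    thresholds = Thresholds(**dict(raw.get("thresholds", {})))
    holidays = load_holidays(raw.get("holidays"))
    return ProxyConfig(
        specs=specs,
        thresholds=thresholds,
        holidays=holidays,
        timestamp_column=str(raw.get("timestamp_column", "timestamp")),
        temperature_variable=str(raw.get("temperature_variable", "temp")),
    )
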