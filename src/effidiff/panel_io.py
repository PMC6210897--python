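"""Panel containers and I/O for efficiency analysis.

Three containers cover the data that flows through the pipeline:

* :class:`IndicatorPanel` — per-unit, per-year input/output indicators
  (the raw material for DEA scoring);
* :class:`EfficiencyPanel` — per-unit, per-year efficiency scores with a
  stage flag (the DEA result, or a transcribed published table);
* :class:`RegionPartition` — a grouping of units into named regions for
  inequality decomposition.

The canonical file layout for indicator panels is long/tidy
(``unit, year, indicator, value``); a wide layout is accepted as a
convenience.  Bundled fixtures expose the published 30-province × 9-year
efficiency panel and the corresponding annual Theil-index series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorPanel",
    "EfficiencyPanel",
    "RegionPartition",
    "PanelValidationError",
    "SchemaError",
    "load_indicator_panel",
    "load_region_partition",
    "load_fixture",
    "list_fixtures",
    "CHINA_THREE_REGION",
]


class PanelValidationError(ValueError):
    """A panel violates a structural invariant (positivity, completeness)."""


class SchemaError(KeyError):
    """A required column is missing from an input table."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class IndicatorPanel:
    """Input/output indicators per unit and year.

    Parameters
    ----------
    unit_ids : list of str
        Decision-making-unit identifiers (e.g. province names).
    years : list of int
        Ordered calendar years.
    input_names, output_names : list of str
        Indicator names; inputs index the last axis of ``X``, outputs of ``Y``.
    X : ndarray, shape (T, n, m)
        Input indicator values per year, unit, indicator. Strictly positive.
    Y : ndarray, shape (T, n, s)
        Output indicator values. Strictly positive (rates such as bed
        utilization are ordinary positive outputs; the slacks-based measure
        is units-invariant so percent vs fraction does not matter).
    """

    unit_ids: list[str]
    years: list[int]
    input_names: list[str]
    output_names: list[str]
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        T, n, m = len(self.years), len(self.unit_ids), len(self.input_names)
        s = len(self.output_names)
        if self.X.shape != (T, n, m) or self.Y.shape != (T, n, s):
            raise PanelValidationError(
                f"shape mismatch: X{self.X.shape} Y{self.Y.shape} vs "
                f"T={T}, n={n}, m={m}, s={s}"
            )
        if m < 1 or s < 1:
            raise PanelValidationError("need at least one input and one output")
        self._check_positive()
        if n < m + s + 1:
            warnings.warn(
                f"only n={n} units for m+s={m + s} indicators; "
                "DEA discrimination may be weak (recommend n >= m+s+1)",
                stacklevel=3,
            )

    def _check_positive(self) -> None:
        for arr, names, kind in ((self.X, self.input_names, "input"),
                                 (self.Y, self.output_names, "output")):
            bad = ~(np.isfinite(arr) & (arr > 0))
            if bad.any():
                t, i, j = (int(v[0]) for v in np.nonzero(bad))
                raise PanelValidationError(
                    f"nonpositive/missing {kind} '{names[j]}' for unit "
                    f"'{self.unit_ids[i]}', year {self.years[t]}: {arr[t, i, j]!r}"
                )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_outputs(self) -> int:
        return len(self.output_names)

    def cross_section(self, year: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` matrices of shape (n, m) and (n, s) for one year."""
        t = self.years.index(year)
        return self.X[t], self.Y[t]

    def to_frame(self) -> pd.DataFrame:
        """Long/tidy representation: unit, year, indicator, value."""
        rows = []
        for t, year in enumerate(self.years):
            for i, unit in enumerate(self.unit_ids):
                for j, name in enumerate(self.input_names):
                    rows.append((unit, year, name, self.X[t, i, j]))
                for j, name in enumerate(self.output_names):
                    rows.append((unit, year, name, self.Y[t, i, j]))
        return pd.DataFrame(rows, columns=["unit", "year", "indicator", "value"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EfficiencyPanel:
    """Unit × year efficiency scores with per-cell stage flags.

    ``status`` entries are ``"sbm"`` (stage-1 score, ≤ 1), ``"super"``
    (super-efficiency rescoring of an efficient unit, ≥ 1) or
    ``"infeasible"`` (no numeric score; the score cell is NaN).
    """

    unit_ids: list[str]
    years: list[int]
    scores: np.ndarray  # (n, T)
    status: np.ndarray = field(default=None)  # (n, T) of str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n, T = len(self.unit_ids), len(self.years)
        if self.scores.shape != (n, T):
            raise PanelValidationError(
                f"scores shape {self.scores.shape} != ({n}, {T})"
            )
        if self.status is None:
            self.status = np.where(self.scores >= 1.0, "super", "sbm").astype(object)
        self.status = np.asarray(self.status, dtype=object)
        if self.status.shape != (n, T):
            raise PanelValidationError("status shape mismatch")
        ok = self.status != "infeasible"
        if not (self.scores[ok] > 0).all():
            raise PanelValidationError("efficiency scores must be positive")

    def year_scores(self, year: int, drop_infeasible: bool = True) -> pd.Series:
        t = self.years.index(year)
        s = pd.Series(self.scores[:, t], index=self.unit_ids, name=year)
        if drop_infeasible:
            mask = self.status[:, t] != "infeasible"
            if not mask.all():
                warnings.warn(
                    f"excluding {int((~mask).sum())} infeasible unit(s) in {year}",
                    stacklevel=2,
                )
            s = s[mask]
        return s

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per unit, one column per year."""
        return pd.DataFrame(self.scores, index=pd.Index(self.unit_ids, name="unit"),
                            columns=self.years)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EfficiencyPanel":
        years = [int(c) for c in df.columns]
        return cls(unit_ids=list(df.index), years=years, scores=df.to_numpy())

    @classmethod
    def read(cls, path: str | Path) -> "EfficiencyPanel":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass
class RegionPartition:
    """Assignment of every unit to exactly one named group."""

    group_names: list[str]
    membership: dict[str, str]

    def __post_init__(self) -> None:
        for unit, g in self.membership.items():
            if g not in self.group_names:
                raise PanelValidationError(f"unit '{unit}' assigned to unknown group '{g}'")
        for g in self.group_names:
            if not any(v == g for v in self.membership.values()):
                raise PanelValidationError(f"group '{g}' is empty")

    def group_of(self, unit: str) -> str:
        try:
            return self.membership[unit]
        except KeyError:
            raise KeyError(f"unit '{unit}' not in partition") from None

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {g: [] for g in self.group_names}
        for unit, g in self.membership.items():
            out[g].append(unit)
        return out

    @classmethod
    def from_groups(cls, groups: Mapping[str, Sequence[str]]) -> "RegionPartition":
        membership: dict[str, str] = {}
        for g, units in groups.items():
            for u in units:
                if u in membership:
                    raise PanelValidationError(
                        f"unit '{u}' assigned to both '{membership[u]}' and '{g}'"
                    )
                membership[u] = g
        return cls(group_names=list(groups), membership=membership)


# --------------------------------------------------------------------------
# builtin region partition (eastern / central / western provinces;
# Tibet absent by construction)
# --------------------------------------------------------------------------

CHINA_THREE_REGION: dict[str, tuple[str, ...]] = {
    "eastern": ("Beijing", "Tianjin", "Hebei", "Liaoning", "Shanghai", "Jiangsu",
                "Zhejiang", "Fujian", "Shandong", "Guangdong", "Hainan"),
    "central": ("Shanxi", "Jilin", "Heilongjiang", "Anhui", "Jiangxi", "Henan",
                "Hubei", "Hunan"),
    "western": ("Inner Mongolia", "Guangxi", "Chongqing", "Sichuan", "Guizhou",
                "Yunnan", "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang"),
}


def load_region_partition(source: str | Path = "china_three_region") -> RegionPartition:
    """Load a region partition, either the builtin or a two-column CSV.

    The builtin ``"china_three_region"`` is the standard eastern (11
    provinces) / central (8) / western (11) division used in Chinese
    health-statistics yearbooks. A file source must have columns
    ``unit, group``.
    """
    if source == "china_three_region":
        return RegionPartition.from_groups(CHINA_THREE_REGION)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"unknown builtin or missing file: {source!r} "
            "(builtins: 'china_three_region')"
        )
    df = pd.read_csv(path)
    for col in ("unit", "group"):
        if col not in df.columns:
            raise SchemaError(f"partition file missing column '{col}'")
    if df["unit"].duplicated().any():
        dup = df.loc[df["unit"].duplicated(), "unit"].iloc[0]
        raise PanelValidationError(f"unit '{dup}' appears more than once in partition")
    groups: dict[str, list[str]] = {}
    for unit, g in zip(df["unit"], df["group"]):
        groups.setdefault(str(g), []).append(str(unit))
    return RegionPartition.from_groups(groups)


# --------------------------------------------------------------------------
# indicator-panel loading
# --------------------------------------------------------------------------

_DEFAULT_SCHEMA = {"unit": "unit", "year": "year", "indicator": "indicator",
                   "value": "value"}


def load_indicator_panel(
    path: str | Path,
    schema: Mapping[str, object],
) -> IndicatorPanel:
    """Read a long/tidy indicator table into an :class:`IndicatorPanel`.

    ``schema`` maps the roles ``unit``, ``year``, ``indicator``, ``value``
    to column names (defaults are the role names themselves) and must list
    ``inputs`` and ``outputs``: the indicator names to treat as DEA inputs
    and outputs respectively.
    """
    cols = {**_DEFAULT_SCHEMA, **{k: v for k, v in schema.items()
                                  if k in _DEFAULT_SCHEMA}}
    try:
        inputs = list(schema["inputs"])
        outputs = list(schema["outputs"])
    except KeyError as exc:
        raise SchemaError(f"schema must name 'inputs' and 'outputs': missing {exc}")
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    return _panel_from_long(df, inputs, outputs)


def _panel_from_long(df: pd.DataFrame, inputs: list[str],
                     outputs: list[str]) -> IndicatorPanel:
    units = list(dict.fromkeys(df["unit"].astype(str)))
    years = sorted(int(y) for y in df["year"].unique())
    wanted = inputs + outputs
    present = set(df["indicator"].unique())
    missing = [ind for ind in wanted if ind not in present]
    if missing:
        raise SchemaError(f"indicator(s) {missing} not found in file")
    pivot = df.pivot_table(index=["year", "unit"], columns="indicator",
                           values="value", aggfunc="first")
    T, n = len(years), len(units)
    X = np.full((T, n, len(inputs)), np.nan)
    Y = np.full((T, n, len(outputs)), np.nan)
    for t, year in enumerate(years):
        for i, unit in enumerate(units):
            try:
                row = pivot.loc[(year, unit)]
            except KeyError:
                raise PanelValidationError(
                    f"missing cell: unit '{unit}', year {year}"
                ) from None
            X[t, i] = row[inputs].to_numpy()
            Y[t, i] = row[outputs].to_numpy()
    return IndicatorPanel(unit_ids=units, years=years, input_names=inputs,
                          output_names=outputs, X=X, Y=Y)


def load_indicator_panel_wide(
    path: str | Path,
    inputs: Sequence[str],
    outputs: Sequence[str],
    unit_col: str = "unit",
    year_col: str = "year",
) -> IndicatorPanel:
    """Read a wide table (one row per unit-year, one column per indicator)."""
    df = pd.read_csv(path)
    missing = [c for c in (unit_col, year_col, *inputs, *outputs)
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    long = df.melt(id_vars=[unit_col, year_col],
                   value_vars=list(inputs) + list(outputs),
                   var_name="indicator", value_name="value")
    long = long.rename(columns={unit_col: "unit", year_col: "year"})
    return _panel_from_long(long, list(inputs), list(outputs))


# --------------------------------------------------------------------------
# bundled fixtures
# --------------------------------------------------------------------------

_FIXTURES = {
    "table1_efficiency_panel": "table1_efficiency.csv",
    "table4_theil_series": "table4_theil.csv",
}


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def _fixture_path(name: str) -> Path:
    return Path(resources.files("effidiff").joinpath("data", _FIXTURES[name]))


def load_fixture(name: str):
    """Load a bundled published table.

    ``"table1_efficiency_panel"`` → :class:`EfficiencyPanel`, the published
    30-province × 9-year (2008–2016) super-SBM efficiency scores.
    ``"table4_theil_series"`` → :class:`pandas.Series` of the annual Theil
    index 2008–2016 indexed by year.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {list_fixtures()}")
    if name == "table1_efficiency_panel":
        df = pd.read_csv(_fixture_path(name), index_col="province")
        return EfficiencyPanel.from_frame(df)
    df = pd.read_csv(_fixture_path(name))
    return pd.Series(df["theil"].to_numpy(), index=df["year"].astype(int),
                     name="theil")
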