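"""End-to-end orchestration: scores → counts → regional means → Theil
series and decomposition → grey forecast, emitted in the published table
layouts.

Two run modes exist because the two halves of the analysis have
different data requirements. A *full* run starts from raw indicator
panels and runs DEA first; a *scores* run starts from an existing
efficiency panel (e.g. a transcribed published table, for which the raw
yearbook indicators are not redistributable) and reproduces only the
downstream inequality and forecasting stages. The bundled fixture mode
is the scores run on the published 30-province panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .dea import (SolveOptions, consistently_efficient, count_efficient,
                  evaluate_panel)
from .gm11 import GM11Model, fit_gm11
from .panel_io import (EfficiencyPanel, RegionPartition, load_fixture,
                       load_indicator_panel, load_region_partition)
from .theil import TheilDecomposition, decomposition_table, \
    theil_series_with_decomposition

__all__ = ["RunConfig", "AnalysisReport", "regional_means",
           "run_full_analysis", "run_fixture_analysis"]


def regional_means(eff: EfficiencyPanel,
                   partition: RegionPartition) -> pd.DataFrame:
    """Arithmetic mean score of each region's members, per year, with a
    trailing all-years average column."""
    groups = partition.groups()
    for g, members in groups.items():
        if not members:
            raise ValueError(f"group '{g}' is empty")
        missing = [u for u in members if u not in eff.unit_ids]
        groups[g] = [u for u in members if u in eff.unit_ids]
        if not groups[g]:
            raise ValueError(f"group '{g}' has no units present in the panel")
    rows = {}
    for g, members in groups.items():
        vals = []
        for year in eff.years:
            s = eff.year_scores(year)
            vals.append(float(s[[u for u in members if u in s.index]].mean()))
        rows[g] = vals
    df = pd.DataFrame(rows, index=eff.years).T
    df.index.name = "region"
    df["Average"] = df.mean(axis=1)
    return df


@dataclass
class RunConfig:
    """Inputs and options for one pipeline run.

    Exactly one of ``indicator_path`` (full run, DEA first) or
    ``efficiency_source`` (scores run; a file path or
    ``"fixture:table1_efficiency_panel"``) must be given.
    """

    indicator_path: str | None = None
    indicator_schema: Mapping | None = None
    efficiency_source: str | None = None
    partition_source: str = "china_three_region"
    solve_options: SolveOptions = field(default_factory=SolveOptions)
    gm_series_source: str | None = None
    horizon: int = 10
    efficiency_threshold: float = 1.0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.indicator_path is None) == (self.efficiency_source is None):
            raise ValueError(
                "exactly one of indicator_path or efficiency_source is required"
            )
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class AnalysisReport:
    """All derived tables from one run, each a pure function of the inputs."""

    efficiency: EfficiencyPanel
    efficiency_table: pd.DataFrame
    efficient_counts: dict[int, list[str]]
    consistently_efficient: list[str]
    regional_means: pd.DataFrame
    theil_series: dict[int, TheilDecomposition]
    theil_table: pd.DataFrame
    gm_model: GM11Model
    forecast_table: pd.DataFrame
    forecast_decline_pct: float
    metadata: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.efficiency_table.to_csv(out / "efficiency.csv",
                                     float_format="%.3f")
        self.regional_means.to_csv(out / "regional_means.csv",
                                   float_format="%.3f")
        tt = self.theil_table.copy()
        share_cols = [c for c in tt.columns if c != "theil"]
        tt[share_cols] = tt[share_cols].round(1)
        tt["theil"] = tt["theil"].round(4)
        tt.to_csv(out / "theil_decomposition.csv")
        self.forecast_table.round(4).to_csv(out / "forecast.csv")
        counts = {str(y): units for y, units in self.efficient_counts.items()}
        with open(out / "run_metadata.json", "w") as fh:
            json.dump({**self.metadata,
                       "efficient_units": counts,
                       "consistently_efficient": self.consistently_efficient},
                      fh, indent=2, sort_keys=True)


def _efficiency_table(eff: EfficiencyPanel) -> pd.DataFrame:
    """Score table with the per-unit trailing average column and the
    per-year average row, as published tables print them."""
    df = eff.to_frame()
    df["Avg"] = df.mean(axis=1)
    df.loc["Avg"] = df.mean(axis=0)
    return df


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Run the pipeline described by ``config`` and return the report.

    Deterministic: identical config and inputs give bit-identical tables.
    Decomposition rows are re-checked for additivity and 100% share sums
    before the report is returned.
    """
    if config.indicator_path is not None:
        if config.indicator_schema is None:
            raise ValueError("indicator runs need an indicator_schema")
        panel = load_indicator_panel(config.indicator_path,
                                     config.indicator_schema)
        eff = evaluate_panel(panel, config.solve_options)
        mode = "indicators"
    else:
        src = config.efficiency_source
        if src.startswith("fixture:"):
            eff = load_fixture(src.split(":", 1)[1])
        else:
            eff = EfficiencyPanel.read(src)
        mode = "scores"

    partition = load_region_partition(config.partition_source)
    counts = {year: count_efficient(eff, year, config.efficiency_threshold)[1]
              for year in eff.years}
    always = consistently_efficient(eff, config.efficiency_threshold)
    means = regional_means(eff, partition)

    series = theil_series_with_decomposition(eff, partition)
    for year, dec in series.items():
        if dec.degenerate:
            continue
        assert abs(dec.within + dec.between - dec.total) < 1e-12
        assert abs(sum(dec.shares[g] for g in dec.within_terms)
                   + dec.shares["between"] - 1.0) < 1e-9
    ttable = decomposition_table(series)

    # The grey model fits the recomputed Theil totals by default; a panel
    # transcribed from a rounded publication can instead supply the
    # published inequality series via gm_series_source (rounded scores do
    # not always regenerate the original series, e.g. when printed tables
    # truncate super-efficiency values to 1.000).
    if config.gm_series_source is not None:
        src = config.gm_series_source
        if src.startswith("fixture:"):
            gm_series = load_fixture(src.split(":", 1)[1])
        else:
            df = pd.read_csv(src)
            gm_series = pd.Series(df.iloc[:, 1].to_numpy(),
                                  index=df.iloc[:, 0].astype(int))
        theil_values = gm_series.to_numpy()
        gm_years = list(gm_series.index)
    else:
        theil_values = [series[y].total for y in eff.years]
        gm_years = list(eff.years)
    gm = fit_gm11(theil_values, years=gm_years)
    fc = gm.forecast(config.horizon)
    forecast_table = pd.DataFrame({"predicted_theil": fc})
    forecast_table.index.name = "year"
    last_observed = theil_values[-1]
    decline_pct = 100.0 * (last_observed - fc.iloc[-1]) / last_observed

    report = AnalysisReport(
        efficiency=eff,
        efficiency_table=_efficiency_table(eff),
        efficient_counts=counts,
        consistently_efficient=always,
        regional_means=means,
        theil_series=series,
        theil_table=ttable,
        gm_model=gm,
        forecast_table=forecast_table,
        forecast_decline_pct=float(decline_pct),
        metadata={
            "mode": mode,
            "partition": config.partition_source,
            "horizon": config.horizon,
            "returns_to_scale": config.solve_options.returns_to_scale,
            "efficiency_threshold": config.efficiency_threshold,
            "gm_a": gm.a,
            "gm_b": gm.b,
            "gm_mean_relative_error": gm.mean_relative_error(),
            "version": __version__,
        },
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report


def run_fixture_analysis(horizon: int = 10,
                         output_dir: str | None = None) -> AnalysisReport:
    """Reproduce the downstream stages from the bundled published
    efficiency panel (counts, regional means, Theil series, forecast)."""
    return run_full_analysis(RunConfig(
        efficiency_source="fixture:table1_efficiency_panel",
        gm_series_source="fixture:table4_theil_series",
        horizon=horizon, output_dir=output_dir))
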