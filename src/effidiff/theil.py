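"""Generalized-entropy inequality and group-wise Theil decomposition.

For positive values :math:`e_i` with weights :math:`p_i` (summing to one,
uniform by default) and weighted mean :math:`\\mu`, the generalized
entropy family is

.. math::

    GE(\\beta) = \\frac{1}{\\beta(\\beta-1)}
        \\sum_i p_i \\left[ \\left(\\frac{e_i}{\\mu}\\right)^{\\beta} - 1 \\right],

with the analytic limits :math:`GE(1) = \\sum_i p_i (e_i/\\mu)\\ln(e_i/\\mu)`
(Theil-T) and :math:`GE(0) = \\sum_i p_i \\ln(\\mu/e_i)` (mean log
deviation). The decomposition is done in the Theil-T (β = 1) form, the
one that is exactly additive over a partition into groups :math:`p` with
sizes :math:`n_p` and means :math:`\\bar e_p`:

.. math::

    T = \\underbrace{\\sum_p \\frac{n_p}{n}\\frac{\\bar e_p}{\\bar e} T_p}_{T_W}
      + \\underbrace{\\sum_p \\frac{n_p}{n}\\frac{\\bar e_p}{\\bar e}
                     \\ln\\frac{\\bar e_p}{\\bar e}}_{T_B}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import EfficiencyPanel, RegionPartition

__all__ = [
    "GEOptions",
    "TheilDecomposition",
    "ge_index",
    "theil_t",
    "decompose_by_group",
    "theil_series_with_decomposition",
]

# below this, beta is treated as one of the analytic limits 0 / 1
_LIMIT_TOL = 1e-12


@dataclass(frozen=True)
class GEOptions:
    beta: float = 1.0
    weights: np.ndarray | None = None


def _check_values(values) -> np.ndarray:
    e = np.asarray(values, dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if not (np.isfinite(e).all() and (e > 0).all()):
        raise ValueError("all values must be finite and strictly positive")
    return e


def _check_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    p = np.asarray(weights, dtype=float)
    if p.shape != (n,):
        raise ValueError(f"weights shape {p.shape} does not match {n} values")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must be nonnegative and sum to 1")
    return p


def ge_index(values, beta: float = 1.0, weights=None) -> float:
    """Generalized entropy index GE(β) of positive values.

    β = 1 gives the Theil-T index, β = 0 the mean log deviation; any other
    real β uses the power form. Scale-invariant, nonnegative, and zero
    exactly when all values coincide.
    """
    e = _check_values(values)
    p = _check_weights(weights, e.size)
    mu = float(p @ e)
    r = e / mu
    if abs(beta - 1.0) < _LIMIT_TOL:
        return float(p @ (r * np.log(r)))
    if abs(beta) < _LIMIT_TOL:
        return float(-(p @ np.log(r)))
    return float((p @ (r ** beta - 1.0)) / (beta * (beta - 1.0)))


def theil_t(values, weights=None) -> float:
    """Theil-T index, the β = 1 member used throughout the decomposition."""
    return ge_index(values, beta=1.0, weights=weights)


@dataclass
class TheilDecomposition:
    """Additive within/between split of the Theil-T index over groups.

    ``shares`` maps each group name to its within-contribution as a
    fraction of the total, plus the keys ``"within"`` and ``"between"``
    for the aggregate components. For a degenerate (zero-total) cross
    section the shares are undefined and ``degenerate`` is set.
    """

    total: float
    within: float
    between: float
    within_terms: dict[str, float]
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    grand_mean: float
    shares: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False


def decompose_by_group(values, units, partition: RegionPartition,
                       group_order=None) -> TheilDecomposition:
    """Decompose the Theil-T index of ``values`` over the partition's groups.

    ``units`` labels each value; every unit must be mapped by the
    partition. Uniform unit weights (n_p/n population shares) are used,
    matching the additive within/between structure.
    """
    e = _check_values(values)
    units = list(units)
    if len(units) != e.size:
        raise ValueError("units and values must have equal length")
    groups: dict[str, list[int]] = {}
    for idx, u in enumerate(units):
        groups.setdefault(partition.group_of(u), []).append(idx)
    order = list(group_order) if group_order is not None else [
        g for g in partition.group_names if g in groups]
    if set(order) != set(groups):
        raise ValueError("group_order must cover exactly the groups present")

    n = e.size
    grand_mean = float(e.mean())
    total = theil_t(e)
    within_terms: dict[str, float] = {}
    group_means: dict[str, float] = {}
    group_sizes: dict[str, int] = {}
    between = 0.0
    for g in order:
        idx = groups[g]
        eg = e[idx]
        mg = float(eg.mean())
        w = (len(idx) / n) * (mg / grand_mean)
        within_terms[g] = w * theil_t(eg)
        between += w * np.log(mg / grand_mean)
        group_means[g] = mg
        group_sizes[g] = len(idx)
    within = float(sum(within_terms.values()))
    between = float(between)

    dec = TheilDecomposition(total=total, within=within, between=between,
                             within_terms=within_terms, group_means=group_means,
                             group_sizes=group_sizes, grand_mean=grand_mean)
    if total <= 0.0:
        dec.degenerate = True
    else:
        dec.shares = {g: v / total for g, v in within_terms.items()}
        dec.shares["within"] = within / total
        dec.shares["between"] = between / total
    return dec


def theil_series_with_decomposition(
    eff: EfficiencyPanel,
    partition: RegionPartition,
) -> dict[int, TheilDecomposition]:
    """Per-year Theil decomposition of an efficiency panel.

    Cells flagged infeasible are excluded (with a warning) and group sizes
    recomputed from the units actually present that year.
    """
    out: dict[int, TheilDecomposition] = {}
    for year in eff.years:
        s = eff.year_scores(year)
        if s.size < 2:
            raise ValueError(f"year {year} has fewer than 2 scored units")
        out[year] = decompose_by_group(s.to_numpy(), list(s.index), partition)
    return out


def decomposition_table(series: dict[int, TheilDecomposition],
                        percent: bool = True) -> pd.DataFrame:
    """Tabulate a decomposition series in the published layout: one row per
    year with per-group within shares, the within sum, the between share,
    and the total index."""
    rows = []
    for year, dec in series.items():
        row: dict[str, float] = {"year": year}
        scale = 100.0 if percent else 1.0
        if dec.degenerate:
            row.update({g: np.nan for g in dec.within_terms})
            row.update({"within": np.nan, "between": np.nan})
        else:
            for g in dec.within_terms:
                row[g] = scale * dec.shares[g]
            row["within"] = scale * dec.shares["within"]
            row["between"] = scale * dec.shares["between"]
        row["theil"] = dec.total
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")
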