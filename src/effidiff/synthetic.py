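"""Synthetic panels with known frontier and known efficiency structure.

Real yearbook indicator data behind published efficiency tables is rarely
redistributable, so every pipeline stage here is exercised against
generated data whose ground truth is known by construction:

* indicator panels where each unit's outputs are a smooth concave
  (Cobb–Douglas) frontier of its inputs scaled by a latent efficiency
  ``u ∈ (0, 1]`` — DEA scores should recover the ranking of ``u``;
* efficiency panels with designed group means and lognormal within-group
  spread — the between-group Theil share has a closed form to recover;
* grey-model sequences satisfying the GM(1,1) difference equation
  exactly — refitting recovers the coefficients at machine precision.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gm11 import generate_gm_sequence
from .panel_io import EfficiencyPanel, IndicatorPanel, RegionPartition

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "generate_dmu_panel",
    "generate_efficiency_panel",
    "generate_gm_sequence",
]


@dataclass(frozen=True)
class GroupSpec:
    """One group of units: its size, mean latent efficiency and spread."""

    name: str
    n_units: int
    mean_efficiency: float
    spread: float = 0.0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError(f"group '{self.name}' needs at least 2 units")
        if not 0.0 < self.mean_efficiency <= 1.0:
            raise ValueError(
                f"group '{self.name}' mean efficiency must lie in (0, 1]"
            )
        if self.spread < 0:
            raise ValueError("spread must be nonnegative")


@dataclass
class SyntheticSpec:
    """Recipe for an indicator panel with a known production frontier.

    The frontier maps m inputs to s outputs as
    ``y_r = scale_r · Π_i x_i^{α_ri}`` with nonnegative elasticities
    ``α_r`` summing to ``returns_to_scale`` for every output (1.0 gives a
    constant-returns frontier, < 1 a strictly concave one). Inputs are
    lognormal (right-skewed, strictly positive, like count indicators);
    outputs are the frontier value times the unit's latent efficiency
    times multiplicative lognormal noise.
    """

    groups: Sequence[GroupSpec]
    years: int = 1
    n_inputs: int = 3
    n_outputs: int = 3
    returns_to_scale: float = 1.0
    output_scales: Sequence[float] | None = None
    input_log_mean: float = 1.0
    input_log_sd: float = 0.6
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = [g if isinstance(g, GroupSpec) else GroupSpec(*g)
                       for g in self.groups]
        if not self.groups:
            raise ValueError("need at least one group")
        if self.years < 1 or self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("years, n_inputs, n_outputs must be >= 1")
        if not 0 < self.returns_to_scale <= 1.0:
            raise ValueError("returns_to_scale must lie in (0, 1]")
        if self.noise_sd < 0 or self.input_log_sd < 0:
            raise ValueError("spreads must be nonnegative")


def _elasticities(rng: np.random.Generator, m: int, s: int,
                  rts: float) -> np.ndarray:
    """Per-output elasticity rows, each strictly positive and summing to rts."""
    alpha = rng.dirichlet(np.full(m, 5.0), size=s)
    return alpha * rts


def generate_dmu_panel(spec: SyntheticSpec) -> tuple[IndicatorPanel, pd.DataFrame]:
    """Generate an indicator panel plus the latent-efficiency truth table.

    Returns the panel and a tidy frame ``(unit, year, group, u)`` holding
    every unit-year's true efficiency relative to the generating frontier.
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    m, s, T = spec.n_inputs, spec.n_outputs, spec.years
    alpha = _elasticities(rng, m, s, spec.returns_to_scale)
    scales = (np.asarray(spec.output_scales, dtype=float)
              if spec.output_scales is not None else np.ones(s))
    if scales.shape != (s,) or (scales <= 0).any():
        raise ValueError("output_scales must be s positive numbers")

    unit_ids: list[str] = []
    unit_group: list[str] = []
    for g in spec.groups:
        for i in range(g.n_units):
            unit_ids.append(f"{g.name}_{i + 1:02d}")
            unit_group.append(g.name)
    n = len(unit_ids)

    X = np.empty((T, n, m))
    Y = np.empty((T, n, s))
    truth_rows = []
    years = list(range(1, T + 1))
    for t in range(T):
        X[t] = rng.lognormal(spec.input_log_mean, spec.input_log_sd, size=(n, m))
        row = 0
        for g in spec.groups:
            for _ in range(g.n_units):
                u = g.mean_efficiency
                if g.spread > 0:
                    u = float(np.clip(rng.normal(u, g.spread), 1e-3, 1.0))
                frontier = scales * np.prod(X[t, row] ** alpha, axis=1)
                noise = (rng.lognormal(-spec.noise_sd**2 / 2, spec.noise_sd, size=s)
                         if spec.noise_sd > 0 else 1.0)
                Y[t, row] = frontier * u * noise
                truth_rows.append((unit_ids[row], years[t], unit_group[row], u))
                row += 1
    panel = IndicatorPanel(
        unit_ids=unit_ids, years=years,
        input_names=[f"input_{i + 1}" for i in range(m)],
        output_names=[f"output_{r + 1}" for r in range(s)],
        X=X, Y=Y)
    truth = pd.DataFrame(truth_rows, columns=["unit", "year", "group", "u"])
    return panel, truth


def generate_efficiency_panel(
    groups: Sequence[GroupSpec | tuple],
    years: Sequence[int] | int = 1,
    seed: int = 0,
) -> tuple[EfficiencyPanel, RegionPartition, float]:
    """Generate score panels with designed group means and lognormal spread.

    Scores are ``mean_g · exp(σ_g Z − σ_g²/2)`` so each group's population
    mean is exactly its design mean. Returns the panel, the matching
    partition, and the analytic between-group Theil share implied by the
    design (within-group Theil of a lognormal is σ²/2).
    """
    groups = [g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in groups]
    if isinstance(years, int):
        years = list(range(1, years + 1))
    years = [int(y) for y in years]
    rng = np.random.default_rng(seed)

    unit_ids: list[str] = []
    membership: dict[str, str] = {}
    for g in groups:
        for i in range(g.n_units):
            uid = f"{g.name}_{i + 1:02d}"
            unit_ids.append(uid)
            membership[uid] = g.name
    n = len(unit_ids)
    scores = np.empty((n, len(years)))
    for t in range(len(years)):
        row = 0
        for g in groups:
            z = rng.standard_normal(g.n_units)
            scores[row:row + g.n_units, t] = (
                g.mean_efficiency * np.exp(g.spread * z - g.spread**2 / 2.0))
            row += g.n_units

    # analytic Theil split of the design (population quantities)
    sizes = np.array([g.n_units for g in groups], dtype=float)
    means = np.array([g.mean_efficiency for g in groups])
    sigmas = np.array([g.spread for g in groups])
    w = sizes / sizes.sum()
    grand = float(w @ means)
    within = float(np.sum(w * (means / grand) * (sigmas**2 / 2.0)))
    between = float(np.sum(w * (means / grand) * np.log(means / grand)))
    total = within + between
    between_share = between / total if total > 0 else 0.0

    panel = EfficiencyPanel(unit_ids=unit_ids, years=years, scores=scores)
    partition = RegionPartition(group_names=[g.name for g in groups],
                                membership=membership)
    return panel, partition, between_share
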