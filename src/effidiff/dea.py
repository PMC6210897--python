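"""Slacks-based measure (SBM) DEA and super-efficiency SBM scoring.

The stage-1 SBM program for decision-making unit (DMU) :math:`k` with
inputs :math:`X` (n×m) and outputs :math:`Y` (n×s) is the fractional
program

.. math::

    \\min \\rho = \\frac{1 - \\tfrac1m \\sum_i s^-_i / x_{ik}}
                       {1 + \\tfrac1s \\sum_r s^+_r / y_{rk}}
    \\quad \\text{s.t. } x_k = X^T\\lambda + s^-, \\;
    y_k = Y^T\\lambda - s^+, \\; \\lambda, s^-, s^+ \\ge 0,

with the convexity constraint :math:`\\sum_j \\lambda_j = 1` under
variable returns to scale (VRS). :math:`\\rho^* = 1` (all slacks zero)
means the unit is on the frontier. Efficient units are then re-scored by
the super-efficiency SBM program, which projects the unit onto the
frontier spanned by the *other* units and reports

.. math::

    \\delta = \\frac{\\tfrac1m \\sum_i \\bar x_i / x_{ik}}
                   {\\tfrac1s \\sum_r \\bar y_r / y_{rk}} \\ge 1,

where :math:`\\bar x \\ge x_k` and :math:`0 \\le \\bar y \\le y_k` lie in
the production set of the remaining units. Both fractional programs are
solved exactly as linear programs via the Charnes–Cooper positive-scalar
substitution (normalize the denominator to one); the LPs are dispatched
to HiGHS through :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import linprog

from .panel_io import EfficiencyPanel, IndicatorPanel, PanelValidationError

__all__ = [
    "DMUSet",
    "SolveOptions",
    "SBMResult",
    "EfficiencyScore",
    "SolverError",
    "solve_sbm",
    "solve_super_sbm",
    "score_dmu",
    "evaluate_panel",
    "count_efficient",
    "consistently_efficient",
]


class SolverError(RuntimeError):
    """The underlying LP solver failed or returned an unexpected status."""


@dataclass
class DMUSet:
    """One evaluation cross-section: strictly positive X (n×m), Y (n×s)."""

    X: np.ndarray
    Y: np.ndarray
    unit_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise PanelValidationError("X and Y must have the same number of rows")
        if not ((self.X > 0).all() and (self.Y > 0).all()):
            raise PanelValidationError("all inputs and outputs must be strictly positive")
        if self.unit_ids is None:
            self.unit_ids = [f"dmu{j}" for j in range(self.X.shape[0])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def s(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class SolveOptions:
    """Solver configuration shared by both stages.

    returns_to_scale : "vrs" adds the convexity constraint Σλ = 1 in both
        stages (the default, matching the variable-returns assumption);
        "crs" drops it.
    efficiency_tolerance : stage-1 scores within this of 1 are treated as
        efficient and re-scored by the super-efficiency program.
    lp_tolerance : feasibility/optimality tolerance handed to HiGHS, and
        the tolerance at which the slack identities are asserted.
    infeasible_policy : "flag" records infeasible super-efficiency
        programs with no numeric score; ("cap", v) assigns the cap v.
    """

    returns_to_scale: Literal["vrs", "crs"] = "vrs"
    efficiency_tolerance: float = 1e-6
    lp_tolerance: float = 1e-9
    infeasible_policy: str | tuple[str, float] = "flag"

    def __post_init__(self) -> None:
        for tol in (self.efficiency_tolerance, self.lp_tolerance):
            if not 0 < tol <= 1e-3:
                raise ValueError("tolerances must lie in (0, 1e-3]")
        if self.returns_to_scale not in ("vrs", "crs"):
            raise ValueError("returns_to_scale must be 'vrs' or 'crs'")


@dataclass
class SBMResult:
    """Optimum of one SBM or super-SBM program."""

    score: float
    slacks_in: np.ndarray | None
    slacks_out: np.ndarray | None
    lambdas: np.ndarray | None
    stage: Literal["sbm", "super"]
    status: Literal["optimal", "infeasible"]
    projection: tuple[np.ndarray, np.ndarray] | None = None


@dataclass
class EfficiencyScore:
    """Two-stage score for one unit: the value, which stage produced it,
    and the solver status."""

    value: float
    stage: Literal["sbm", "super"]
    status: Literal["optimal", "infeasible"]


_HIGHS_OPTS = {"presolve": True}


def _run_lp(c, A_eq, b_eq, A_ub, b_ub, tol: float):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs",
                  options={**_HIGHS_OPTS,
                           "primal_feasibility_tolerance": tol,
                           "dual_feasibility_tolerance": tol})
    return res


def solve_sbm(dmus: DMUSet, k: int, opts: SolveOptions = SolveOptions()) -> SBMResult:
    """Solve the stage-1 SBM program for unit ``k``.

    Returns the exact fractional-program optimum: the score ρ ∈ (0, 1],
    input slacks s⁻, output slacks s⁺ and peer weights λ satisfying
    x_k = X'λ + s⁻ and y_k = Y'λ − s⁺.
    """
    n, m, s = dmus.n, dmus.m, dmus.s
    if not 0 <= k < n:
        raise IndexError(f"unit index {k} out of range for n={n}")
    x0, y0 = dmus.X[k], dmus.Y[k]

    # Charnes-Cooper variables: [t, Lambda (n), S- (m), S+ (s)]
    nv = 1 + n + m + s
    c = np.zeros(nv)
    c[0] = 1.0
    c[1 + n:1 + n + m] = -1.0 / (m * x0)

    rows_eq = []
    rhs_eq = []
    # denominator normalization: t + (1/s) sum S+/y0 = 1
    row = np.zeros(nv)
    row[0] = 1.0
    row[1 + n + m:] = 1.0 / (s * y0)
    rows_eq.append(row)
    rhs_eq.append(1.0)
    # t*x0 = X'Lambda + S-
    for i in range(m):
        row = np.zeros(nv)
        row[0] = x0[i]
        row[1:1 + n] = -dmus.X[:, i]
        row[1 + n + i] = -1.0
        rows_eq.append(row)
        rhs_eq.append(0.0)
    # t*y0 = Y'Lambda - S+
    for r in range(s):
        row = np.zeros(nv)
        row[0] = y0[r]
        row[1:1 + n] = -dmus.Y[:, r]
        row[1 + n + m + r] = 1.0
        rows_eq.append(row)
        rhs_eq.append(0.0)
    if opts.returns_to_scale == "vrs":
        row = np.zeros(nv)
        row[0] = -1.0
        row[1:1 + n] = 1.0
        rows_eq.append(row)
        rhs_eq.append(0.0)

    res = _run_lp(c, np.array(rows_eq), np.array(rhs_eq), None, None,
                  opts.lp_tolerance)
    if res.status == 2:
        # cannot happen for stage 1 (lambda = e_k is always feasible)
        return SBMResult(score=np.nan, slacks_in=None, slacks_out=None,
                         lambdas=None, stage="sbm", status="infeasible")
    if res.status != 0:
        raise SolverError(f"stage-1 LP failed for unit {k}: {res.message}")
    t = res.x[0]
    if t <= 0:
        raise SolverError(f"degenerate Charnes-Cooper scalar t={t} for unit {k}")
    lam = res.x[1:1 + n] / t
    s_in = res.x[1 + n:1 + n + m] / t
    s_out = res.x[1 + n + m:] / t
    return SBMResult(score=float(res.fun), slacks_in=s_in, slacks_out=s_out,
                     lambdas=lam, stage="sbm", status="optimal")


def solve_super_sbm(dmus: DMUSet, k: int,
                    opts: SolveOptions = SolveOptions()) -> SBMResult:
    """Solve the super-efficiency SBM program for unit ``k``.

    Unit ``k`` is excluded from the reference set; the program finds the
    nearest dominated point (x̄ ≥ x_k, ȳ ≤ y_k) of the remaining
    technology and reports δ ≥ 1. Intended for units found efficient in
    stage 1 (see :func:`score_dmu` for the two-stage protocol).
    """
    n, m, s = dmus.n, dmus.m, dmus.s
    if n < 2:
        raise PanelValidationError("super-efficiency needs at least 2 units")
    if not 0 <= k < n:
        raise IndexError(f"unit index {k} out of range for n={n}")
    x0, y0 = dmus.X[k], dmus.Y[k]
    others = [j for j in range(n) if j != k]
    Xo, Yo = dmus.X[others], dmus.Y[others]
    p = n - 1

    # variables: [t, Lambda (p), Xbar (m), Ybar (s)]
    nv = 1 + p + m + s
    c = np.zeros(nv)
    c[1 + p:1 + p + m] = 1.0 / (m * x0)

    rows_eq, rhs_eq = [], []
    # denominator normalization: (1/s) sum Ybar/y0 = 1
    row = np.zeros(nv)
    row[1 + p + m:] = 1.0 / (s * y0)
    rows_eq.append(row)
    rhs_eq.append(1.0)
    if opts.returns_to_scale == "vrs":
        row = np.zeros(nv)
        row[0] = -1.0
        row[1:1 + p] = 1.0
        rows_eq.append(row)
        rhs_eq.append(0.0)

    rows_ub, rhs_ub = [], []
    # X'Lambda - Xbar <= 0  and  t*x0 - Xbar <= 0
    for i in range(m):
        row = np.zeros(nv)
        row[1:1 + p] = Xo[:, i]
        row[1 + p + i] = -1.0
        rows_ub.append(row)
        rhs_ub.append(0.0)
        row = np.zeros(nv)
        row[0] = x0[i]
        row[1 + p + i] = -1.0
        rows_ub.append(row)
        rhs_ub.append(0.0)
    # Ybar - Y'Lambda <= 0  and  Ybar - t*y0 <= 0
    for r in range(s):
        row = np.zeros(nv)
        row[1:1 + p] = -Yo[:, r]
        row[1 + p + m + r] = 1.0
        rows_ub.append(row)
        rhs_ub.append(0.0)
        row = np.zeros(nv)
        row[0] = -y0[r]
        row[1 + p + m + r] = 1.0
        rows_ub.append(row)
        rhs_ub.append(0.0)

    res = _run_lp(c, np.array(rows_eq), np.array(rhs_eq),
                  np.array(rows_ub), np.array(rhs_ub), opts.lp_tolerance)
    if res.status == 2:
        return SBMResult(score=np.nan, slacks_in=None, slacks_out=None,
                         lambdas=None, stage="super", status="infeasible")
    if res.status != 0:
        raise SolverError(f"super-efficiency LP failed for unit {k}: {res.message}")
    t = res.x[0]
    if t <= 0:
        raise SolverError(f"degenerate Charnes-Cooper scalar t={t} for unit {k}")
    lam_full = np.zeros(n)
    lam_full[others] = res.x[1:1 + p] / t
    xbar = res.x[1 + p:1 + p + m] / t
    ybar = res.x[1 + p + m:] / t
    return SBMResult(score=float(res.fun),
                     slacks_in=np.maximum(xbar - x0, 0.0),
                     slacks_out=np.maximum(y0 - ybar, 0.0),
                     lambdas=lam_full, stage="super", status="optimal",
                     projection=(xbar, ybar))


def score_dmu(dmus: DMUSet, k: int,
              opts: SolveOptions = SolveOptions()) -> EfficiencyScore:
    """Two-stage score for unit ``k``.

    Runs stage-1 SBM; if the unit is efficient (ρ ≥ 1 − tol) it is
    re-scored by the super-efficiency program so that efficient units can
    be ranked (scores may exceed 1 only through this stage).
    """
    stage1 = solve_sbm(dmus, k, opts)
    if stage1.score < 1.0 - opts.efficiency_tolerance:
        return EfficiencyScore(value=stage1.score, stage="sbm", status="optimal")
    stage2 = solve_super_sbm(dmus, k, opts)
    if stage2.status == "infeasible":
        if isinstance(opts.infeasible_policy, tuple):
            policy, cap = opts.infeasible_policy
            if policy != "cap":
                raise ValueError(f"unknown infeasible policy {opts.infeasible_policy!r}")
            return EfficiencyScore(value=float(cap), stage="super", status="infeasible")
        return EfficiencyScore(value=np.nan, stage="super", status="infeasible")
    # guard against roundoff placing delta a hair under 1
    return EfficiencyScore(value=max(stage2.score, 1.0), stage="super",
                           status="optimal")


def evaluate_panel(panel: IndicatorPanel,
                   opts: SolveOptions = SolveOptions()) -> EfficiencyPanel:
    """Score every unit of every year against that year's own frontier.

    Units are compared only within the same calendar year (contemporaneous
    frontiers), so scores are not directly comparable across years except
    through the cross-section statistics built on them.
    """
    n, T = panel.n_units, len(panel.years)
    scores = np.empty((n, T))
    status = np.empty((n, T), dtype=object)
    for t, year in enumerate(panel.years):
        X, Y = panel.cross_section(year)
        if n < 2:
            raise PanelValidationError(f"year {year} has fewer than 2 units")
        dmus = DMUSet(X=X, Y=Y, unit_ids=panel.unit_ids)
        for i in range(n):
            es = score_dmu(dmus, i, opts)
            scores[i, t] = es.value
            status[i, t] = es.stage if es.status == "optimal" else "infeasible"
    return EfficiencyPanel(unit_ids=list(panel.unit_ids), years=list(panel.years),
                           scores=scores, status=status)


def count_efficient(eff: EfficiencyPanel, year: int, threshold: float = 1.0,
                    tol: float = 1e-9) -> tuple[int, list[str]]:
    """Units scoring at or above ``threshold`` (within ``tol``) in ``year``."""
    s = eff.year_scores(year)
    units = sorted(s.index[s >= threshold - tol])
    return len(units), units


def consistently_efficient(eff: EfficiencyPanel, threshold: float = 1.0,
                           tol: float = 1e-9) -> list[str]:
    """Units efficient in every year of the panel (all-years intersection)."""
    units: set[str] | None = None
    for year in eff.years:
        _, eff_units = count_efficient(eff, year, threshold, tol)
        units = set(eff_units) if units is None else units & set(eff_units)
    return sorted(units or [])
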