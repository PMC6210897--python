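# Methods

This note records the models implemented, the conventions and numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations. Everything quantitative stated here is
computed by the test suite or `scripts/acceptance.py`.

## Slacks-based DEA and super-efficiency

The stage-1 program is Tone's slacks-based measure: for unit *k* it
minimizes

ρ = [1 − (1/m) Σᵢ s⁻ᵢ/xᵢₖ] / [1 + (1/s) Σᵣ s⁺ᵣ/yᵣₖ]

subject to x_k = X'λ + s⁻, y_k = Y'λ − s⁺, nonnegative λ and slacks, and
Σλ = 1 under variable returns to scale (VRS). The score is non-radial:
it averages *relative* input excesses and output shortfalls rather than
assuming proportional contraction, so a unit is efficient (ρ = 1) only
when no slack of any kind remains.

Units found efficient are re-scored by the super-efficiency SBM program:
unit *k* is removed from the reference set and the program finds the
closest point (x̄ ≥ x_k, ȳ ≤ y_k, ȳ ≥ 0) of the remaining technology,
reporting δ = mean(x̄/x_k) / mean(ȳ/y_k) ≥ 1. δ ranks the frontier units:
it measures how much a unit could worsen before its peers would envelop
it.

**Linearization.** Both objectives are linear-fractional, so each is
solved exactly as an LP by the Charnes–Cooper positive-scalar
substitution: scale all variables by t > 0 and normalize the denominator
to one. The LPs go to HiGHS via `scipy.optimize.linprog`. Correctness of
the whole formulation is checked against an independent brute-force
minimizer of the *fractional* programs (lattice search over the
peer-weight simplex plus exhaustive vertex enumeration of the constraint
polytope — a linear-fractional optimum sits at a vertex); on small random
instances LP and brute force agree to ~1e−12.

**Conventions and tolerances.**

- Default returns-to-scale is VRS in *both* stages, for internal
  consistency; CRS is available via `SolveOptions(returns_to_scale="crs")`.
- A stage-1 score within `efficiency_tolerance = 1e-6` of 1 counts as
  efficient and triggers the super-efficiency rescoring. Feasibility /
  optimality tolerance handed to the LP solver is `1e-9`.
- Super-efficiency scores that land a hair under 1 through roundoff are
  clamped to 1, so reported score < 1 always means stage "sbm" and
  score > 1 always means stage "super".
- With ȳ ≥ 0 admitted (rather than ȳ > 0 elementwise), the VRS
  super-efficiency program is feasible for every n ≥ 2 instance with
  positive data, so the `infeasible` status can only arise from solver
  failure; the flag/cap policy exists for completeness and for data that
  violate the positivity contract upstream.
- Panels are scored year by year against contemporaneous frontiers:
  units are compared only with units of the same calendar year. A pooled
  multi-year frontier is a deliberate non-feature; cross-year statements
  are made through the cross-sectional statistics (means, counts, Theil).
- Strict positivity of all indicators is a hard precondition. Rates
  (e.g. bed-utilization) are ordinary positive outputs: SBM is invariant
  to separate positive rescaling of every indicator column (asserted to
  1e−9 in tests), so percent vs fraction is immaterial.

## Theil index and regional decomposition

The inequality measure is the generalized entropy family GE(β) with
equal unit weights; β = 1 (Theil-T) is used throughout the decomposition
because it is the member whose within/between split with weights
(n_p/n)(ē_p/ē) is exactly additive. β = 1 and β = 0 are implemented as
analytic limits, not numerical ones. Equal province weights match the
population shares n_p/n in the decomposition; no size weighting is
applied anywhere.

Additivity (within + between = total) is asserted at 1e−12 on every
decomposition the pipeline emits. A zero-total cross-section (all scores
equal) has undefined shares and is returned flagged degenerate rather
than as NaN arithmetic. Cells flagged infeasible are dropped with a
warning and group sizes recomputed from the units actually present.

The bundled published efficiency panel reproduces the published annual
Theil series at three significant figures in eight of nine years. The
remaining year (2014) cannot be regenerated from the printed scores: the
published panel prints many 2014 frontier provinces as exactly 1.000,
truncating their super-efficiency values, which deflates the recomputed
index (0.1135 vs 0.1494). For this reason the pipeline's reproduction
mode fits the grey model on the bundled published Theil series itself
(`RunConfig.gm_series_source`), while the decomposition table is always
recomputed from the score panel.

The published GE form prints the mean/value ratio orientation inside the
power; direct computation on the bundled panel shows the series and its
printed decomposition are reproduced by the standard value/mean
(Theil-T) orientation — e.g. 2008 gives 0.1778 vs the printed 0.1779,
and every 2008/2016 share matches to 0.1 pp — whereas the printed
orientation at β = 1 gives the mean-log-deviation-like value 0.1766,
which does not match. The implementation therefore uses the standard
orientation.

## GM(1,1) grey model

Coefficients (a, b) are estimated by least squares on the discretized
grey equation x⁰(k+1) = b − a·z¹(k), where z¹ is the consecutive-
neighbour mean of the accumulated (1-AGO) series; the minimum series
length is 4. Fitted and forecast values use the exponential
time-response function with x̂⁰(1) ≡ x⁰(1). |a| < 1e−12 switches to the
analytic a → 0 limit (constant increments b), so constant series fit
exactly with a = 0.

Two deliberate conventions:

- **Fit error.** The mean absolute relative residual excludes the first
  point by default — its residual is structurally zero and would only
  dilute the average; `include_first=True` is exposed. On the bundled
  series the two conventions give 5.20% and 4.62% respectively; the
  excluding convention is the one consistent with the published 5.30% at
  the published coefficient precision.
- **Generator/estimator consistency.** `generate_gm_sequence` produces
  series satisfying the *discrete* (trapezoid) equation exactly, which
  makes least squares recover (a, b) to machine precision — the
  self-consistency oracle used in tests. Because fitted values then come
  from the *continuous* exponential response, their residual on such
  series is not exactly zero but O(a³) per point (~2e−5 at a ≈ 0.016).

No smoothness/class-ratio pre-test gates fitting (none is customary for
series this short); the class ratios and their admissible band
exp(∓2/(n+1)) are exposed as a diagnostic, and the CLI prints a note
when ratios fall outside it. Forecast step k maps to calendar year
last_year + k. The conventional adequacy bar (mean relative error
< 20%) is reported as the `acceptable` flag.

## Synthetic generators

`generate_dmu_panel` emulates a province-level indicator panel: inputs
are lognormal (right-skewed, strictly positive, like facility/staff/bed
counts); each output is a Cobb–Douglas frontier value — elasticities
drawn from a Dirichlet and scaled to sum to `returns_to_scale` per
output — multiplied by the unit's latent efficiency u ∈ (0, 1] and
optional multiplicative lognormal noise. The latent u is returned so
recovery is testable. What this does *not* emulate: the magnitudes and
correlation structure of real yearbook indicators, measurement error in
official statistics, or serial correlation of a province's efficiency
across years (years are drawn independently). Passing tests therefore
show the estimator chain recovers known structure under clean
conditions, not that real data meet those conditions.

Rank recovery by DEA is exact only when the DEA technology can represent
the generating frontier: with one input, one output and constant
returns, the CRS hull *is* the generating ray and score ranks equal
true-efficiency ranks exactly. With two or more inputs the
piecewise-linear hull approximates the smooth frontier from below and
ranks agree only approximately (Spearman ≈ 0.9–0.97 at n = 16–60);
tests cover both regimes.

`generate_efficiency_panel` skips the DEA stage: scores are
mean_g·exp(σ_g Z − σ_g²/2), so each group's population mean is its
design mean and the within-group Theil of each lognormal group is
σ_g²/2, giving a closed-form between-group share to recover (within
±3 pp at n = 300 in tests). `generate_gm_sequence` is described above.
All generators are deterministic functions of an explicit integer seed.

## Pipeline and reporting

Two run modes: from raw indicators (DEA first) or from an existing
efficiency panel (inequality and forecasting only — the mode that
reproduces published downstream tables when the raw indicator data
behind a published score table is not redistributable). Emitted tables
round efficiencies to 3 decimals, indices to 4, percentage shares to 1,
matching the usual print precision; all invariants (additivity, 100%
share sums, stage consistency) are re-asserted on the emitted rows, and
identical configurations produce byte-identical output files.

Problem sizes in the test suite are chosen for desk-scale runs: oracle
comparisons use n ≤ 5 units and m + s ≤ 3 indicators, recovery checks
use panels of 16–300 units, and the published-table reproductions are
30 × 9. The relative decline of the 2026 forecast vs the last observed
year is computed from unrounded values (13.11%; rounding the forecast to
4 decimals first gives 13.08%).

## Known limitations

- No undesirable-output SBM variant, Malmquist productivity dynamics,
  window/bootstrap DEA, or radial models; no Gini/Atkinson indices; no
  GM(1,N) or residual-corrected grey variants.
- Super-efficiency under VRS ranks only units inside the span of the
  others' convexified technology in the sense of this formulation;
  degenerate data (e.g. near-duplicate columns) are handled by the LP
  solver's tolerances, not by preprocessing.
- The Theil decomposition assumes every scored unit maps to exactly one
  region; weighted (e.g. population-share) decompositions beyond equal
  unit weights are not implemented.
- GM(1,1) is a two-parameter exponential trend: it cannot represent
  turning points, and its forecasts are only as meaningful as the
  monotone-trend assumption for the series at hand.
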