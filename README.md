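# effidiff

Efficiency measurement, inequality decomposition and trend forecasting
for provincial service panels — the tool-chain used in health-services
research to ask three questions of a province × year indicator panel:

1. **How efficiently does each province turn health-service inputs into
   outputs?** Scored with the slacks-based measure (SBM) of data
   envelopment analysis, plus super-efficiency rescoring so that
   frontier provinces can be ranked.
2. **How unequal are those efficiency scores, and where does the
   inequality sit?** Measured with the Theil index and decomposed
   additively into within-region and between-region components.
3. **Where is the inequality heading?** Extrapolated with the GM(1,1)
   grey model, which needs only a handful of annual observations.

The package bundles the published 30-province × 9-year (2008–2016)
efficiency panel for Chinese community health services and its annual
Theil series as text fixtures, ships a synthetic-data generator with
known ground truth for every stage, and exposes both a Python API and a
thin `effidiff` command line.

## Models

**SBM DEA.** For decision-making unit *k* with inputs `x_k` and outputs
`y_k` against technology `(X, Y)`:

```
min ρ = [1 − (1/m) Σ_i s⁻_i / x_ik] / [1 + (1/s) Σ_r s⁺_r / y_rk]
s.t.   x_k = X'λ + s⁻,   y_k = Y'λ − s⁺,   λ, s⁻, s⁺ ≥ 0,  (Σλ = 1 under VRS)
```

ρ = 1 with zero slacks means efficient. Efficient units are re-scored by
the super-efficiency program, which excludes the unit from the reference
set and finds the nearest dominated point `(x̄ ≥ x_k, ȳ ≤ y_k)` of the
remaining technology, giving δ ≥ 1. Both fractional programs are solved
exactly as linear programs (Charnes–Cooper substitution, HiGHS).

**Theil decomposition.** For positive scores `e_i` with uniform weights,
groups *p* of size `n_p` with means `ē_p`:

```
T = Σ_i (1/n)(e_i/ē) ln(e_i/ē)
  = Σ_p (n_p/n)(ē_p/ē) T_p  +  Σ_p (n_p/n)(ē_p/ē) ln(ē_p/ē)
        (within, T_W)             (between, T_B)
```

The split is exactly additive; shares are reported as percent of total.

**GM(1,1).** Fits `dx¹/dt + a·x¹ = b` to the running sum `x¹` of a short
positive series by least squares on the consecutive-neighbour means, then
reconstructs and forecasts through the exponential time-response
`x̂¹(i) = (x⁰(1) − b/a)e^{−a(i−1)} + b/a`.

## Worked example

```python
from effidiff import run_fixture_analysis

report = run_fixture_analysis(horizon=10)
print(len(report.efficient_counts[2008]))      # 12 efficient provinces in 2008
print(report.regional_means["Average"].round(3))
# eastern 0.797, central 0.487, western 0.718
print(report.theil_table.loc[2008, ["within", "between"]].round(1))
# within 79.5, between 20.5  (percent of the 2008 Theil index 0.1778)
m = report.metadata
print(f"{m['gm_a']:.4f} {m['gm_b']:.4f}")      # 0.0158 0.1712
print(report.forecast_table.loc[2026].round(4))  # predicted_theil 0.1276
```

Read: in 2008 twelve provinces sat on the best-practice frontier; the
eastern region had the highest average efficiency over the period; about
80% of the 2008 score inequality came from gaps *inside* regions; and
the fitted grey model (developing coefficient a = 0.0158, fit error
5.2%) predicts the inequality index to drift down to 0.1276 by 2026 —
slow convergence.

The same stages are available piecewise (`evaluate_panel`, `theil_t`,
`decompose_by_group`, `fit_gm11`, …); `examples/` holds one short script
per capability, and the CLI mirrors them:

```sh
effidiff run-all --fixtures --outdir report/
effidiff forecast series.csv --horizon 10
```

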