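"""Run the whole analysis on the bundled published tables.

Chains every stage — efficient-unit counts, regional means, the Theil
series with its regional decomposition, and the GM(1,1) forecast — and
prints the summary numbers each table carries.
"""

from effidiff import run_fixture_analysis

report = run_fixture_analysis(horizon=10)

print("efficient provinces per year:")
for year, units in report.efficient_counts.items():
    print(f"  {year}: {len(units)}")
print(f"efficient in every year: {', '.join(report.consistently_efficient)}")

print("\nregional period averages:")
print(report.regional_means["Average"].round(3).to_string())

meta = report.metadata
print(f"\nGM(1,1): a = {meta['gm_a']:.4f}, b = {meta['gm_b']:.4f}, "
      f"fit error = {100 * meta['gm_mean_relative_error']:.2f}%")
fc = report.forecast_table["predicted_theil"]
print(f"Theil forecast: {fc.index[0]} -> {fc.iloc[0]:.4f}, "
      f"{fc.index[-1]} -> {fc.iloc[-1]:.4f} "
      f"({report.forecast_decline_pct:.2f}% below the last observed year)")
print("\nThe efficiency gap between provinces narrows slowly; most of it "
      "sits within regions rather than between regional averages.")
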