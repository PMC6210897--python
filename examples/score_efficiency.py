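"""Score a synthetic indicator panel with the two-stage super-SBM protocol.

Builds a 16-province panel whose true efficiencies are known by
construction, runs the slacks-based DEA scorer against each year's
frontier, and compares recovered scores with the latent truth.
"""

import pandas as pd

from effidiff import (GroupSpec, SolveOptions, SyntheticSpec, evaluate_panel,
                      generate_dmu_panel)

spec = SyntheticSpec(
    groups=[GroupSpec("strong", 8, mean_efficiency=0.9, spread=0.08),
            GroupSpec("weak", 8, mean_efficiency=0.6, spread=0.08)],
    years=1, n_inputs=2, n_outputs=1, returns_to_scale=1.0,
    noise_sd=0.0, seed=0)
panel, truth = generate_dmu_panel(spec)

eff = evaluate_panel(panel, SolveOptions(returns_to_scale="crs"))

out = pd.DataFrame({
    "true_u": truth.set_index("unit").loc[panel.unit_ids, "u"],
    "sbm_score": eff.scores[:, 0],
    "stage": eff.status[:, 0],
}).sort_values("sbm_score", ascending=False)
print(out.round(3).to_string())
rho = out["true_u"].corr(out["sbm_score"], method="spearman")
print(f"\nSpearman(truth, score) = {rho:.3f}")
print("Scores <= 1 are distances to the best-practice frontier; scores > 1 "
      "rank units that sit on it. With zero noise the ranking should track "
      "the generating efficiency closely.")
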