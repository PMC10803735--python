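"""Hierarchical Bayesian decisions on a ΔC1 table.

Fits (a) the cell-means model that asks, per group × condition ×
electrode, whether a ΔC1 is present at all (one-sided BF_+0 > 3 and 95%
HDI outside the ROPE of 0.1 × SD), (b) the reparametrized contrast model
for condition and group differences (two-sided BF_10), and (c) the
ordered-factor trend test for a suppression that grows with spatial
specificity (V > AV_i > AV_c).
"""

import numpy as np
import pandas as pd

from c1race.bayes import (
    ModelSpec,
    fit_cell_means,
    linear_trend_test,
    test_contrasts,
)

rng = np.random.default_rng(1)
rows = []
true_means = {
    "CC": {"V": 2.0, "AV_i": 1.0, "AV_c": 0.0},     # graded suppression
    "MCC": {"V": 2.0, "AV_i": 2.0, "AV_c": 2.0},    # intact control
}
for group, cells in true_means.items():
    for p in range(14):
        offset = 0.3 * rng.standard_normal()
        for cond, mu in cells.items():
            for e in ("O1", "O2", "P3", "P4", "Pz"):
                rows.append(dict(
                    participant=f"{group}{p:02d}", group=group,
                    condition=cond, electrode=e,
                    delta_c1=mu + offset + 0.5 * rng.standard_normal()))
table = pd.DataFrame(rows)

spec = ModelSpec(draws=8000, warmup=1000, seed=0)

cells = fit_cell_means(table, spec)
print("presence decisions at O1 (one-sided BF_+0 with ROPE):")
at_o1 = cells.summary[cells.summary.parameter.str.endswith(":O1")]
print(at_o1[["parameter", "mean", "hdi_low", "hdi_high",
             "decision_one_sided"]].to_string(index=False))

contrasts = test_contrasts(table, spec=spec)
print("\nsubstantial contrasts (BF_10 > 3 and HDI outside ROPE):")
hits = contrasts.summary[contrasts.summary.substantial]
print(hits[["parameter", "mean", "bf_10"]].to_string(index=False))

trend = linear_trend_test(table[table.group == "CC"], spec)
lin = trend.summary.set_index("parameter").loc["linear"]
print(f"\nCC ordered-factor linear component: {lin['mean']:.2f} µV "
      f"(BF_10 = {lin.bf_10:.3g}, {lin.decision_two_sided})")
print("A negative linear component with a large BF indicates the ΔC1 "
      "shrinks monotonically as crossmodal spatial specificity increases.")
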