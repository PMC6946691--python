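"""Sensitivity of the risk-factor ranking to the prior settings.

Re-runs the model search over grids of the prior inclusion probability p
and the prior effect variance sigma^2, and reports how stable the marginal
inclusion probabilities are across the grid.
"""

import numpy as np

from mrbma import (
    AnalysisConfig,
    PriorConfig,
    SearchConfig,
    StandardizedData,
    prior_sensitivity_sweep,
)

rng = np.random.default_rng(5)
n, d = 100, 10
X = rng.standard_normal((n, d))
y = 0.8 * X[:, 2] + 0.6 * X[:, 6] + rng.normal(0, 0.7, size=n)
data = StandardizedData(
    variant_ids=[f"rs{i}" for i in range(n)],
    rf_names=[f"rf{j}" for j in range(d)],
    beta_x=X, beta_y=y,
)

cfg = AnalysisConfig(priors=PriorConfig(max_model_size=5),
                     search=SearchConfig(mode="exhaustive", seed=0,
                                         max_model_size=5))
table = prior_sensitivity_sweep(cfg, p_grid=[0.01, 0.1, 0.3], data=data)

print("MIP of each risk factor per prior inclusion probability p:")
print(table.pivot(index="rf", columns="p", values="mip")
      .to_string(float_format="%.3f"))
print("\nSpearman rank correlation between adjacent grid points:",
      [f"{c:.3f}" for c in table.attrs["rank_correlations"]])
print("\np controls the expected number of causal factors (p x d). A")
print("robust signal keeps the same top-ranked factors across the grid")
print("even though individual model posteriors shift.")
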