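"""Comparative simulation study at desk scale.

Twelve candidate risk factors with block-correlated genetic associations,
four of which carry a true causal effect of 0.3; outcome associations
explain 30% of the variance. Each method estimates the causal effects and
ranks the factors; mean squared error (MSE) and ROC AUC are reported over
25 repetitions (the full benchmark uses 1000).
"""

from mrbma import SimulationConfig, run_simulation_study

cfg = SimulationConfig(n_variants=150, d_risk_factors=12,
                       n_causal_positive=4, theta_magnitude=0.3,
                       r_squared=0.3, n_reps=25, seed=3)
res = run_simulation_study(cfg)

print(res.mse_table().to_string(index=False, float_format="%.4f"))
print("\nLower MSE = better causal-effect estimation; higher AUC = better")
print("separation of causal from non-causal risk factors. Expect the")
print("model-averaging approach and the penalised regressions to beat")
print("unregularised IVW, whose unbiased estimates pay a high variance")
print("price under strongly correlated risk factors.")
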