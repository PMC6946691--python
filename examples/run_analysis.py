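"""Full analysis on a small synthetic two-sample summary dataset.

Builds exposure and outcome summary files for 60 variants and 8 candidate
risk factors, of which two (hdl_xl and apoa1) truly affect the outcome,
then runs the complete pipeline: harmonization, standardization,
correlation pruning, exhaustive Bayesian model search, and diagnostics.
"""

import tempfile
from pathlib import Path

import numpy as np

from mrbma import AnalysisConfig, PriorConfig, SearchConfig, run_full_analysis

rng = np.random.default_rng(7)
n, names = 60, ["ldl", "hdl_xl", "hdl_m", "tg", "apoa1", "apob", "glc", "ala"]
se_y = rng.uniform(0.02, 0.08, size=n)
beta_x = rng.standard_normal((n, len(names))) * 0.1
beta_y = (0.4 * beta_x[:, 1] + 0.3 * beta_x[:, 4]
          + rng.normal(0, 0.5, size=n) * se_y / se_y.mean() * 0.05)

tmp = Path(tempfile.mkdtemp())
with open(tmp / "exposures.tsv", "w") as fh:
    fh.write("rsid\t" + "\t".join(f"beta_{c}" for c in names) + "\n")
    for i in range(n):
        fh.write(f"rs{i}\t" + "\t".join(f"{v:.6f}" for v in beta_x[i]) + "\n")
with open(tmp / "outcome.tsv", "w") as fh:
    fh.write("rsid\tbeta_out\tse_out\n")
    for i in range(n):
        fh.write(f"rs{i}\t{beta_y[i]:.6f}\t{se_y[i]:.6f}\n")

cfg = AnalysisConfig(
    path_x=str(tmp / "exposures.tsv"),
    path_y=str(tmp / "outcome.tsv"),
    priors=PriorConfig(sigma2=0.25, p_inclusion=0.1, max_model_size=8),
    search=SearchConfig(mode="exhaustive", seed=0, max_model_size=8),
    out_dir=str(tmp / "out"),
)
result, reports = run_full_analysis(cfg)

print("Risk factors ranked by marginal inclusion probability (MIP):")
print(result.ranking().to_string(index=False, float_format="%.3f"))
print("\nBest models (posterior probability > 0.02):")
for s in result.top_models(0.02):
    members = ", ".join(result.rf_names[j] for j in s.model.indices) or "(null)"
    print(f"  PP={s.posterior_prob:.3f}  {{{members}}}")
print("\nA MIP near 1 means the factor appears in essentially every")
print("well-supported model; the MACE column is the posterior-weighted")
print("(conservative, shrunk-toward-zero) direct causal effect estimate.")
print(f"\nAll artifacts (TSVs + run manifest) in {tmp/'out'}")
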