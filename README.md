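# mrbma — Bayesian risk-factor selection for multivariable Mendelian randomization

`mrbma` selects likely causal risk factors from high-dimensional,
highly correlated candidate sets (e.g. NMR metabolite panels or blood cell
traits) using two-sample GWAS summary statistics. It is aimed at genetic
epidemiologists who have an n × d matrix of variant–risk-factor association
estimates β<sub>X</sub>, variant–outcome estimates β<sub>Y</sub> with standard
errors, and want to know *which* of the d risk factors drive the outcome —
a question that multivariable inverse-variance weighted (IVW) regression
answers poorly when d is large and the risk factors are correlated.

## The model

After dividing both sides by se(β<sub>Y</sub>) (so every variant has unit
error variance), risk-factor selection is variable selection in the weighted
linear model

&nbsp;&nbsp;β<sub>Y</sub> | β<sub>X</sub>, θ, τ ∼ N(β<sub>X</sub> θ, 1/τ)

with conjugate priors θ ∼ N(0, σ²/τ·I) on the causal effects of the
included factors. For each subset γ of risk factors the Bayes factor against
the null model is available in closed form:

&nbsp;&nbsp;BF(M<sub>γ</sub>) = |Ω|<sup>1/2</sup> |ν<sub>γ</sub>|<sup>−1/2</sup> ·
((β<sub>Y</sub>ᵗβ<sub>Y</sub> − ΘᵗΩ<sup>−1</sup>Θ)/β<sub>Y</sub>ᵗβ<sub>Y</sub>)<sup>−n/2</sup>,
&nbsp;&nbsp;Ω = (ν<sub>γ</sub><sup>−1</sup> + β<sub>Xγ</sub>ᵗβ<sub>Xγ</sub>)<sup>−1</sup>,
&nbsp;&nbsp;Θ = Ω β<sub>Xγ</sub>ᵗβ<sub>Y</sub>,

where Θ is also the ridge-type shrinkage estimate of the causal effects.
Combining BF with the independent-Bernoulli model prior p<sup>k</sup>(1−p)<sup>d−k</sup>
gives each model's posterior probability (PP); averaging over models yields

* **MIP** — each factor's marginal inclusion probability (the ranking statistic), and
* **MACE** — the model-averaged, deliberately conservative causal-effect estimate.

Small model spaces are enumerated exhaustively; large ones (d > 20) are
explored by a shotgun stochastic search over add/delete/swap neighbourhoods.
Per-model instrument diagnostics (q-statistic for outliers, Cook's distance
under the shrinkage hat matrix for influence) flag potentially pleiotropic
or dominating variants, and a multivariable IVW baseline plus a simulation
framework (MSE / bias / ROC against Lars, Lasso, Elastic Net) complete the
toolkit.

## Worked example

`python examples/run_analysis.py` builds a synthetic 60-variant, 8-factor
dataset in which `hdl_xl` and `apoa1` truly affect the outcome, then runs the
full pipeline:

```
Risk factors ranked by marginal inclusion probability (MIP):
    rf   mip   mace
hdl_xl 1.000  0.918
 apoa1 1.000  0.817
   glc 0.056 -0.005
 hdl_m 0.051  0.004
   ...
Best models (posterior probability > 0.02):
  PP=0.785  {hdl_xl, apoa1}
  PP=0.047  {hdl_xl, apoa1, glc}
  ...
```

The two causal factors get MIP ≈ 1 (present in every well-supported model)
while the noise factors sit near the prior floor; the MACE column gives their
shrunk direct-effect estimates on the standardized scale. The pair model
alone carries 79% of the posterior mass. `examples/` also contains short
scripts for the simulation study, the pleiotropic-variant diagnostics and
the prior-sensitivity sweep.

The same pipeline is available from the shell:

```bash
mrbma analyze --exposures exposures.tsv --outcome outcome.tsv --seed 1 --out-dir out/
mrbma diagnose --exposures ... --outcome ... --model hdl_xl,apoa1
mrbma simulate --reps 100 --seed 1
mrbma sweep --exposures ... --outcome ... --p-grid 0.01,0.1,0.3
```

Input files are delimited text with a header: a variant-id column (`rsid`),
`beta_<factor>` columns for the exposures, `beta_out`/`se_out` for the
outcome, and optional `ea`/`oa` allele columns (harmonized automatically).

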