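# Methods

## Model and scoring

The package treats two-sample multivariable Mendelian randomization as
variable selection in a weighted linear model of summary statistics. Inputs
are per-variant association estimates: β*<sub>X</sub> (n variants × d risk
factors), β*<sub>Y</sub> and se(β*<sub>Y</sub>) (length n). Dividing both
sides by se(β*<sub>Y</sub>) makes every variant's error variance 1, so
ordinary least squares on the transformed scale equals inverse-variance
weighted regression on the raw scale; all internal computation uses this
standardized scale.

For a subset γ of risk factors the likelihood is
β<sub>Y</sub> ∼ N(β<sub>Xγ</sub> θ<sub>γ</sub>, 1/τ) with conjugate priors
θ<sub>γ</sub> ∼ N(0, ν<sub>γ</sub>/τ), ν<sub>γ</sub> = σ²I, and a Gamma
prior on the precision τ. Both θ and τ integrate out analytically, leaving
the closed-form Bayes factor against the empty (null) model

BF(M<sub>γ</sub>) = |Ω|<sup>1/2</sup>|ν<sub>γ</sub>|<sup>−1/2</sup>
((yᵗy − ΘᵗΩ<sup>−1</sup>Θ)/yᵗy)<sup>−n/2</sup>,
 Ω = (ν<sub>γ</sub><sup>−1</sup> + XᵗX)<sup>−1</sup>, Θ = ΩXᵗy,

with X = β<sub>Xγ</sub>, y = β<sub>Y</sub>. Θ is simultaneously the
reported shrinkage (ridge-type) causal-effect estimate. The model prior is
independent-Bernoulli, p per factor, so a model of size k has prior
p<sup>k</sup>(1−p)<sup>d−k</sup>. Posterior probabilities, marginal
inclusion probabilities (MIP) and model-averaged causal effects (MACE)
follow by normalization and averaging.

Numerical choices: Ω is never formed explicitly — each model costs one
k × k Cholesky factorization of Ω<sup>−1</sup> = σ<sup>−2</sup>I + XᵗX,
which is positive definite for any σ² > 0; log-determinants come from the
Cholesky diagonal, ΘᵗΩ<sup>−1</sup>Θ from the identity (Xᵗy)ᵗΘ; all scores
are kept in log space and normalized by log-sum-exp, so enumeration at
d ≈ 100 cannot underflow. The residual term yᵗy − (Xᵗy)ᵗΘ is floored at
the smallest positive double for exactly interpolating fits. Cross-products
XᵗX and Xᵗy are precomputed once per dataset and subset per model.

The empty model is a member of the enumerated space with BF = 1 and prior
(1−p)<sup>d</sup>; it affects only the normalization and gives the null
hypothesis a posterior foothold (a flag excludes it for parity with
implementations that rank only non-empty models).

## Defaults

| parameter | default | meaning |
|---|---|---|
| σ² | 0.25 | prior variance of a causal effect on the standardized scale (sd 0.5) |
| p | 0.1 | prior inclusion probability; expected model size p·d |
| max model size | 12 | hard cap on subset size |
| pruning threshold | 0.99 | drop one of each risk-factor pair with \|r\| above it |
| shotgun iterations | 10,000 (100,000 via the workflow default) | search length |
| q threshold | 10 | outlier flag on the per-variant heterogeneity statistic |
| PP inspection threshold | 0.02 | models diagnosed individually |

These mirror the applied-analysis convention for metabolite panels. The
two pruning conventions in circulation (0.99 for simulation inputs, 0.985
for applied analyses) are both reachable through the `prune_threshold`
parameter.

## Search

Exhaustive enumeration is used up to d = 20 (2<sup>20</sup> models); above
that a shotgun stochastic search starts from the empty model (optionally
the best single-factor model), scores the full add/delete/swap
neighbourhood of the current model, and moves to a neighbour with
probability proportional to prior × BF. Every model is memoized and scored
at most once; the posterior normalizer is approximated by the sum over all
visited models, on the assumption that the unvisited bulk has negligible
mass. The move set is the standard one from the shotgun-stochastic-search
literature; the visited-set normalization means repeat visits do not
re-count. For d ≤ 12 with a few thousand iterations the visited set
contains every non-negligible model and the MIPs agree with exhaustive
enumeration to < 1e−6 (tested).

## Diagnostics

For each model with PP above the inspection threshold the package reports
per-variant q-statistics q<sub>i</sub> = (β<sub>Yi</sub> − β̂<sub>Yi</sub>)²
(equivalently the 1/se² -weighted squared residual on the raw scale) and
Cook's distances Cd<sub>i</sub> = q<sub>i</sub>/(s²d<sub>m</sub>) ·
h<sub>i</sub>/(1−h<sub>i</sub>)² under the shrinkage hat matrix
H = X(ν<sub>γ</sub><sup>−1</sup>+XᵗX)<sup>−1</sup>Xᵗ. Here d<sub>m</sub>
is taken to be the size of the fitted model and s² the residual mean square
on n − d<sub>m</sub> degrees of freedom — the classical Cook's-distance
convention for the number of fitted parameters; with a diffuse prior
(σ² → ∞) the statistic reduces exactly to textbook Cook's distance, which
the tests verify against an independent implementation. Variants with
q > 10 are flagged as outliers and variants with Cd above the median of
F(d<sub>m</sub>, n−d<sub>m</sub>) as influential. Variants flagged in
*every* top model are reported for a user-driven exclude-and-refit run;
nothing is removed automatically, keeping the analyst in the loop.

## IVW baseline

Multivariable IVW is the no-intercept least-squares fit on the standardized
scale (= raw-scale WLS with weights 1/se²; tested against an independent
WLS implementation). In multiplicative random-effects mode standard errors
are inflated by √φ, φ = max(1, RSS/(n−d)): overdispersion widens but never
narrows them. The full-model shrinkage estimate converges to the IVW point
estimate as σ² → ∞.

## Synthetic-data generator and simulation study

The benchmark design this framework reproduces uses real metabolite /
blood-cell association matrices, which are not redistributable here; a
block-correlated Gaussian generator stands in. Defaults: n = 150 variants,
d = 12 factors in three blocks of four with within-block correlation 0.9
(uncorrelated across blocks), columns scaled to unit sample variance.
The 0.9 default reflects what survives the |r| > 0.99 de-duplication step
in real lipoprotein-subfraction panels, whose within-cluster genetic
correlations routinely exceed 0.9 — the strong-correlation regime is
precisely what makes unregularised IVW high-variance and motivates model
averaging. A user-supplied matrix file can replace the generator for runs
on real data.

Outcomes: per repetition a causal subset is drawn at random (Setting A:
four effects of +0.3; Setting B adds four of −0.3), the signal is
s = β<sub>X</sub>θ, and i.i.d. Gaussian noise is added with variance
var(s)(1−R²)/R² calibrated from the *realized* signal variance, so the
expected explained proportion equals R²; se<sub>Y</sub> ≡ 1. An empty
causal set is the null configuration (pure unit noise). Methods compared:
IVW (ranking score |t|), cross-validated Lars/Lasso/Elastic Net from
scikit-learn (ranking |coefficient|), the model average (estimate MACE,
ranking MIP) and best-model selection (top-PP model's estimates, zeros
elsewhere). MSE pools squared errors over all factors and repetitions
(a switch restricts to causal factors); ROC curves pool ranking scores
over repetitions. The reported MSE decomposes exactly into squared bias
plus variance (tested to 1e−10).

What the generator does *not* emulate: realistic minor-allele-frequency
and instrument-strength heterogeneity, LD between variants, non-Gaussian
association errors, and the exact correlation spectra of real panels.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative method ordering under strong correlation, not quantitative
error rates on any particular real dataset. Desk-scale runs use 100
repetitions (the full benchmark convention is 1000) and the d = 12 small
space; these sizes are the package's test-bed choices and are stated in
each test.

## Weak-instrument bias

For two risk factors with observed associations contaminated by estimation
error (noise-to-signal ratios λ₁, λ₂; observed correlation ρ), the expected
IVW estimates are

θ̂₁ = θ₁ − (θ₁λ₁ − ρθ₂λ₂)/(1−ρ), θ̂₂ symmetric.

This is a first-order approximation from the measurement-error literature,
implemented exactly in this printed form. Caveat: for correlated observed
associations (ρ ≠ 0) a standard errors-in-variables expansion yields a
(1−ρ²) denominator, so the two forms diverge at first order away from
ρ = 0; the Monte-Carlo cross-check in the test suite therefore validates
the formula in the uncorrelated case, where it is first-order exact, and
the function's docstring carries the same caveat.

## Known limitations

* MACE values carry no standard errors or credible intervals by design —
  they are comparative, conservatively shrunk estimates, not absolute
  effect sizes.
* Allele harmonization handles simple effect/other flips only;
  strand-ambiguous palindromic variants pass through with a warning.
* Correlation pruning is greedy (deterministically dropping the
  later-listed member of the currently worst pair by default; a
  seed-controlled random choice is available), which need not find the
  largest surviving subset.
* The shotgun search gives no guarantee of visiting all relevant models at
  very large d; the monotone growth of the visited-set evidence with
  iterations is the practical convergence signal.
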