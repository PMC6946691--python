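"""Synthetic-data generation and the comparative simulation study.

Emulates the evaluation design used to benchmark model-averaged risk-factor
selection: a fixed n x d matrix of genetic associations with candidate risk
factors (in the benchmark these come from real metabolite / blood-cell
GWAS; here a block-correlated Gaussian generator stands in), outcome
associations simulated from a sparse causal vector with a controlled
explained-variance proportion R^2, and repeated fitting of several
methods — multivariable IVW, cross-validated Lars/Lasso/Elastic-Net, the
Bayesian model average (MACE/MIP) and best-model selection — scored by MSE
against the true effects and by ROC curves for causal-factor ranking.

The analytic weak-instrument bias of the two-risk-factor IVW fit, derived
from the measurement-error literature, lives here too, together with its
Monte-Carlo counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV, LarsCV, LassoCV
from sklearn.metrics import roc_curve

from .core import PriorConfig
from .data import StandardizedData, ValidationError
from .ivw import multivariable_ivw
from .search import SearchConfig, run_search

__all__ = [
    "SimulationConfig",
    "BiasParams",
    "StudyResult",
    "generate_beta_x",
    "simulate_outcome",
    "roc_points",
    "run_simulation_study",
    "weak_instrument_bias",
    "weak_instrument_bias_mc",
    "METHODS",
]

#: default block-correlation structure of the synthetic association matrix:
#: (number of factors, within-block correlation) — remaining factors are
#: uncorrelated. Mimics the strongly clustered genetic-association
#: correlation of lipoprotein subfraction measures, where within-cluster
#: correlations routinely exceed 0.9 and only near-duplicates (|r| > 0.99)
#: are pruned before analysis.
DEFAULT_BLOCKS: tuple[tuple[int, float], ...] = ((4, 0.9), (4, 0.9), (4, 0.9))

METHODS = ("IVW", "Lars", "Lasso", "ElasticNet", "MR-BMA", "BestModel")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions.

    Defaults mirror the small-risk-factor-space benchmark cell: d = 12
    candidate risk factors of which 4 carry a positive effect of 0.3
    (Setting A; Setting B adds 4 negative effects), R^2 = 0.3 of outcome
    association variance explained, n = 150 variants.
    """

    n_variants: int = 150
    d_risk_factors: int = 12
    n_causal_positive: int = 4
    n_causal_negative: int = 0
    theta_magnitude: float = 0.3
    r_squared: float = 0.3
    n_reps: int = 100
    seed: int = 0
    correlation_blocks: tuple[tuple[int, float], ...] = DEFAULT_BLOCKS
    beta_x_file: str | None = None  # real association matrix, overrides generator
    mse_causal_only: bool = False

    def __post_init__(self) -> None:
        if self.n_causal_positive + self.n_causal_negative > self.d_risk_factors:
            raise ValidationError("more causal factors than risk factors")
        if not 0.0 < self.r_squared < 1.0:
            raise ValidationError("r_squared must lie in (0, 1)")
        if sum(b[0] for b in self.correlation_blocks) > self.d_risk_factors:
            raise ValidationError("correlation blocks exceed d_risk_factors")

    @property
    def n_causal(self) -> int:
        return self.n_causal_positive + self.n_causal_negative


@dataclass(frozen=True)
class BiasParams:
    """Inputs to the two-risk-factor weak-instrument bias formula."""

    theta1: float
    theta2: float
    lambda1: float  # var(estimation error) / var(true association), factor 1
    lambda2: float
    rho: float  # correlation between the observed associations

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1.0:
            raise ValidationError("|rho| must be < 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("noise-to-signal ratios must be nonnegative")


@dataclass
class StudyResult:
    config: SimulationConfig
    methods: tuple[str, ...]
    mse_by_method: dict[str, float]
    bias_by_method: dict[str, float]  # mean estimation error, pooled
    variance_by_method: dict[str, float]
    auc_by_method: dict[str, float]
    roc_by_method: dict[str, np.ndarray]  # (FPR, TPR) rows
    bias_tables: dict[str, pd.DataFrame]  # per-factor mean/sd of errors
    n_failures: dict[str, int]
    errors_by_method: dict[str, np.ndarray]  # reps x d, estimate - truth
    truth_matrix: np.ndarray  # reps x d boolean, causal indicator
    truth_values: np.ndarray  # reps x d, true causal effects

    def mse_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"method": list(self.methods),
             "mse": [self.mse_by_method[m] for m in self.methods],
             "auc": [self.auc_by_method[m] for m in self.methods]}
        )


def _correlation_matrix(d: int, blocks) -> np.ndarray:
    corr = np.eye(d)
    start = 0
    for size, r in blocks:
        if not -1.0 < r < 1.0:
            raise ValidationError("block correlation must lie in (-1, 1)")
        block = np.full((size, size), r)
        np.fill_diagonal(block, 1.0)
        corr[start:start + size, start:start + size] = block
        start += size
    return corr


def generate_beta_x(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> StandardizedData:
    """Draw a standardized n x d association matrix with block correlation.

    Columns are scaled to unit sample variance, matching the pre-processing
    applied to real association matrices before model selection.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.beta_x_file is not None:
        frame = pd.read_csv(cfg.beta_x_file, sep=None, engine="python")
        ids = frame.iloc[:, 0].astype(str).tolist()
        X = frame.iloc[:, 1:].to_numpy(dtype=float)
        names = list(frame.columns[1:])
    else:
        n, d = cfg.n_variants, cfg.d_risk_factors
        corr = _correlation_matrix(d, cfg.correlation_blocks)
        try:
            L = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("correlation structure not positive definite") from exc
        X = rng.standard_normal((n, d)) @ L.T
        ids = [f"rs{i + 1}" for i in range(n)]
        names = [f"rf{j + 1}" for j in range(d)]
    X = X / X.std(axis=0, ddof=1)
    return StandardizedData(
        variant_ids=ids, rf_names=names, beta_x=X,
        beta_y=np.zeros(X.shape[0]),
    )


def simulate_outcome(
    beta_x: np.ndarray,
    causal_idx: np.ndarray,
    theta: np.ndarray,
    r_squared: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Outcome associations from a sparse causal vector plus calibrated noise.

    The signal is s = beta_x @ theta_full; i.i.d. Gaussian noise is added
    with variance var(s) (1 - R^2) / R^2, computed from the realized signal
    variance, so the expected explained proportion equals R^2. Standard
    errors are 1 (the data are already on the standardized scale).
    """
    if not 0.0 < r_squared < 1.0:
        raise ValidationError("r_squared must lie in (0, 1)")
    n, d = beta_x.shape
    causal_idx = np.asarray(causal_idx, dtype=int)
    if causal_idx.size == 0:
        # null configuration: outcome associations are pure unit noise
        return rng.standard_normal(n), np.ones(n)
    theta_full = np.zeros(d)
    theta_full[causal_idx] = theta
    signal = beta_x @ theta_full
    var_s = signal.var()
    if var_s == 0.0:
        raise ValidationError("causal signal is identically zero but R^2 > 0")
    noise_sd = np.sqrt(var_s * (1.0 - r_squared) / r_squared)
    beta_y = signal + rng.normal(0.0, noise_sd, size=n)
    return beta_y, np.ones(n)


def roc_points(
    ranking_scores: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a descending threshold sweep, and trapezoid AUC."""
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(ranking_scores, dtype=float)
    if truth.all() or not truth.any():
        raise ValidationError("truth vector needs at least one positive and one negative")
    fpr, tpr, _ = roc_curve(truth, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _fit_method(method: str, data: StandardizedData, cfg: SimulationConfig,
                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-factor causal estimates and ranking scores for one repetition."""
    X, y = data.beta_x, data.beta_y
    d = X.shape[1]
    if method == "IVW":
        res = multivariable_ivw(data)
        return res.theta, np.abs(res.z)
    if method in {"Lars", "Lasso", "ElasticNet"}:
        est = {
            "Lars": LarsCV(fit_intercept=False, cv=5),
            "Lasso": LassoCV(fit_intercept=False, cv=5, random_state=seed),
            "ElasticNet": ElasticNetCV(fit_intercept=False, cv=5, random_state=seed),
        }[method]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
        coef = np.asarray(est.coef_)
        return coef, np.abs(coef)
    if method in {"MR-BMA", "BestModel"}:
        # small space: exhaustive with p = 0.5; larger: shotgun with p = 0.1
        if d <= 20:
            priors = PriorConfig(sigma2=0.25, p_inclusion=0.5, max_model_size=d)
            search = SearchConfig(mode="exhaustive", seed=seed,
                                  max_model_size=d)
        else:
            priors = PriorConfig(sigma2=0.25, p_inclusion=0.1,
                                 max_model_size=min(d, 12))
            search = SearchConfig(mode="shotgun", iterations=10_000, seed=seed,
                                  max_model_size=min(d, 12))
        result = run_search(data, priors, search)
        if method == "MR-BMA":
            return result.mace, result.mip
        best = result.models[0]
        est_vec = np.zeros(d)
        for pos, j in enumerate(best.model.indices):
            est_vec[j] = best.theta_hat[pos]
        return est_vec, result.mip
    raise ValidationError(f"unknown method {method!r}")


def run_simulation_study(
    cfg: SimulationConfig, methods: tuple[str, ...] = METHODS
) -> StudyResult:
    """Repeatedly simulate outcomes over a fixed association matrix and score methods.

    Per repetition the causal subset is drawn at random, the outcome
    associations are simulated, every method is fitted, and its per-factor
    estimates and ranking scores are recorded. MSE pools squared estimation
    errors over factors and repetitions (optionally causal factors only);
    ROC curves pool ranking scores over repetitions.
    """
    if not methods:
        raise ValidationError("need at least one method")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown methods: {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    base = generate_beta_x(cfg, rng)
    d = base.n_risk_factors

    errors = {m: [] for m in methods}  # estimate - truth, per rep (length d)
    scores = {m: [] for m in methods}
    truths: list[np.ndarray] = []
    truth_vals: list[np.ndarray] = []
    failures = {m: 0 for m in methods}

    for rep in range(cfg.n_reps):
        causal = rng.choice(d, size=cfg.n_causal, replace=False)
        theta = np.concatenate([
            np.full(cfg.n_causal_positive, cfg.theta_magnitude),
            np.full(cfg.n_causal_negative, -cfg.theta_magnitude),
        ])
        beta_y, _ = simulate_outcome(base.beta_x, causal, theta,
                                     cfg.r_squared, rng)
        data = StandardizedData(
            variant_ids=base.variant_ids, rf_names=base.rf_names,
            beta_x=base.beta_x, beta_y=beta_y,
        )
        truth_vec = np.zeros(d)
        truth_vec[causal] = theta
        truth_bool = truth_vec != 0
        rep_seed = int(rng.integers(2**31 - 1))
        truths.append(truth_bool)
        truth_vals.append(truth_vec)
        for m in methods:
            try:
                est, score = _fit_method(m, data, cfg, rep_seed)
            except Exception:
                failures[m] += 1
                errors[m].append(np.full(d, np.nan))
                scores[m].append(np.full(d, np.nan))
                continue
            errors[m].append(est - truth_vec)
            scores[m].append(score)

    truth_mat = np.array(truths)
    mse, bias, var, auc, roc, tables = {}, {}, {}, {}, {}, {}
    for m in methods:
        err = np.array(errors[m])
        if cfg.mse_causal_only:
            sel = truth_mat
            pooled = err[sel]
        else:
            pooled = err.ravel()
        pooled = pooled[~np.isnan(pooled)]
        mse[m] = float(np.mean(pooled**2))
        bias[m] = float(np.mean(pooled))
        var[m] = float(np.var(pooled))
        sc = np.array(scores[m])
        ok = ~np.isnan(sc).any(axis=1)
        pooled_truth = truth_mat[ok].ravel()
        if pooled_truth.any() and not pooled_truth.all():
            roc[m], auc[m] = roc_points(sc[ok].ravel(), pooled_truth)
        else:  # null configuration: ranking quality is undefined
            roc[m], auc[m] = np.empty((0, 2)), float("nan")
        tables[m] = pd.DataFrame({
            "rf": base.rf_names,
            "mean_error": np.nanmean(err, axis=0),
            "sd_error": np.nanstd(err, axis=0, ddof=1),
        })
    return StudyResult(
        config=cfg, methods=tuple(methods), mse_by_method=mse,
        bias_by_method=bias, variance_by_method=var, auc_by_method=auc,
        roc_by_method=roc, bias_tables=tables, n_failures=failures,
        errors_by_method={m: np.array(errors[m]) for m in methods},
        truth_matrix=truth_mat, truth_values=np.array(truth_vals),
    )


def weak_instrument_bias(params: BiasParams) -> tuple[float, float]:
    """Expected IVW estimates under measurement error in the associations.

    theta1_hat = theta1 - (theta1 lambda1 - rho theta2 lambda2) / (1 - rho)
    and symmetrically for theta2. A first-order approximation, accurate for
    small noise-to-signal ratios; exact attenuation when the two observed
    association vectors are uncorrelated and the ratios are small.
    """
    t1, t2 = params.theta1, params.theta2
    l1, l2, rho = params.lambda1, params.lambda2, params.rho
    denom = 1.0 - rho
    theta1_hat = t1 - (t1 * l1 - rho * t2 * l2) / denom
    theta2_hat = t2 - (t2 * l2 - rho * t1 * l1) / denom
    return theta1_hat, theta2_hat


def weak_instrument_bias_mc(
    params: BiasParams,
    n_variants: int = 2000,
    n_reps: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo counterpart: inject measurement error and refit IVW.

    True associations are bivariate normal with unit variances and the
    correlation that yields the requested observed correlation; estimation
    error of variance lambda_j is added to column j; the error-free outcome
    is regressed on the noisy associations. Returns the mean estimate pair
    and its Monte-Carlo standard errors.
    """
    rng = np.random.default_rng(seed)
    l1, l2, rho = params.lambda1, params.lambda2, params.rho
    rho_true = rho * np.sqrt((1.0 + l1) * (1.0 + l2))
    if not abs(rho_true) < 1.0:
        raise ValidationError("requested observed correlation unattainable")
    L = np.linalg.cholesky(np.array([[1.0, rho_true], [rho_true, 1.0]]))
    theta = np.array([params.theta1, params.theta2])
    noise_sd = np.sqrt([l1, l2])
    est = np.empty((n_reps, 2))
    for r in range(n_reps):
        true_x = rng.standard_normal((n_variants, 2)) @ L.T
        y = true_x @ theta
        X = true_x + rng.standard_normal((n_variants, 2)) * noise_sd
        est[r] = np.linalg.lstsq(X, y, rcond=None)[0]
    return est.mean(axis=0), est.std(axis=0, ddof=1) / np.sqrt(n_reps)
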