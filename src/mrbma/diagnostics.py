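"""Outlier and influence diagnostics for fitted risk-factor models.

A genetic variant that acts on the outcome through a pathway not captured
by the selected risk factors (unmeasured pleiotropy) shows up as an outlier
to the model fit; a variant with an unusually strong outcome association
can dominate the selection. Two per-variant statistics quantify this for a
given model:

* the q-statistic, the variant's contribution to the heterogeneity
  Q-statistic: q_i = (beta_Y[i] - predicted[i])^2 on the standardized
  scale (equivalently the se-weighted squared residual on the raw scale);
* Cook's distance under the shrinkage hat matrix
  H = X (nu^{-1} + X'X)^{-1} X', combining the residual with the
  leverage h_i = H[i, i].

Variants with q above a fixed threshold (default 10) are flagged as
outliers; variants with Cook's distance above the median of the
F(d_m, n - d_m) reference distribution are flagged as influential, where
d_m is the number of fitted risk factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import f as f_dist

from .core import BMAResult, ModelScorer, ModelSpec
from .data import StandardizedData, ValidationError

__all__ = [
    "DiagnosticReport",
    "predicted_outcome_associations",
    "q_contributions",
    "q_contributions_raw",
    "cooks_distances",
    "influence_threshold",
    "flag_variants",
    "diagnose_model",
    "diagnose_top_models",
    "consistent_flags",
    "write_report",
    "write_scatter_data",
]

Q_THRESHOLD_DEFAULT = 10.0


@dataclass
class DiagnosticReport:
    model: ModelSpec
    variant_ids: list[str]
    predicted_beta_y: np.ndarray
    q_contributions: np.ndarray
    q_total: float
    cooks_distance: np.ndarray
    leverages: np.ndarray
    s2: float
    cd_threshold: float
    outlier_flags: np.ndarray | None = None
    influential_flags: np.ndarray | None = None

    def flagged_variants(self) -> list[str]:
        """Identifiers flagged as outlying or influential, for exclude-and-refit."""
        if self.outlier_flags is None or self.influential_flags is None:
            raise ValidationError("report has not been flagged yet")
        mask = self.outlier_flags | self.influential_flags
        return [v for v, m in zip(self.variant_ids, mask) if m]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "rsid": self.variant_ids,
            "predicted_beta_y": self.predicted_beta_y,
            "q": self.q_contributions,
            "cooks_d": self.cooks_distance,
            "leverage": self.leverages,
        })
        if self.outlier_flags is not None:
            frame["outlier"] = self.outlier_flags
            frame["influential"] = self.influential_flags
        return frame


def predicted_outcome_associations(
    model: ModelSpec, data: StandardizedData, theta_hat: np.ndarray
) -> np.ndarray:
    """Predicted standardized outcome associations beta_X[gamma] @ theta_hat."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta_hat.shape != (model.size,):
        raise ValidationError(
            f"theta_hat length {theta_hat.size} != model size {model.size}"
        )
    if model.size == 0:
        return np.zeros(data.n_variants)
    return data.beta_x[:, list(model.indices)] @ theta_hat


def q_contributions(
    beta_y: np.ndarray, predicted: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-variant squared residuals on the standardized scale, and their sum."""
    beta_y = np.asarray(beta_y, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if beta_y.shape != predicted.shape:
        raise ValidationError("observed and predicted vectors differ in length")
    q = (beta_y - predicted) ** 2
    return q, float(q.sum())


def q_contributions_raw(
    beta_y_raw: np.ndarray, predicted_raw: np.ndarray, se_y_raw: np.ndarray
) -> tuple[np.ndarray, float]:
    """Raw-scale form: residuals weighted by 1/se(beta_y)^2.

    Algebraically identical to :func:`q_contributions` applied to the
    standardized quantities.
    """
    q = ((np.asarray(beta_y_raw) - np.asarray(predicted_raw))
         / np.asarray(se_y_raw)) ** 2
    return q, float(q.sum())


def influence_threshold(d_m: int, n: int) -> float:
    """Median of the F(d_m, n - d_m) reference distribution."""
    if d_m < 1 or n <= d_m:
        raise ValidationError(f"invalid degrees of freedom: d_m={d_m}, n={n}")
    return float(f_dist.ppf(0.5, d_m, n - d_m))


def cooks_distances(
    model: ModelSpec, data: StandardizedData, sigma2: float
) -> DiagnosticReport:
    """Cook's distances and leverages of every variant under one model.

    Cd_i = q_i / (s^2 d_m) * h_i / (1 - h_i)^2 with d_m the fitted model
    size, s^2 the residual mean square on n - d_m degrees of freedom, and
    h_i the diagonal of the shrinkage hat matrix. As sigma2 grows the hat
    matrix approaches the ordinary projection and Cd_i the classical
    Cook's distance.
    """
    k = model.size
    n = data.n_variants
    if n <= k:
        raise ValidationError(f"need n > model size ({n} <= {k})")
    if k == 0:
        raise ValidationError("diagnostics are undefined for the empty model")

    scorer = ModelScorer(data, sigma2)
    _, theta = scorer.score(model)
    idx = list(model.indices)
    X = data.beta_x[:, idx]
    predicted = X @ theta
    q, q_total = q_contributions(data.beta_y, predicted)

    A = scorer.gram[np.ix_(idx, idx)] + np.eye(k) / sigma2
    cho = cho_factor(A, lower=True)
    # h_i = x_i' A^{-1} x_i via one triangular solve per column block
    h = np.einsum("ij,ji->i", X, cho_solve(cho, X.T))

    resid = data.beta_y - predicted
    s2 = float(resid @ resid) / (n - k)
    with np.errstate(divide="ignore"):
        cd = q / (s2 * k) * h / (1.0 - h) ** 2
    cd = np.where(h >= 1.0, np.inf, cd)

    return DiagnosticReport(
        model=model,
        variant_ids=list(data.variant_ids),
        predicted_beta_y=predicted,
        q_contributions=q,
        q_total=q_total,
        cooks_distance=cd,
        leverages=h,
        s2=s2,
        cd_threshold=influence_threshold(k, n),
    )


def flag_variants(
    report: DiagnosticReport, q_threshold: float = Q_THRESHOLD_DEFAULT
) -> DiagnosticReport:
    """Mark outliers (q above threshold) and influential points (Cd above F-median)."""
    report.outlier_flags = report.q_contributions > q_threshold
    report.influential_flags = report.cooks_distance > report.cd_threshold
    return report


def diagnose_model(
    model: ModelSpec,
    data: StandardizedData,
    sigma2: float,
    q_threshold: float = Q_THRESHOLD_DEFAULT,
) -> DiagnosticReport:
    """Full per-variant diagnostic report for one model, with flags."""
    return flag_variants(cooks_distances(model, data, sigma2), q_threshold)


def diagnose_top_models(
    result: BMAResult,
    data: StandardizedData,
    sigma2: float,
    pp_threshold: float = 0.02,
    q_threshold: float = Q_THRESHOLD_DEFAULT,
) -> list[DiagnosticReport]:
    """Diagnostic reports for every model with posterior probability above threshold."""
    return [
        diagnose_model(s.model, data, sigma2, q_threshold)
        for s in result.top_models(pp_threshold)
        if s.model.size > 0
    ]


def consistent_flags(reports: list[DiagnosticReport]) -> list[str]:
    """Variants flagged in every supplied report — candidates for exclusion."""
    if not reports:
        return []
    sets = [set(r.flagged_variants()) for r in reports]
    common = set.intersection(*sets)
    return [v for v in reports[0].variant_ids if v in common]


def write_report(report: DiagnosticReport, path: str) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_scatter_data(
    report: DiagnosticReport, data: StandardizedData, path: str
) -> None:
    """Predicted-vs-observed scatter table for plotting."""
    pd.DataFrame({
        "rsid": report.variant_ids,
        "predicted_beta_y": report.predicted_beta_y,
        "observed_beta_y": data.beta_y,
        "q": report.q_contributions,
        "cooks_d": report.cooks_distance,
    }).to_csv(path, sep="\t", index=False, float_format="%.6g")
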