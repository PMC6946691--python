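"""Multivariable inverse-variance weighted (IVW) regression.

The unbiased comparator: on the standardized scale (both sides divided by
the outcome standard error) IVW is ordinary least squares of beta_Y on
beta_X without an intercept, equivalent to weighted least squares with
weights 1/se(beta_Y)^2 on the raw scale. The univariable ratio-based IVW
estimate is the d = 1 special case. In multiplicative random-effects mode
the standard errors are inflated by sqrt(phi) with phi = max(1, RSS/(n-d)),
so overdispersion can widen but never narrow them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .data import StandardizedData, ValidationError

__all__ = ["IVWResult", "multivariable_ivw", "write_ivw"]


@dataclass
class IVWResult:
    rf_names: list[str]
    theta: np.ndarray
    se_theta: np.ndarray
    phi: float

    @property
    def z(self) -> np.ndarray:
        return self.theta / self.se_theta

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rf": self.rf_names, "theta": self.theta,
            "se": self.se_theta, "z": self.z,
        })


def multivariable_ivw(
    data: StandardizedData, random_effects: bool = False
) -> IVWResult:
    """No-intercept least squares of standardized outcome on risk-factor associations."""
    X, y = data.beta_x, data.beta_y
    n, d = X.shape
    if n <= d:
        raise ValidationError(f"under-determined fit: n={n} <= d={d}")
    gram = X.T @ X
    try:
        cho = cho_factor(gram, lower=True)
    except LinAlgError as exc:
        raise ValidationError(
            "design matrix is rank deficient: risk-factor associations are "
            "multi-collinear (no-multi-collinearity condition violated); "
            "prune correlated risk factors first"
        ) from exc
    theta = cho_solve(cho, X.T @ y)
    resid = y - X @ theta
    rss = float(resid @ resid)
    phi = max(1.0, rss / (n - d)) if random_effects else 1.0
    cov = cho_solve(cho, np.eye(d)) * phi
    return IVWResult(
        rf_names=list(data.rf_names),
        theta=theta,
        se_theta=np.sqrt(np.diag(cov)),
        phi=phi,
    )


def write_ivw(result: IVWResult, path: str) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
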