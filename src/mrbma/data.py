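"""Loading, harmonization and standardization of two-sample summary data.

The analysis operates on per-variant GWAS association estimates: an n x d
matrix of variant--risk-factor associations (``beta_x``) and a length-n
vector of variant--outcome associations (``beta_y``) with standard errors.
All downstream modules consume :class:`StandardizedData`, in which both
sides have been divided by the outcome standard error so the residual
variance of every variant is one and ordinary (unweighted) least squares on
the transformed scale equals inverse-variance weighted regression on the
raw scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryData",
    "StandardizedData",
    "load_summary_data",
    "standardize",
    "prune_correlated",
    "scale_columns_unit_variance",
    "write_standardized",
]


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


#: palindromic allele pairs that cannot be resolved without strand information
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SummaryData:
    """Raw per-variant association estimates for d risk factors and one outcome."""

    variant_ids: list[str]
    rf_names: list[str]
    beta_x_raw: np.ndarray  # n x d, per-allele units
    beta_y_raw: np.ndarray  # length n
    se_y_raw: np.ndarray  # length n, strictly positive
    se_x_raw: np.ndarray | None = None  # n x d, optional (reporting only)
    effect_allele: list[str] | None = None
    other_allele: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta_x_raw = np.asarray(self.beta_x_raw, dtype=float)
        self.beta_y_raw = np.asarray(self.beta_y_raw, dtype=float)
        self.se_y_raw = np.asarray(self.se_y_raw, dtype=float)
        n, d = self.beta_x_raw.shape
        if len(self.variant_ids) != n or len(self.rf_names) != d:
            raise ValidationError("inconsistent dimensions in SummaryData")
        if len(set(self.variant_ids)) != n:
            raise ValidationError("variant identifiers must be unique")
        if self.beta_y_raw.shape != (n,) or self.se_y_raw.shape != (n,):
            raise ValidationError("outcome vectors must have length n")
        bad = np.flatnonzero(~(self.se_y_raw > 0))
        if bad.size:
            raise ValidationError(
                f"non-positive outcome standard error at row(s) "
                f"{[self.variant_ids[i] for i in bad[:5]]}"
            )
        for arr in (self.beta_x_raw, self.beta_y_raw, self.se_y_raw):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("missing or non-finite values after loading")

    @property
    def n_variants(self) -> int:
        return self.beta_x_raw.shape[0]

    @property
    def n_risk_factors(self) -> int:
        return self.beta_x_raw.shape[1]


@dataclass
class StandardizedData:
    """Dimensionless association data: both sides divided by se(beta_y_raw)."""

    variant_ids: list[str]
    rf_names: list[str]
    beta_x: np.ndarray  # n x d
    beta_y: np.ndarray  # length n
    se_y_raw: np.ndarray | None = field(default=None, repr=False)  # for round-trips

    def __post_init__(self) -> None:
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        n, d = self.beta_x.shape
        if len(self.variant_ids) != n or len(self.rf_names) != d:
            raise ValidationError("inconsistent dimensions in StandardizedData")
        if self.beta_y.shape != (n,):
            raise ValidationError("beta_y must have length n")

    @property
    def n_variants(self) -> int:
        return self.beta_x.shape[0]

    @property
    def n_risk_factors(self) -> int:
        return self.beta_x.shape[1]


_DEFAULT_COLUMNS = {
    "rsid": "rsid",
    "beta_out": "beta_out",
    "se_out": "se_out",
    "ea": "ea",
    "oa": "oa",
}


def load_summary_data(
    path_x: str,
    path_y: str,
    columns: dict[str, str] | None = None,
    sep: str | None = None,
) -> SummaryData:
    """Read and inner-join exposure and outcome summary files on variant id.

    The exposure file carries one ``beta_<rf>`` column per risk factor (and
    optionally ``se_<rf>``); the outcome file carries ``beta_out``/``se_out``.
    When both files provide effect/other allele columns, outcome effects
    reported on the opposite allele are sign-flipped; variants whose allele
    pairs cannot be reconciled are dropped and logged. Palindromic (A/T, C/G)
    variants are passed through with a warning because strand cannot be
    resolved from the alleles alone.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    id_col = cols["rsid"]

    fx = pd.read_csv(path_x, sep=sep, engine="python")
    fy = pd.read_csv(path_y, sep=sep, engine="python")
    for frame, path in ((fx, path_x), (fy, path_y)):
        if id_col not in frame.columns:
            raise ValidationError(f"missing variant-id column {id_col!r} in {path}")
    for c in (cols["beta_out"], cols["se_out"]):
        if c not in fy.columns:
            raise ValidationError(f"missing required column {c!r} in {path_y}")

    rf_names = [c[len("beta_"):] for c in fx.columns
                if c.startswith("beta_") and c != cols["beta_out"]]
    if not rf_names:
        raise ValidationError(f"no beta_<risk factor> columns found in {path_x}")

    # restrict each side to its own columns so shared names cannot collide
    keep_x = [id_col] + [c for c in fx.columns
                         if c.startswith(("beta_", "se_")) and c not in
                         (cols["beta_out"], cols["se_out"])]
    keep_y = [id_col, cols["beta_out"], cols["se_out"]]
    for frame, keep in ((fx, keep_x), (fy, keep_y)):
        for c in (cols["ea"], cols["oa"]):
            if c in frame.columns:
                keep.append(c)
    merged = fx[keep_x].merge(fy[keep_y], on=id_col, suffixes=("_x", "_y"),
                              how="inner")
    if merged.empty:
        raise ValidationError("zero overlapping variants between the two files")
    n_dropped_join = len(fx) + len(fy) - 2 * len(merged)
    if n_dropped_join:
        logger.info("inner join dropped %d non-overlapping variant rows", n_dropped_join)

    ea_x, oa_x = cols["ea"] + "_x", cols["oa"] + "_x"
    ea_y, oa_y = cols["ea"] + "_y", cols["oa"] + "_y"
    have_alleles = all(c in merged.columns for c in (ea_x, oa_x, ea_y, oa_y))
    beta_y = merged[cols["beta_out"]].to_numpy(dtype=float)

    if have_alleles:
        exa = merged[ea_x].str.upper()
        oxa = merged[oa_x].str.upper()
        eya = merged[ea_y].str.upper()
        oya = merged[oa_y].str.upper()
        same = (exa == eya) & (oxa == oya)
        flipped = (exa == oya) & (oxa == eya)
        palindromic = [tuple(p) in _PALINDROMIC for p in zip(exa, oxa)]
        if any(palindromic):
            ids = merged.loc[palindromic, id_col].tolist()
            logger.warning(
                "palindromic variants passed through unresolved: %s", ids
            )
        beta_y = np.where(flipped, -beta_y, beta_y)
        keep = (same | flipped).to_numpy()
        if not keep.all():
            dropped = merged.loc[~keep, id_col].tolist()
            logger.warning("dropping %d variants with irreconcilable alleles: %s",
                           len(dropped), dropped)
            merged = merged.loc[keep].reset_index(drop=True)
            beta_y = beta_y[keep]
        if merged.empty:
            raise ValidationError("no variants left after allele harmonization")

    beta_x = merged[[f"beta_{rf}" for rf in rf_names]].to_numpy(dtype=float)
    se_x_cols = [f"se_{rf}" for rf in rf_names]
    se_x = (merged[se_x_cols].to_numpy(dtype=float)
            if all(c in merged.columns for c in se_x_cols) else None)

    data = SummaryData(
        variant_ids=merged[id_col].astype(str).tolist(),
        rf_names=rf_names,
        beta_x_raw=beta_x,
        beta_y_raw=np.asarray(beta_y, dtype=float),
        se_y_raw=merged[cols["se_out"]].to_numpy(dtype=float),
        se_x_raw=se_x,
        effect_allele=merged[ea_x].tolist() if have_alleles else None,
        other_allele=merged[oa_x].tolist() if have_alleles else None,
    )
    logger.info("loaded %d variants x %d risk factors", data.n_variants,
                data.n_risk_factors)
    return data


def standardize(data: SummaryData) -> StandardizedData:
    """Divide beta_y and every beta_x row by se(beta_y) of that variant.

    On the resulting scale the error variance of every variant is 1, so the
    likelihood used by the Bayesian scoring (and plain least squares for the
    IVW comparator) is correctly weighted.
    """
    inv = 1.0 / data.se_y_raw
    return StandardizedData(
        variant_ids=list(data.variant_ids),
        rf_names=list(data.rf_names),
        beta_x=data.beta_x_raw * inv[:, None],
        beta_y=data.beta_y_raw * inv,
        se_y_raw=data.se_y_raw.copy(),
    )


def prune_correlated(
    data: StandardizedData,
    threshold: float = 0.99,
    rng: np.random.Generator | None = None,
) -> tuple[StandardizedData, list[str]]:
    """Drop one of each pair of risk factors with |Pearson r| above threshold.

    Near-duplicate genetic association profiles make the causal effects of
    the two factors unidentifiable, so one member of each offending pair is
    removed before model selection. By default the later column (input
    order) of the currently worst pair is dropped, which is deterministic;
    pass ``rng`` to pick the victim at random instead.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0, 1]")
    if data.n_variants < 3:
        raise ValidationError("need at least 3 variants to estimate correlations")

    keep = list(range(data.n_risk_factors))
    dropped: list[str] = []
    while len(keep) >= 2:
        corr = np.corrcoef(data.beta_x[:, keep], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        corr = np.abs(corr)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        if i > j:
            i, j = j, i
        victim = keep[j] if rng is None else keep[int(rng.choice([i, j]))]
        dropped.append(data.rf_names[victim])
        keep.remove(victim)
    pruned = StandardizedData(
        variant_ids=list(data.variant_ids),
        rf_names=[data.rf_names[k] for k in keep],
        beta_x=data.beta_x[:, keep],
        beta_y=data.beta_y.copy(),
        se_y_raw=None if data.se_y_raw is None else data.se_y_raw.copy(),
    )
    if dropped:
        logger.info("pruned %d risk factors at |r| > %g: %s",
                    len(dropped), threshold, dropped)
    return pruned, dropped


def scale_columns_unit_variance(data: StandardizedData) -> StandardizedData:
    """Scale every beta_x column to unit sample variance.

    Equalises the a-priori chance of each risk factor being selected, so
    that inclusion probabilities are not driven by the measurement scale.
    """
    sd = data.beta_x.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValidationError(
            f"constant risk-factor column(s): {[data.rf_names[i] for i in flat]}"
        )
    return replace(data, beta_x=data.beta_x / sd)


def write_standardized(data: StandardizedData, path: str) -> None:
    """Write the analysis-ready table as TSV for provenance."""
    frame = pd.DataFrame(data.beta_x, columns=data.rf_names)
    frame.insert(0, "rsid", data.variant_ids)
    frame["beta_out_std"] = data.beta_y
    frame.to_csv(path, sep="\t", index=False)
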