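"""Model-space exploration: exhaustive enumeration and shotgun stochastic search.

For d risk factors there are 2^d candidate models, so exhaustive scoring is
feasible only for small d (the default refuses above d = 20). Beyond that a
shotgun stochastic search walks the model space through add/delete/swap
neighbourhoods, moving to a neighbour with probability proportional to its
(unnormalized) posterior score. Every model is scored at most once; the
posterior normalizing constant is approximated by the sum over all visited
models, on the assumption that the unvisited bulk of the space has
negligible posterior mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .core import (
    BMAResult,
    ModelScore,
    ModelScorer,
    ModelSpec,
    PriorConfig,
    log_model_prior,
    summarize,
)
from .data import StandardizedData, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "enumerate_models",
    "neighborhood",
    "score_models",
    "exhaustive_search",
    "shotgun_stochastic_search",
    "run_search",
]

#: d above which exhaustive enumeration is refused unless overridden
EXHAUSTIVE_THRESHOLD = 20


@dataclass(frozen=True)
class SearchConfig:
    mode: str = "auto"  # auto | exhaustive | shotgun
    iterations: int = 10_000
    seed: int = 0
    max_model_size: int = 12
    exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD
    include_empty_model: bool = True
    warm_start: bool = False  # start shotgun from best single-factor model

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.max_model_size < 1:
            raise ValidationError("max_model_size must be >= 1")
        if self.mode not in {"auto", "exhaustive", "shotgun"}:
            raise ValidationError(f"unknown search mode {self.mode!r}")


def enumerate_models(
    d: int,
    max_size: int,
    include_empty: bool = True,
    exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD,
    force: bool = False,
) -> list[ModelSpec]:
    """All subsets of the d risk factors up to max_size members."""
    if d > exhaustive_threshold and not force:
        raise ValidationError(
            f"exhaustive enumeration refused for d={d} > {exhaustive_threshold}; "
            "use shotgun mode (or force=True)"
        )
    models = []
    if include_empty:
        models.append(ModelSpec(()))
    for k in range(1, min(max_size, d) + 1):
        models.extend(ModelSpec(c) for c in combinations(range(d), k))
    return models


def neighborhood(model: ModelSpec, d: int, max_size: int) -> list[ModelSpec]:
    """All single-factor deletions, additions (size permitting) and swaps.

    The returned list never contains the input model and has no duplicates.
    """
    current = set(model.indices)
    absent = [j for j in range(d) if j not in current]
    out: list[ModelSpec] = []
    for j in model.indices:  # deletions
        out.append(ModelSpec(tuple(sorted(current - {j}))))
    if model.size < max_size:  # additions
        for j in absent:
            out.append(ModelSpec(tuple(sorted(current | {j}))))
    for j in model.indices:  # swaps
        for l in absent:
            out.append(ModelSpec(tuple(sorted((current - {j}) | {l}))))
    return out


def score_models(
    models: list[ModelSpec], data: StandardizedData, priors: PriorConfig
) -> list[ModelScore]:
    """Score a model list: log Bayes factor, shrinkage estimate, log prior."""
    scorer = ModelScorer(data, priors.sigma2)
    d = data.n_risk_factors
    out = []
    for m in models:
        log_bf, theta = scorer.score(m)
        out.append(ModelScore(
            model=m, log_bf=log_bf,
            log_prior=log_model_prior(m.size, d, priors.p_inclusion),
            theta_hat=theta,
        ))
    return out


def exhaustive_search(
    data: StandardizedData, priors: PriorConfig, cfg: SearchConfig
) -> BMAResult:
    models = enumerate_models(
        data.n_risk_factors, priors.max_model_size,
        include_empty=cfg.include_empty_model,
        exhaustive_threshold=cfg.exhaustive_threshold,
    )
    return summarize(score_models(models, data, priors), data)


def shotgun_stochastic_search(
    data: StandardizedData, priors: PriorConfig, cfg: SearchConfig
) -> BMAResult:
    """Stochastic model-space walk; normalizes over the visited model set.

    At each step the full neighbourhood of the current model is scored
    (memoized, so no model is ever scored twice) and the next model is
    drawn with probability proportional to prior x Bayes factor within the
    neighbourhood. Deterministic for a fixed seed.
    """
    d = data.n_risk_factors
    scorer = ModelScorer(data, priors.sigma2)
    rng = np.random.default_rng(cfg.seed)
    visited: dict[tuple[int, ...], ModelScore] = {}

    def get(m: ModelSpec) -> ModelScore:
        key = m.indices
        hit = visited.get(key)
        if hit is None:
            log_bf, theta = scorer.score(m)
            hit = ModelScore(
                model=m, log_bf=log_bf,
                log_prior=log_model_prior(m.size, d, priors.p_inclusion),
                theta_hat=theta,
            )
            visited[key] = hit
        return hit

    if cfg.warm_start:
        singles = [get(ModelSpec((j,))) for j in range(d)]
        current = max(singles, key=lambda s: s.log_prior + s.log_bf).model
    else:
        current = ModelSpec(())
    get(current)

    for _ in range(cfg.iterations):
        neigh = neighborhood(current, d, priors.max_model_size)
        if not cfg.include_empty_model:
            neigh = [m for m in neigh if m.size > 0] or neigh
        scores = [get(m) for m in neigh]
        log_w = np.array([s.log_prior + s.log_bf for s in scores])
        prob = np.exp(log_w - logsumexp(log_w))
        current = neigh[rng.choice(len(neigh), p=prob)]

    kept = list(visited.values())
    if not cfg.include_empty_model:
        kept = [s for s in kept if s.model.size > 0]
    logger.info("shotgun search visited %d unique models in %d iterations",
                len(kept), cfg.iterations)
    return summarize(kept, data)


def run_search(
    data: StandardizedData, priors: PriorConfig, cfg: SearchConfig
) -> BMAResult:
    """Dispatch to exhaustive or shotgun search; 'auto' picks by dimension."""
    mode = cfg.mode
    if mode == "auto":
        mode = "exhaustive" if data.n_risk_factors <= cfg.exhaustive_threshold \
            else "shotgun"
    if mode == "exhaustive":
        return exhaustive_search(data, priors, cfg)
    return shotgun_stochastic_search(data, priors, cfg)
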