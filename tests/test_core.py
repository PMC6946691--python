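import numpy as np
import pytest

from mrbma import (
    ModelScore,
    ModelSpec,
    StandardizedData,
    causal_estimate,
    log_bayes_factor,
    log_model_prior,
    marginal_inclusion_probabilities,
    model_averaged_effects,
    normalize_posteriors,
)
from mrbma.data import ValidationError
from tests.conftest import random_standardized


def _tiny(beta_x, beta_y):
    beta_x = np.atleast_2d(np.asarray(beta_x, dtype=float))
    if beta_x.shape[0] == 1:
        beta_x = beta_x.T
    n = beta_x.shape[0]
    return StandardizedData(
        variant_ids=[f"v{i}" for i in range(n)],
        rf_names=[f"rf{j}" for j in range(beta_x.shape[1])],
        beta_x=beta_x,
        beta_y=np.asarray(beta_y, dtype=float),
    )


def dense_log_bf(model, data, sigma2):
    """Naive oracle: the closed form evaluated with explicit inversions."""
    idx = list(model.indices)
    k = len(idx)
    if k == 0:
        return 0.0
    X = data.beta_x[:, idx]
    y = data.beta_y
    nu = sigma2 * np.eye(k)
    omega = np.linalg.inv(np.linalg.inv(nu) + X.T @ X)
    theta = omega @ X.T @ y
    yty = y @ y
    ratio = (yty - theta @ np.linalg.inv(omega) @ theta) / yty
    return (0.5 * np.log(np.linalg.det(omega))
            - 0.5 * np.log(np.linalg.det(nu))
            - 0.5 * len(y) * np.log(ratio))


class TestLogModelPrior:
    def test_empty_model(self):
        assert log_model_prior(0, 5, 0.2) == pytest.approx(5 * np.log(0.8))

    def test_half_inclusion_is_uniform(self):
        vals = {log_model_prior(k, 8, 0.5) for k in range(9)}
        assert all(v == pytest.approx(8 * np.log(0.5)) for v in vals)

    def test_single_factor_arithmetic(self):
        assert log_model_prior(1, 30, 0.1) == pytest.approx(
            np.log(0.1 * 0.9**29))

    def test_oversized_model_rejected(self):
        with pytest.raises(ValidationError):
            log_model_prior(4, 3, 0.1)


class TestBayesFactor:
    def test_empty_model_is_null_reference(self, small_data):
        log_bf, theta = log_bayes_factor(ModelSpec(()), small_data, 0.25)
        assert log_bf == 0.0
        assert theta.size == 0

    def test_aligned_instrument_hand_value(self):
        # beta_X = beta_Y = (1,1), sigma2 = 1: BF = sqrt(3), theta = 2/3
        data = _tiny([1.0, 1.0], [1.0, 1.0])
        log_bf, theta = log_bayes_factor(ModelSpec((0,)), data, 1.0)
        assert np.exp(log_bf) == pytest.approx(np.sqrt(3), rel=1e-12)
        assert theta[0] == pytest.approx(2 / 3, rel=1e-12)

    def test_orthogonal_instrument_evidence_against(self):
        # beta_X = (1,-1), beta_Y = (1,1): Theta = 0, BF = sqrt(1/3) < 1
        data = _tiny([1.0, -1.0], [1.0, 1.0])
        log_bf, theta = log_bayes_factor(ModelSpec((0,)), data, 1.0)
        assert np.exp(log_bf) == pytest.approx(np.sqrt(1 / 3), rel=1e-12)
        assert theta[0] == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_oracle(self, seed):
        """Cholesky log-space evaluation equals naive dense evaluation."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        d = int(rng.integers(1, 4))
        data = random_standardized(n, d, seed=seed + 100)
        k = int(rng.integers(1, min(d, 2) + 1))
        model = ModelSpec(tuple(sorted(rng.choice(d, size=k, replace=False))))
        sigma2 = float(rng.uniform(0.05, 2.0))
        log_bf, _ = log_bayes_factor(model, data, sigma2)
        assert log_bf == pytest.approx(dense_log_bf(model, data, sigma2),
                                       rel=1e-10, abs=1e-10)

    def test_degenerate_outcome_rejected(self):
        data = _tiny([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValidationError):
            log_bayes_factor(ModelSpec((0,)), data, 1.0)


class TestCausalEstimate:
    def test_orthogonal_gives_zero(self):
        data = _tiny([1.0, -1.0], [1.0, 1.0])
        assert causal_estimate(ModelSpec((0,)), data, 1.0)[0] == pytest.approx(0.0)

    def test_large_sigma2_approaches_least_squares(self):
        data = _tiny([1.0, 1.0], [2.0, 2.0])
        est = causal_estimate(ModelSpec((0,)), data, 1e6)
        assert est[0] == pytest.approx(2.0, rel=1e-5)

    def test_shrinkage_norm_nondecreasing_in_sigma2(self, small_data):
        model = ModelSpec((0, 1, 2))
        norms = [
            np.linalg.norm(causal_estimate(model, small_data, s2))
            for s2 in [0.01, 0.1, 1.0, 10.0, 1e4]
        ]
        assert all(a <= b + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_sigma2_limit_is_ols(self, small_data):
        model = ModelSpec((0, 1, 2, 3))
        est = causal_estimate(model, small_data, 1e10)
        ols, *_ = np.linalg.lstsq(small_data.beta_x, small_data.beta_y,
                                  rcond=None)
        np.testing.assert_allclose(est, ols, rtol=1e-6)


def _score(indices, log_bf, log_prior, theta=None):
    spec = ModelSpec(indices)
    return ModelScore(model=spec, log_bf=log_bf, log_prior=log_prior,
                      theta_hat=np.zeros(spec.size) if theta is None
                      else np.asarray(theta, dtype=float))


class TestPosteriors:
    def test_symmetric_models_split_evenly(self):
        scores, _ = normalize_posteriors(
            [_score((0,), 1.0, -1.0), _score((1,), 1.0, -1.0)])
        assert [s.posterior_prob for s in scores] == pytest.approx([0.5, 0.5])

    def test_bayes_factor_ratio_three_to_one(self):
        scores, _ = normalize_posteriors(
            [_score((0,), np.log(3), 0.0), _score((1,), 0.0, 0.0)])
        probs = sorted(s.posterior_prob for s in scores)
        assert probs == pytest.approx([0.25, 0.75])

    def test_prior_evidence_tradeoff(self):
        # prior 0.09 with BF 1 balances prior 0.01 with BF 9
        scores, _ = normalize_posteriors([
            _score((0,), 0.0, np.log(0.09)),
            _score((0, 1), np.log(9), np.log(0.01)),
        ])
        assert [s.posterior_prob for s in scores] == pytest.approx([0.5, 0.5])

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(5)
        scores = [_score((j,), float(rng.normal(scale=200)),
                         float(rng.normal())) for j in range(30)]
        normalized, log_z = normalize_posteriors(scores)
        assert sum(s.posterior_prob for s in normalized) == pytest.approx(
            1.0, abs=1e-12)
        assert np.isfinite(log_z)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            normalize_posteriors([])


class TestAveraging:
    def test_mip_enumeration(self):
        scores = [_score((0,), 0, 0), _score((0, 1), 0, 0), _score((1,), 0, 0)]
        for s, pp in zip(scores, (0.5, 0.3, 0.2)):
            s.posterior_prob = pp
        mip = marginal_inclusion_probabilities(scores, 2)
        np.testing.assert_allclose(mip, [0.8, 0.5])

    def test_absent_factor_has_zero_mip_and_mace(self):
        scores = [_score((0,), 0, 0, theta=[0.5])]
        scores[0].posterior_prob = 1.0
        assert marginal_inclusion_probabilities(scores, 3)[1:] == pytest.approx(0)
        mace = model_averaged_effects(scores, 3)
        np.testing.assert_allclose(mace, [0.5, 0.0, 0.0])

    def test_mace_weighted_sum(self):
        scores = [_score((0,), 0, 0, theta=[0.4]),
                  _score((0, 1), 0, 0, theta=[0.2, 0.1])]
        scores[0].posterior_prob = 0.5
        scores[1].posterior_prob = 0.25
        mace = model_averaged_effects(scores, 2)
        assert mace[0] == pytest.approx(0.5 * 0.4 + 0.25 * 0.2)
        assert mace[1] == pytest.approx(0.25 * 0.1)

    def test_mip_sum_equals_size_weighted_posterior(self, small_data):
        """Sum of MIPs equals the posterior-expected model size (exhaustive)."""
        from mrbma import PriorConfig, SearchConfig
        from mrbma.search import exhaustive_search
        result = exhaustive_search(small_data, PriorConfig(max_model_size=4),
                                   SearchConfig(max_model_size=4))
        expected_size = sum(s.posterior_prob * s.model.size
                            for s in result.models)
        assert result.mip.sum() == pytest.approx(expected_size, abs=1e-10)


class TestNullBehaviour:
    def test_empty_model_wins_under_pure_noise(self):
        """With an independent-noise outcome the null model should dominate."""
        from mrbma import PriorConfig, SearchConfig
        from mrbma.search import exhaustive_search
        wins = 0
        reps = 50
        for seed in range(reps):
            data = random_standardized(500, 4, seed=1000 + seed)
            res = exhaustive_search(
                data, PriorConfig(p_inclusion=0.1, max_model_size=4),
                SearchConfig(max_model_size=4))
            wins += res.models[0].model.size == 0
        assert wins / reps >= 0.95
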