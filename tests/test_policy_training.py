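import math

import numpy as np
import pytest
from scipy import integrate

from saccade.glimpse import GlimpseConfig
from saccade.model import (
    ModelDims,
    action_logits,
    glimpse_net_forward,
    gru_forward,
    init_params,
    softmax,
)
from saccade.policy_training import (
    Adam,
    EpisodeBatch,
    RewardSpec,
    TrainSettings,
    episode_return,
    hybrid_update,
    location_log_prob,
    predict,
    reinforce_loss,
    rollout_batch,
    rollout_episode,
    sample_location,
    score_function_terms,
    step_reward,
    train,
)
from saccade.synthetic_data import SignalEpoch, gen_burst_eeg, two_class_burst_specs

SMALL_GLIMPSE = GlimpseConfig(k=2, base_rows=2, base_cols=3)


def small_params(rng, num_classes=2, sigma=0.2):
    dims = ModelDims(
        input_dim=SMALL_GLIMPSE.patch_size,
        glimpse_hidden=8,
        loc_hidden=6,
        g_dim=10,
        hidden=9,
        num_classes=num_classes,
    )
    return init_params(dims, rng, sigma=sigma)


def small_dataset(rng, n=8, num_classes=2):
    epochs = []
    for i in range(n):
        epochs.append(SignalEpoch(data=rng.normal(size=(6, 20)), label=i % num_classes))
    return epochs


class TestSampleLocation:
    def test_tiny_sigma_returns_clipped_mean(self, rng):
        loc = sample_location((0.4, -0.2), 1e-12, rng)
        assert loc.row == pytest.approx(0.4, abs=1e-9)
        assert loc.col == pytest.approx(-0.2, abs=1e-9)

    def test_far_mean_clips_to_corner(self, rng):
        loc = sample_location((5.0, 5.0), 0.1, rng)
        assert (loc.row, loc.col) == (1.0, 1.0)

    def test_monte_carlo_moments(self):
        rng = np.random.default_rng(42)
        n = 100_000
        draws = np.array([sample_location((0.0, 0.0), 0.2, rng).as_array() for _ in range(n)])
        tol = 3 * 0.2 / math.sqrt(n)
        assert abs(draws[:, 0].mean()) < tol
        assert abs(draws[:, 1].mean()) < tol

    def test_nonpositive_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_location((0, 0), 0.0, rng)


class TestLocationLogProb:
    def test_mode_value(self):
        sigma = 0.3
        assert location_log_prob((0.1, 0.2), (0.1, 0.2), sigma) == pytest.approx(
            -math.log(2 * math.pi * sigma**2)
        )

    def test_symmetry(self):
        mean, d = np.array([0.2, -0.1]), np.array([0.15, -0.3])
        assert location_log_prob(mean + d, mean, 0.25) == pytest.approx(
            location_log_prob(mean - d, mean, 0.25)
        )

    def test_density_integrates_to_one(self):
        sigma = 0.3
        val, _ = integrate.dblquad(
            lambda y, x: math.exp(location_log_prob((x, y), (0.0, 0.0), sigma)),
            -2.5, 2.5, -2.5, 2.5,
        )
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            location_log_prob((0, 0), (0, 0), -1.0)


class TestRewardAndReturn:
    @pytest.mark.parametrize(
        "pred,label,t,T,expected",
        [(2, 2, 6, 6, 1.0), (2, 3, 6, 6, 0.0), (2, 2, 3, 6, 0.0), (0, 0, 1, 1, 1.0)],
    )
    def test_terminal_only_rule(self, pred, label, t, T, expected):
        assert step_reward(pred, label, t, T) == expected

    def test_step_out_of_range(self):
        with pytest.raises(ValueError):
            step_reward(0, 0, 0, 6)
        with pytest.raises(ValueError):
            step_reward(0, 0, 7, 6)

    @pytest.mark.parametrize(
        "rewards,gamma,expected",
        [((0, 0, 1), 1.0, 1.0), ((0, 0, 1), 0.5, 0.25), ((0, 0, 0), 1.0, 0.0)],
    )
    def test_episode_return(self, rewards, gamma, expected):
        assert episode_return(rewards, gamma) == pytest.approx(expected)

    def test_empty_rewards_rejected(self):
        with pytest.raises(ValueError):
            episode_return([], 1.0)

    def test_reward_spec_gamma_range(self):
        with pytest.raises(ValueError):
            RewardSpec(gamma=0.0)
        with pytest.raises(ValueError):
            RewardSpec(gamma=1.5)


class TestRollout:
    def test_trajectory_lengths(self, rng):
        params = small_params(rng)
        sample = small_dataset(rng, n=1)[0]
        T = 5
        tr = rollout_episode(sample, params, T, SMALL_GLIMPSE, np.random.default_rng(0))
        assert tr.num_glimpses == T
        for name in ("locations", "raw_locations", "location_means", "log_probs",
                     "hidden_states", "glimpses", "loc_inputs", "rewards"):
            assert len(getattr(tr, name)) == T

    def test_identical_seeds_bit_identical(self, rng):
        params = small_params(rng)
        sample = small_dataset(rng, n=1)[0]
        tr1 = rollout_episode(sample, params, 4, SMALL_GLIMPSE, np.random.default_rng(9))
        tr2 = rollout_episode(sample, params, 4, SMALL_GLIMPSE, np.random.default_rng(9))
        np.testing.assert_array_equal(tr1.raw_locations, tr2.raw_locations)
        np.testing.assert_array_equal(tr1.hidden_states, tr2.hidden_states)
        assert tr1.action == tr2.action
        assert tr1.ret == tr2.ret

    def test_forced_correct_head_gets_unit_return(self, rng):
        params = small_params(rng, num_classes=3)
        params.arrays["W_a"][:] = 0.0
        params.arrays["b_a"][:] = [0.0, 10.0, 0.0]  # always predicts class 1
        sample = SignalEpoch(data=rng.normal(size=(6, 20)), label=1)
        tr = rollout_episode(sample, params, 3, SMALL_GLIMPSE, np.random.default_rng(0))
        assert tr.ret == 1.0
        np.testing.assert_array_equal(tr.rewards, [0.0, 0.0, 1.0])

    def test_rewards_zero_except_terminal(self, rng):
        params = small_params(rng)
        batch = rollout_batch(
            small_dataset(rng, n=4), params, 5, SMALL_GLIMPSE, np.random.default_rng(3)
        )
        for tr in batch.trajectories:
            np.testing.assert_array_equal(tr.rewards[:-1], 0.0)
            assert tr.rewards[-1] in (0.0, 1.0)
            assert 0.0 <= tr.ret <= 1.0

    def test_invalid_T(self, rng):
        params = small_params(rng)
        with pytest.raises(ValueError):
            rollout_batch(small_dataset(rng, n=1), params, 0, SMALL_GLIMPSE,
                          np.random.default_rng(0))


class TestReinforceEstimator:
    def test_zero_advantage_gives_zero_gradient(self, rng):
        params = small_params(rng)
        batch = rollout_batch(
            small_dataset(rng), params, 3, SMALL_GLIMPSE, np.random.default_rng(5)
        )
        rets = np.array([tr.ret for tr in batch.trajectories])
        baselines = np.tile(rets[:, None], (1, 3))  # b_t = R exactly
        _, grads = reinforce_loss(batch, params, baselines=baselines)
        np.testing.assert_array_equal(grads["W_l"], 0.0)
        np.testing.assert_array_equal(grads["b_l"], 0.0)

    def test_empty_batch_rejected(self, rng):
        params = small_params(rng)
        with pytest.raises(ValueError):
            reinforce_loss(EpisodeBatch(trajectories=[], labels=[]), params)

    def test_reinforce_loss_gradient_matches_finite_differences(self, rng):
        # d(surrogate)/d(W_l) via the analytic path vs central differences of
        # the surrogate recomputed from stored raw draws (score function only)
        params = small_params(rng)
        batch = rollout_batch(
            small_dataset(rng), params, 3, SMALL_GLIMPSE, np.random.default_rng(11)
        )
        v_fixed = np.zeros((len(batch), 3))
        _, grads = reinforce_loss(batch, params, baselines=v_fixed)
        W = params.arrays["W_l"]
        eps = 1e-6
        for ix in [(0, 0), (1, 3), (0, 5)]:
            orig = W[ix]
            W[ix] = orig + eps
            lp, _ = reinforce_loss(batch, params, baselines=v_fixed)
            W[ix] = orig - eps
            lm, _ = reinforce_loss(batch, params, baselines=v_fixed)
            W[ix] = orig
            num = (lp - lm) / (2 * eps)
            assert grads["W_l"][ix] == pytest.approx(num, rel=1e-5, abs=1e-9)

    def test_bandit_gradient_matches_closed_form(self):
        # 1-step scalar bandit: l ~ N(mu, sigma^2), R(l) = -(l - l*)^2,
        # dJ/dmu = -2 (mu - l*)
        rng = np.random.default_rng(77)
        mu, sigma, l_star, M = 0.3, 0.25, -0.2, 100_000
        draws = mu + sigma * rng.standard_normal(M)
        rewards = -((draws - l_star) ** 2)
        terms = score_function_terms(draws, mu, sigma, rewards)
        estimate = terms.mean()
        se = terms.std(ddof=1) / math.sqrt(M)
        assert abs(estimate - (-2 * (mu - l_star))) < 5 * se

    def test_bandit_estimator_vs_crn_finite_difference(self):
        # common-random-numbers FD of the Monte-Carlo objective
        rng = np.random.default_rng(123)
        mu, sigma, l_star, M = 0.1, 0.3, -0.4, 200_000
        z = rng.standard_normal(M)

        def J(m):
            return np.mean(-((m + sigma * z - l_star) ** 2))

        eps = 1e-4
        fd = (J(mu + eps) - J(mu - eps)) / (2 * eps)
        draws = mu + sigma * z
        estimate = score_function_terms(draws, mu, sigma, -((draws - l_star) ** 2)).mean()
        assert abs(estimate - fd) / abs(fd) < 0.05

    def test_baseline_invariance(self):
        # constant baseline leaves the expectation unchanged
        rng = np.random.default_rng(5)
        mu, sigma, l_star = 0.2, 0.3, -0.1
        n = 10_000 * 16
        draws = mu + sigma * rng.standard_normal(n)
        rewards = -((draws - l_star) ** 2)
        t0 = score_function_terms(draws, mu, sigma, rewards)
        tc = score_function_terms(draws, mu, sigma, rewards - 0.7)
        se = math.sqrt(t0.var(ddof=1) / n + tc.var(ddof=1) / n)
        assert abs(t0.mean() - tc.mean()) < 3 * se

    def test_learned_baseline_reduces_variance(self):
        rng = np.random.default_rng(6)
        mu, sigma, l_star, M = 0.2, 0.3, -0.1, 50_000
        fit = mu + sigma * rng.standard_normal(M)
        learned_b = float(np.mean(-((fit - l_star) ** 2)))  # MSE-optimal constant
        draws = mu + sigma * rng.standard_normal(M)
        rewards = -((draws - l_star) ** 2)
        var_no_baseline = score_function_terms(draws, mu, sigma, rewards).var(ddof=1)
        var_learned = score_function_terms(draws, mu, sigma, rewards - learned_b).var(ddof=1)
        assert var_learned < var_no_baseline


class TestHybridUpdate:
    def test_zero_learning_rate_leaves_params_unchanged(self, rng):
        params = small_params(rng)
        before = {k: v.copy() for k, v in params.arrays.items()}
        batch = rollout_batch(
            small_dataset(rng), params, 3, SMALL_GLIMPSE, np.random.default_rng(2)
        )
        hybrid_update(batch, params, Adam(lr=0.0))
        for name, arr in params.arrays.items():
            np.testing.assert_array_equal(arr, before[name])

    def test_cross_entropy_decreases_on_single_sample(self, rng):
        params = small_params(rng)
        sample = small_dataset(rng, n=1)[0]
        batch = rollout_batch([sample], params, 3, SMALL_GLIMPSE, np.random.default_rng(4))

        def ce(p):
            tr = batch.trajectories[0]
            h = np.zeros((1, p.dims.hidden))
            for t in range(3):
                g, _ = glimpse_net_forward(tr.glimpses[t][None, :], tr.loc_inputs[t][None, :], p)
                h, _ = gru_forward(h, g, p)
            probs = softmax(action_logits(h, p))
            return -math.log(probs[0, sample.label])

        before = ce(params)
        hybrid_update(batch, params, Adam(lr=1e-3))
        assert ce(params) < before

    def test_diagnostics_ranges(self, rng):
        params = small_params(rng)
        batch = rollout_batch(
            small_dataset(rng), params, 3, SMALL_GLIMPSE, np.random.default_rng(8)
        )
        diag = hybrid_update(batch, params, Adam(lr=1e-3))
        assert 0.0 <= diag["mean_return"] <= 1.0
        assert 0.0 <= diag["accuracy"] <= 1.0
        assert diag["loss_ce"] >= 0.0
        assert diag["loss_baseline"] >= 0.0

    def test_empty_batch_rejected(self, rng):
        params = small_params(rng)
        with pytest.raises(ValueError):
            hybrid_update(EpisodeBatch(trajectories=[], labels=[]), params, Adam())


class TestTrain:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainSettings())

    def test_log_rows_and_return_accuracy_identity(self, rng):
        dataset = gen_burst_eeg(
            30, channels=6, timepoints=40,
            specs=two_class_burst_specs(channels=6, timepoints=40),
            rng=np.random.default_rng(0),
        )
        settings = TrainSettings(
            T=3, epochs=2, batch_size=10, lr=1e-3, seed=0,
            glimpse=SMALL_GLIMPSE, glimpse_hidden=8, loc_hidden=6, g_dim=10, hidden=9,
        )
        params, log = train(dataset, settings)
        assert len(log) == 2
        for row in log:
            # terminal 0/1 reward with gamma=1 and argmax actions makes the
            # mean return equal the rollout accuracy by definition
            assert row["mean_return"] == pytest.approx(row["accuracy"])

    def test_reproducible_under_seed(self, rng):
        dataset = small_dataset(np.random.default_rng(1), n=12)
        settings = TrainSettings(
            T=2, epochs=1, batch_size=6, seed=3, glimpse=SMALL_GLIMPSE,
            glimpse_hidden=8, loc_hidden=6, g_dim=10, hidden=9,
        )
        p1, log1 = train(dataset, settings)
        p2, log2 = train(dataset, settings)
        assert log1 == log2
        for name in p1.arrays:
            np.testing.assert_array_equal(p1.arrays[name], p2.arrays[name])

    def test_greedy_predict_deterministic(self, rng):
        params = small_params(rng)
        dataset = small_dataset(rng, n=5)
        p1 = predict(dataset, params, 3, SMALL_GLIMPSE)
        p2 = predict(dataset, params, 3, SMALL_GLIMPSE)
        np.testing.assert_array_equal(p1, p2)
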