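"""Episode rollout, REINFORCE with a value baseline, and the hybrid training loop.

The agent takes ``T`` glimpses of one sample per episode.  Locations are drawn
from a fixed-variance Gaussian policy whose mean is a head on the GRU state;
the class decision is made once, at step ``T``, and earns a terminal 0/1
reward.  Training is hybrid: the classification path (action head, GRU core,
glimpse network) is trained by backpropagated cross-entropy, the location head
by the score-function (REINFORCE) estimator with a learned state-value
baseline, and the baseline head by mean squared error to the realized return.
Gradients never flow through the sampled location coordinates (hard attention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .glimpse import GlimpseConfig, Location, extract_glimpse, extract_glimpse_multichannel
from .model import (
    ModelDims,
    ModelParams,
    action_logits,
    baseline_batch,
    glimpse_net_backward,
    glimpse_net_forward,
    gru_backward,
    gru_forward,
    init_params,
    location_mean_batch,
    softmax,
)
from .synthetic_data import SignalEpoch

__all__ = [
    "RewardSpec",
    "Trajectory",
    "EpisodeBatch",
    "TrainSettings",
    "Adam",
    "sample_location",
    "location_log_prob",
    "step_reward",
    "episode_return",
    "score_function_terms",
    "rollout_episode",
    "rollout_batch",
    "reinforce_loss",
    "hybrid_update",
    "train",
    "predict",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class RewardSpec:
    """Terminal 0/1 reward discounted by gamma (inert at the default gamma=1)."""

    gamma: float = 1.0
    terminal_only: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")


@dataclass
class Trajectory:
    """Per-episode record of everything the estimators need.

    ``loc_inputs[t]`` is the (clipped) location fed to the glimpse sensor at
    step ``t`` (so ``loc_inputs[0]`` is the uniformly drawn starting point);
    ``raw_locations[t]`` is the pre-clip Gaussian draw the log-density is
    evaluated at; ``locations[t]`` is the clipped draw the environment sees.
    """

    locations: list
    raw_locations: np.ndarray
    location_means: np.ndarray
    log_probs: np.ndarray
    hidden_states: np.ndarray
    glimpses: np.ndarray
    loc_inputs: np.ndarray
    action: int
    action_log_prob: float
    rewards: np.ndarray
    ret: float
    num_glimpses: int

    def __post_init__(self) -> None:
        t = self.num_glimpses
        for name in ("locations", "raw_locations", "location_means", "log_probs",
                     "hidden_states", "glimpses", "loc_inputs", "rewards"):
            if len(getattr(self, name)) != t:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {t}")


@dataclass
class EpisodeBatch:
    trajectories: list
    labels: list

    def __post_init__(self) -> None:
        if len(self.trajectories) != len(self.labels):
            raise ValueError("trajectories and labels must have equal length")

    def __len__(self) -> int:
        return len(self.trajectories)


# ---------------------------------------------------------------------------
# Policy primitives
# ---------------------------------------------------------------------------


def sample_location(
    mean: tuple[float, float], sigma: float, rng: np.random.Generator
) -> Location:
    """Draw l ~ N(mean, sigma^2 I) and clip into the valid coordinate box."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    draw = np.asarray(mean, dtype=np.float64) + sigma * rng.standard_normal(2)
    return Location(draw[0], draw[1])


def location_log_prob(loc_raw, mean, sigma: float) -> float:
    """Log-density of the pre-clip draw under the diagonal Gaussian policy."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(loc_raw, dtype=np.float64)
    mu = np.asarray(mean, dtype=np.float64)
    return float(np.sum(-math.log(sigma) - 0.5 * _LOG_2PI - (x - mu) ** 2 / (2.0 * sigma**2)))


def step_reward(prediction: int, label: int, t: int, T: int) -> float:
    """1 at the final step of a correct episode, 0 everywhere else."""
    if not (1 <= t <= T):
        raise ValueError(f"step index {t} outside 1..{T}")
    return 1.0 if (t == T and prediction == label) else 0.0


def episode_return(rewards, gamma: float) -> float:
    """Discounted return: sum_t gamma^(t-1) * r_t."""
    r = np.asarray(rewards, dtype=np.float64)
    if r.size == 0:
        raise ValueError("rewards must be non-empty")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return float(np.sum(gamma ** np.arange(r.size) * r))


def score_function_terms(raws, means, sigma: float, advantages) -> np.ndarray:
    """Per-sample score-function contributions d log pi / d mean * advantage.

    ``raws`` and ``means`` broadcast together; ``advantages`` broadcasts against
    the leading axes.  Averaging the result over the first axis gives the
    REINFORCE estimate of dJ/d mean.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    raws = np.asarray(raws, dtype=np.float64)
    means = np.asarray(means, dtype=np.float64)
    adv = np.asarray(advantages, dtype=np.float64)
    return (raws - means) / sigma**2 * adv


# ---------------------------------------------------------------------------
# Rollout
# ---------------------------------------------------------------------------


def _glimpse_rho(
    signals: list, is_image: bool, locs: np.ndarray, config: GlimpseConfig
) -> np.ndarray:
    extract = extract_glimpse if is_image else extract_glimpse_multichannel
    rho = np.empty((len(signals), config.patch_size))
    for b, sig in enumerate(signals):
        rho[b] = extract(sig, Location(locs[b, 0], locs[b, 1]), config).flatten()
    return rho


def rollout_batch(
    samples: list,
    params: ModelParams,
    T: int,
    config: GlimpseConfig,
    rng: np.random.Generator | None = None,
    reward_spec: RewardSpec = RewardSpec(),
    greedy: bool = False,
) -> EpisodeBatch:
    """Run one episode per sample in lockstep.

    Stochastic mode draws the starting location uniformly over [-1, 1]^2 and
    samples every subsequent location from the Gaussian policy; greedy mode
    starts at the center and follows the policy mean deterministically.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not samples:
        raise ValueError("empty sample batch")
    B = len(samples)
    H = params.dims.hidden
    signals = [ep.signal2d for ep in samples]
    is_image = samples[0].data.ndim == 3

    if greedy:
        loc = np.zeros((B, 2))
    else:
        if rng is None:
            raise ValueError("stochastic rollout requires an rng")
        loc = rng.uniform(-1.0, 1.0, size=(B, 2))

    h = np.zeros((B, H))
    loc_inputs = np.empty((T, B, 2))
    glimpses = np.empty((T, B, config.patch_size))
    hiddens = np.empty((T, B, H))
    means = np.empty((T, B, 2))
    raws = np.empty((T, B, 2))
    logps = np.empty((T, B))

    sigma = params.sigma
    for t in range(T):
        loc_inputs[t] = loc
        rho = _glimpse_rho(signals, is_image, loc, config)
        glimpses[t] = rho
        g, _ = glimpse_net_forward(rho, loc, params)
        h, _ = gru_forward(h, g, params)
        hiddens[t] = h
        mu, _ = location_mean_batch(h, params)
        means[t] = mu
        raw = mu if greedy else mu + sigma * rng.standard_normal((B, 2))
        raws[t] = raw
        logps[t] = (
            -math.log(sigma) - 0.5 * _LOG_2PI - (raw - mu) ** 2 / (2.0 * sigma**2)
        ).sum(axis=1)
        loc = np.clip(raw, -1.0, 1.0)

    probs = softmax(action_logits(h, params))
    actions = probs.argmax(axis=1)

    trajectories = []
    labels = []
    for b, ep in enumerate(samples):
        rewards = np.array(
            [step_reward(int(actions[b]), ep.label, t, T) for t in range(1, T + 1)]
        )
        trajectories.append(
            Trajectory(
                locations=[Location(raws[t, b, 0], raws[t, b, 1]) for t in range(T)],
                raw_locations=raws[:, b].copy(),
                location_means=means[:, b].copy(),
                log_probs=logps[:, b].copy(),
                hidden_states=hiddens[:, b].copy(),
                glimpses=glimpses[:, b].copy(),
                loc_inputs=loc_inputs[:, b].copy(),
                action=int(actions[b]),
                action_log_prob=float(np.log(probs[b, actions[b]])),
                rewards=rewards,
                ret=episode_return(rewards, reward_spec.gamma),
                num_glimpses=T,
            )
        )
        labels.append(ep.label)
    return EpisodeBatch(trajectories=trajectories, labels=labels)


def rollout_episode(
    sample: SignalEpoch,
    params: ModelParams,
    T: int,
    config: GlimpseConfig,
    rng: np.random.Generator,
    reward_spec: RewardSpec = RewardSpec(),
) -> Trajectory:
    """One stochastic episode on a single sample (see :func:`rollout_batch`)."""
    return rollout_batch([sample], params, T, config, rng, reward_spec).trajectories[0]


# ---------------------------------------------------------------------------
# REINFORCE estimator and hybrid update
# ---------------------------------------------------------------------------


def _stack_batch(batch: EpisodeBatch):
    trajs = batch.trajectories
    T = trajs[0].num_glimpses
    raws = np.stack([tr.raw_locations for tr in trajs])        # (B, T, 2)
    hiddens = np.stack([tr.hidden_states for tr in trajs])     # (B, T, H)
    glimpses = np.stack([tr.glimpses for tr in trajs])         # (B, T, D)
    loc_inputs = np.stack([tr.loc_inputs for tr in trajs])     # (B, T, 2)
    rets = np.array([tr.ret for tr in trajs])                  # (B,)
    return T, raws, hiddens, glimpses, loc_inputs, rets


def reinforce_loss(
    batch: EpisodeBatch, params: ModelParams, baselines: np.ndarray | None = None
) -> tuple[float, dict]:
    """Surrogate objective whose psi_l gradient is the baseline-subtracted
    score-function estimator.

    Returns ``(loss, grads)`` where ``grads`` holds the analytic gradients for
    the location head only; the baseline enters as a detached constant.
    """
    if len(batch) == 0:
        raise ValueError("empty episode batch")
    T, raws, hiddens, _, _, rets = _stack_batch(batch)
    B = len(batch)
    sigma = params.sigma
    H = params.dims.hidden
    h_flat = hiddens.reshape(B * T, H)
    mu_flat, _ = location_mean_batch(h_flat, params)
    mu = mu_flat.reshape(B, T, 2)
    if baselines is None:
        baselines = baseline_batch(h_flat, params).reshape(B, T)
    adv = rets[:, None] - np.asarray(baselines)                # (B, T), detached
    logp = (
        -math.log(sigma) - 0.5 * _LOG_2PI - (raws - mu) ** 2 / (2.0 * sigma**2)
    ).sum(axis=2)                                              # (B, T)
    loss = float(-(logp * adv).sum(axis=1).mean())
    # d loss / d mu, then through the tanh squash into the linear head
    dmu = -(adv[:, :, None] * (raws - mu) / sigma**2) / B
    du = (dmu * (1.0 - mu**2)).reshape(B * T, 2)
    grads = {
        "W_l": du.T @ h_flat,
        "b_l": du.sum(axis=0),
    }
    return loss, grads


class Adam:
    """Adaptive moment estimation over a named dict of parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: ModelParams, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / (1 - b1**self.t)
            v_hat = self.v[name] / (1 - b2**self.t)
            params.arrays[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def hybrid_update(
    batch: EpisodeBatch,
    params: ModelParams,
    optimizer: Adam,
) -> dict:
    """One optimizer step on cross-entropy + REINFORCE surrogate + baseline MSE.

    The differentiable path is re-run teacher-forced along the recorded
    glimpses and location inputs, so cross-entropy gradients reach the action
    head, the GRU core, and the glimpse network (but not the location
    coordinates themselves).  Returns scalar diagnostics.
    """
    if len(batch) == 0:
        raise ValueError("empty episode batch")
    T, raws, _, glimpses, loc_inputs, rets = _stack_batch(batch)
    B = len(batch)
    labels = np.asarray(batch.labels)
    H = params.dims.hidden
    sigma = params.sigma
    grads = params.zero_grads()

    # teacher-forced forward
    h = np.zeros((B, H))
    g_caches, gru_caches, hiddens = [], [], []
    for t in range(T):
        g, gcache = glimpse_net_forward(glimpses[:, t], loc_inputs[:, t], params)
        h, rcache = gru_forward(h, g, params)
        g_caches.append(gcache)
        gru_caches.append(rcache)
        hiddens.append(h)
    h_all = np.stack(hiddens, axis=1)                          # (B, T, H)
    h_flat = h_all.reshape(B * T, H)

    # (i) cross-entropy on the final-step classification
    logits = action_logits(h_all[:, -1], params)
    probs = softmax(logits)
    ce = float(-np.mean(np.log(probs[np.arange(B), labels] + 1e-300)))
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    grads["W_a"] += dlogits.T @ h_all[:, -1]
    grads["b_a"] += dlogits.sum(axis=0)

    dh = dlogits @ params.arrays["W_a"]
    for t in range(T - 1, -1, -1):
        dh, dg = gru_backward(dh, gru_caches[t], params, grads)
        glimpse_net_backward(dg, g_caches[t], params, grads)

    # (ii) REINFORCE surrogate for the location head (baseline detached)
    v = baseline_batch(h_flat, params).reshape(B, T)
    mu_flat, _ = location_mean_batch(h_flat, params)
    mu = mu_flat.reshape(B, T, 2)
    adv = rets[:, None] - v
    logp = (
        -math.log(sigma) - 0.5 * _LOG_2PI - (raws - mu) ** 2 / (2.0 * sigma**2)
    ).sum(axis=2)
    rl_loss = float(-(logp * adv).sum(axis=1).mean())
    dmu = -(adv[:, :, None] * (raws - mu) / sigma**2) / B
    du = (dmu * (1.0 - mu**2)).reshape(B * T, 2)
    grads["W_l"] += du.T @ h_flat
    grads["b_l"] += du.sum(axis=0)

    # (iii) baseline regression toward the realized return (core detached)
    err = v - rets[:, None]
    b_loss = float(np.mean(err**2))
    dv = (2.0 * err / (B * T)).reshape(B * T)
    grads["W_b"] += (dv[:, None] * h_flat).sum(axis=0)[None, :]
    grads["b_b"] += np.array([dv.sum()])

    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {name}")
    optimizer.step(params, grads)
    for name, arr in params.arrays.items():
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite parameter {name} after update")

    actions = np.array([tr.action for tr in batch.trajectories])
    return {
        "loss_ce": ce,
        "loss_reinforce": rl_loss,
        "loss_baseline": b_loss,
        "mean_return": float(rets.mean()),
        "accuracy": float((actions == labels).mean()),
    }


# ---------------------------------------------------------------------------
# Training loop and greedy prediction
# ---------------------------------------------------------------------------


@dataclass
class TrainSettings:
    """Hyperparameters for :func:`train`; defaults follow the reference setup."""

    T: int = 6
    epochs: int = 10
    batch_size: int = 32
    lr: float = 1e-3
    sigma: float = 0.17
    seed: int = 0
    glimpse: GlimpseConfig = field(default_factory=GlimpseConfig)
    reward: RewardSpec = field(default_factory=RewardSpec)
    glimpse_hidden: int = 128
    loc_hidden: int = 128
    g_dim: int = 256
    hidden: int = 256
    num_classes: int | None = None  # inferred from labels when None


def train(
    dataset: list,
    settings: TrainSettings,
    init: ModelParams | None = None,
    start_epoch: int = 0,
) -> tuple[ModelParams, list[dict]]:
    """Epochs of rollout + hybrid update over shuffled minibatches.

    Returns the trained parameters and one log row per epoch (epoch index,
    loss terms, training accuracy, mean return).  Fully reproducible given
    ``settings.seed``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(settings.seed)
    num_classes = settings.num_classes or int(max(ep.label for ep in dataset)) + 1
    if init is not None:
        params = init
    else:
        dims = ModelDims(
            input_dim=settings.glimpse.patch_size,
            glimpse_hidden=settings.glimpse_hidden,
            loc_hidden=settings.loc_hidden,
            g_dim=settings.g_dim,
            hidden=settings.hidden,
            num_classes=num_classes,
        )
        params = init_params(dims, rng, sigma=settings.sigma)
    optimizer = Adam(lr=settings.lr)
    log: list[dict] = []
    n = len(dataset)
    for epoch in range(start_epoch, start_epoch + settings.epochs):
        order = rng.permutation(n)
        sums = {"loss_ce": 0.0, "loss_reinforce": 0.0, "loss_baseline": 0.0,
                "mean_return": 0.0, "accuracy": 0.0}
        seen = 0
        for lo in range(0, n, settings.batch_size):
            idx = order[lo : lo + settings.batch_size]
            samples = [dataset[i] for i in idx]
            batch = rollout_batch(
                samples, params, settings.T, settings.glimpse, rng, settings.reward
            )
            diag = hybrid_update(batch, params, optimizer)
            w = len(samples)
            for key in sums:
                sums[key] += diag[key] * w
            seen += w
        row = {"epoch": epoch, **{k: v / seen for k, v in sums.items()}}
        log.append(row)
    return params, log


def predict(
    dataset: list,
    params: ModelParams,
    T: int,
    config: GlimpseConfig,
    return_means: bool = False,
):
    """Deterministic greedy evaluation: start at the center, follow the policy
    mean, classify by argmax at step ``T``."""
    batch = rollout_batch(dataset, params, T, config, rng=None, greedy=True)
    preds = np.array([tr.action for tr in batch.trajectories])
    if return_means:
        means = np.stack([tr.location_means for tr in batch.trajectories])
        return preds, means
    return preds
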