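"""Parametric networks of the hard-attention agent.

All forward maps are deterministic NumPy functions of ``ModelParams``.  Each
batched kernel has a matching backward pass; analytic gradients are validated
against central finite differences in the test suite.

Architecture:

* glimpse network — two ReLU input projections (flattened patch stack and the
  focal location) combined by a third ReLU layer into the feature vector ``g``
* recurrent core — a single GRU cell maintaining the agent state ``h``
* heads on ``h`` — location mean (tanh-squashed linear), class softmax, and a
  scalar value baseline
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .glimpse import GlimpseStack, Location

__all__ = [
    "ModelDims",
    "ModelParams",
    "init_params",
    "glimpse_forward",
    "gru_step",
    "location_mean",
    "classify",
    "baseline_value",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelDims:
    """Layer sizes; defaults follow the 128/128/256/256 reference setup."""

    input_dim: int
    glimpse_hidden: int = 128
    loc_hidden: int = 128
    g_dim: int = 256
    hidden: int = 256
    num_classes: int = 4

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")


# weight name -> (rows, cols) expressed in ModelDims attributes; biases are 1-D
_WEIGHT_SPECS = {
    "W_ms": ("glimpse_hidden", "input_dim"),
    "W_lc": ("loc_hidden", 2),
    "W_g_ms": ("g_dim", "glimpse_hidden"),
    "W_g_lc": ("g_dim", "loc_hidden"),
    "W_z": ("hidden", "g_dim"),
    "U_z": ("hidden", "hidden"),
    "W_r": ("hidden", "g_dim"),
    "U_r": ("hidden", "hidden"),
    "W_c": ("hidden", "g_dim"),
    "U_c": ("hidden", "hidden"),
    "W_l": (2, "hidden"),
    "W_a": ("num_classes", "hidden"),
    "W_b": (1, "hidden"),
}
_BIAS_SPECS = {
    "b_ms": "glimpse_hidden",
    "b_lc": "loc_hidden",
    "b_g": "g_dim",
    "b_z": "hidden",
    "b_r": "hidden",
    "b_c": "hidden",
    "b_l": 2,
    "b_a": "num_classes",
    "b_b": 1,
}


def _resolve(dims: ModelDims, spec) -> int:
    return spec if isinstance(spec, int) else getattr(dims, spec)


@dataclass
class ModelParams:
    """All trainable arrays plus the fixed location-policy standard deviation."""

    dims: ModelDims
    arrays: dict[str, np.ndarray]
    sigma: float = 0.17

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        expected = set(_WEIGHT_SPECS) | set(_BIAS_SPECS)
        missing = expected - set(self.arrays)
        if missing:
            raise ValueError(f"missing parameter arrays: {sorted(missing)}")
        for name, spec in _WEIGHT_SPECS.items():
            shape = (_resolve(self.dims, spec[0]), _resolve(self.dims, spec[1]))
            if self.arrays[name].shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {self.arrays[name].shape}")
        for name, spec in _BIAS_SPECS.items():
            if self.arrays[name].shape != (_resolve(self.dims, spec),):
                raise ValueError(f"{name}: bad shape {self.arrays[name].shape}")
        for name, arr in self.arrays.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {name: np.zeros_like(arr) for name, arr in self.arrays.items()}

    def copy(self) -> "ModelParams":
        return ModelParams(
            dims=self.dims,
            arrays={k: v.copy() for k, v in self.arrays.items()},
            sigma=self.sigma,
        )


def init_params(dims: ModelDims, rng: np.random.Generator, sigma: float = 0.17) -> ModelParams:
    """Initialize weights uniformly in ±1/sqrt(fan_in); biases start at zero."""
    arrays: dict[str, np.ndarray] = {}
    for name, spec in _WEIGHT_SPECS.items():
        rows, cols = _resolve(dims, spec[0]), _resolve(dims, spec[1])
        bound = 1.0 / np.sqrt(cols)
        arrays[name] = rng.uniform(-bound, bound, size=(rows, cols))
    for name, spec in _BIAS_SPECS.items():
        arrays[name] = np.zeros(_resolve(dims, spec))
    return ModelParams(dims=dims, arrays=arrays, sigma=sigma)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Batched kernels (B, dim) with caches for backprop
# ---------------------------------------------------------------------------


def glimpse_net_forward(rho: np.ndarray, loc: np.ndarray, p: ModelParams):
    """rho (B, input_dim), loc (B, 2) -> g (B, g_dim), cache."""
    a = p.arrays
    if rho.shape[1] != p.dims.input_dim:
        raise ValueError(
            f"glimpse input dim {rho.shape[1]} does not match model input_dim {p.dims.input_dim}"
        )
    a_ms = rho @ a["W_ms"].T + a["b_ms"]
    h_ms = _relu(a_ms)
    a_lc = loc @ a["W_lc"].T + a["b_lc"]
    h_lc = _relu(a_lc)
    a_g = h_ms @ a["W_g_ms"].T + h_lc @ a["W_g_lc"].T + a["b_g"]
    g = _relu(a_g)
    return g, (rho, loc, a_ms, h_ms, a_lc, h_lc, a_g)


def glimpse_net_backward(dg: np.ndarray, cache, p: ModelParams, grads: dict) -> None:
    rho, loc, a_ms, h_ms, a_lc, h_lc, a_g = cache
    a = p.arrays
    da_g = dg * (a_g > 0)
    grads["W_g_ms"] += da_g.T @ h_ms
    grads["W_g_lc"] += da_g.T @ h_lc
    grads["b_g"] += da_g.sum(axis=0)
    da_ms = (da_g @ a["W_g_ms"]) * (a_ms > 0)
    da_lc = (da_g @ a["W_g_lc"]) * (a_lc > 0)
    grads["W_ms"] += da_ms.T @ rho
    grads["b_ms"] += da_ms.sum(axis=0)
    grads["W_lc"] += da_lc.T @ loc
    grads["b_lc"] += da_lc.sum(axis=0)


def gru_forward(h_prev: np.ndarray, g: np.ndarray, p: ModelParams):
    """Standard GRU update; h_prev (B, H), g (B, g_dim) -> h (B, H), cache."""
    a = p.arrays
    z = _sigmoid(g @ a["W_z"].T + h_prev @ a["U_z"].T + a["b_z"])
    r = _sigmoid(g @ a["W_r"].T + h_prev @ a["U_r"].T + a["b_r"])
    c = np.tanh(g @ a["W_c"].T + (r * h_prev) @ a["U_c"].T + a["b_c"])
    h = (1.0 - z) * h_prev + z * c
    return h, (h_prev, g, z, r, c)


def gru_backward(dh: np.ndarray, cache, p: ModelParams, grads: dict):
    """Returns (dh_prev, dg)."""
    h_prev, g, z, r, c = cache
    a = p.arrays
    dz = dh * (c - h_prev)
    dc = dh * z
    dh_prev = dh * (1.0 - z)
    dac = dc * (1.0 - c * c)
    grads["W_c"] += dac.T @ g
    grads["U_c"] += dac.T @ (r * h_prev)
    grads["b_c"] += dac.sum(axis=0)
    drh = dac @ a["U_c"]
    dr = drh * h_prev
    dh_prev = dh_prev + drh * r
    dar = dr * r * (1.0 - r)
    grads["W_r"] += dar.T @ g
    grads["U_r"] += dar.T @ h_prev
    grads["b_r"] += dar.sum(axis=0)
    dh_prev = dh_prev + dar @ a["U_r"]
    daz = dz * z * (1.0 - z)
    grads["W_z"] += daz.T @ g
    grads["U_z"] += daz.T @ h_prev
    grads["b_z"] += daz.sum(axis=0)
    dh_prev = dh_prev + daz @ a["U_z"]
    dg = dac @ a["W_c"] + dar @ a["W_r"] + daz @ a["W_z"]
    return dh_prev, dg


def action_logits(h: np.ndarray, p: ModelParams) -> np.ndarray:
    return h @ p.arrays["W_a"].T + p.arrays["b_a"]


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=-1, keepdims=True)


def location_mean_batch(h: np.ndarray, p: ModelParams):
    """h (B, H) -> (mu (B, 2), pre-squash activations)."""
    u = h @ p.arrays["W_l"].T + p.arrays["b_l"]
    return np.tanh(u), u


def baseline_batch(h: np.ndarray, p: ModelParams) -> np.ndarray:
    return (h @ p.arrays["W_b"].T + p.arrays["b_b"])[:, 0]


# ---------------------------------------------------------------------------
# Single-sample operations
# ---------------------------------------------------------------------------


def _as_hidden(h) -> np.ndarray:
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 1:
        raise ValueError(f"hidden state must be 1-D, got shape {h.shape}")
    if not np.all(np.isfinite(h)):
        raise ValueError("hidden state contains non-finite values")
    return h


def glimpse_forward(stack: GlimpseStack, loc: Location, params: ModelParams) -> np.ndarray:
    """Map a glimpse stack and its location to the feature vector ``g``.

    ``g = ReLU(Linear(h_MS) + Linear(h_l))`` with ``h_MS`` / ``h_l`` ReLU
    projections of the flattened patches and the location; entries are >= 0.
    """
    rho = stack.flatten()[None, :]
    g, _ = glimpse_net_forward(rho, loc.as_array()[None, :], params)
    return g[0]


def gru_step(h_prev: np.ndarray, g: np.ndarray, params: ModelParams) -> np.ndarray:
    """One GRU update of the agent state."""
    h_prev = _as_hidden(h_prev)
    g = np.asarray(g, dtype=np.float64)
    if h_prev.shape[0] != params.dims.hidden or g.shape[0] != params.dims.g_dim:
        raise ValueError(
            f"dimension mismatch: h {h_prev.shape}, g {g.shape}, "
            f"expected ({params.dims.hidden},), ({params.dims.g_dim},)"
        )
    h, _ = gru_forward(h_prev[None, :], g[None, :], params)
    return h[0]


def location_mean(h: np.ndarray, params: ModelParams) -> tuple[float, float]:
    """Mean of the Gaussian location policy, tanh-squashed into (-1, 1)."""
    mu, _ = location_mean_batch(_as_hidden(h)[None, :], params)
    return float(mu[0, 0]), float(mu[0, 1])


def classify(h: np.ndarray, params: ModelParams) -> np.ndarray:
    """Softmax class probabilities from the agent state."""
    return softmax(action_logits(_as_hidden(h)[None, :], params))[0]


def baseline_value(h: np.ndarray, params: ModelParams) -> float:
    """Scalar estimate of the expected return from state ``h``."""
    return float(baseline_batch(_as_hidden(h)[None, :], params)[0])


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_checkpoint(path, params: ModelParams, epoch: int = 0, cfg_hash: str = "") -> None:
    """Write all parameter arrays plus metadata to a single .npz archive."""
    meta = {
        "dims": asdict(params.dims),
        "sigma": params.sigma,
        "epoch": int(epoch),
        "config_hash": cfg_hash,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **params.arrays)


def load_checkpoint(path) -> tuple[ModelParams, dict]:
    """Read a checkpoint; returns (params, metadata)."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    dims = ModelDims(**meta["dims"])
    return ModelParams(dims=dims, arrays=arrays, sigma=meta["sigma"]), meta
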