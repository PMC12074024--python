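"""The mixture-of-experts age regressor: experts, gating network, prediction.

Each expert is a dense network (default hidden widths 640/256/128/64, one
output neuron) with batch normalization, ReLU and dropout on the hidden
layers.  The gating network shares the architecture but ends in an E-way
softmax head; the final prediction is the per-sample gate-weighted convex
combination of expert outputs.
"""
from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import engine as E
from .engine import Tensor

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclasses.dataclass
class MoEConfig:
    input_dim: int
    n_experts: int = 2
    hidden_widths: tuple[int, ...] = (640, 256, 128, 64)
    dropout_rate: float = 0.3
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if self.n_experts < 1:
            raise ValueError("need at least one expert")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


def _init_stack(rng: np.random.Generator, dims: list[int], batch_norm: bool) -> list[dict]:
    """He-style uniform fan-in initialization for a dense stack."""
    layers = []
    for li in range(len(dims) - 1):
        fan_in, fan_out = dims[li], dims[li + 1]
        bound = np.sqrt(6.0 / fan_in)
        layer = {
            "W": Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)), requires_grad=True),
            "b": Tensor(np.zeros(fan_out), requires_grad=True),
        }
        hidden = li < len(dims) - 2
        if hidden and batch_norm:
            layer["gamma"] = Tensor(np.ones(fan_out), requires_grad=True)
            layer["beta"] = Tensor(np.zeros(fan_out), requires_grad=True)
            layer["running_mean"] = np.zeros(fan_out)
            layer["running_var"] = np.ones(fan_out)
        layers.append(layer)
    return layers


@dataclasses.dataclass
class MoEModel:
    config: MoEConfig
    experts: list[list[dict]]
    gate: list[list] | list[dict]

    def parameters(self) -> list[Tensor]:
        params = []
        for stack in [*self.experts, self.gate]:
            for layer in stack:
                for key in ("W", "b", "gamma", "beta"):
                    if key in layer:
                        params.append(layer[key])
        return params


def init_model(config: MoEConfig) -> MoEModel:
    """Reproducibly initialize experts and gate from the config seed."""
    rng = np.random.default_rng(config.seed)
    dims_expert = [config.input_dim, *config.hidden_widths, 1]
    dims_gate = [config.input_dim, *config.hidden_widths, config.n_experts]
    experts = [_init_stack(rng, dims_expert, config.batch_norm) for _ in range(config.n_experts)]
    gate = _init_stack(rng, dims_gate, config.batch_norm)
    return MoEModel(config=config, experts=experts, gate=gate)


def parameter_count(model: MoEModel) -> int:
    """Number of trainable scalars (weights, biases, BN scale/shift)."""
    return int(sum(p.data.size for p in model.parameters()))


def _batchnorm(h: Tensor, layer: dict, mode: str, update_stats: bool) -> Tensor:
    if mode == "train":
        mu = E.tmean(h, axis=0, keepdims=True)
        xc = h - mu
        var = E.tmean(xc * xc, axis=0, keepdims=True)
        if update_stats:
            m = h.data.shape[0]
            unbiased = var.data.ravel() * (m / max(m - 1, 1))
            layer["running_mean"] *= 1.0 - _BN_MOMENTUM
            layer["running_mean"] += _BN_MOMENTUM * mu.data.ravel()
            layer["running_var"] *= 1.0 - _BN_MOMENTUM
            layer["running_var"] += _BN_MOMENTUM * unbiased
        xhat = xc * (E.power(var + _BN_EPS, -0.5))
    else:
        mu = Tensor(layer["running_mean"])
        inv = Tensor(1.0 / np.sqrt(layer["running_var"] + _BN_EPS))
        xhat = (h - mu) * inv
    return xhat * layer["gamma"] + layer["beta"]


def _forward_stack(stack: list[dict], X: Tensor, config: MoEConfig, mode: str,
                   rng: np.random.Generator | None = None, update_stats: bool = False) -> Tensor:
    """Dense → batch-norm → ReLU → dropout per hidden layer; linear head."""
    h = X
    n_layers = len(stack)
    for li, layer in enumerate(stack):
        h = h @ layer["W"] + layer["b"]
        if li < n_layers - 1:
            if config.batch_norm:
                h = _batchnorm(h, layer, mode, update_stats)
            h = E.relu(h)
            if mode == "train" and config.dropout_rate > 0:
                if rng is None:
                    raise ValueError("dropout in train mode requires an rng")
                keep = 1.0 - config.dropout_rate
                mask = (rng.random(h.data.shape) < keep) / keep
                h = h * Tensor(mask)
    return h


def _check_input(model: MoEModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"input has {X.shape[-1] if X.ndim else 0} features, "
            f"model expects {model.config.input_dim}"
        )
    return X


def expert_out(model: MoEModel, i: int, X: Tensor, mode: str = "eval",
               rng=None, update_stats: bool = False) -> Tensor:
    """Graph-building forward pass of expert ``i`` (output shape (m, 1))."""
    if not 0 <= i < model.config.n_experts:
        raise IndexError(f"expert index {i} out of range")
    return _forward_stack(model.experts[i], X, model.config, mode, rng, update_stats)


def gate_out(model: MoEModel, X: Tensor, mode: str = "eval",
             rng=None, update_stats: bool = False) -> Tensor:
    """Graph-building gate forward pass: per-sample simplex weights (m, E)."""
    logits = _forward_stack(model.gate, X, model.config, mode, rng, update_stats)
    return E.softmax(logits, axis=1)


def expert_forward(model: MoEModel, i: int, X: np.ndarray, mode: str = "eval", rng=None) -> np.ndarray:
    """Predictions of a single expert, in years (length m)."""
    X = _check_input(model, X)
    with E.no_graph():
        out = expert_out(model, i, Tensor(X), mode, rng).data.ravel()
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("expert forward produced non-finite values")
    return out


def gate_forward(model: MoEModel, X: np.ndarray, mode: str = "eval", rng=None) -> np.ndarray:
    """Gate weights, one row on the E-simplex per sample (m × E)."""
    X = _check_input(model, X)
    with E.no_graph():
        p = gate_out(model, X if isinstance(X, Tensor) else Tensor(X), mode, rng).data
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("gate forward produced non-finite values")
    return p


def predict(model: MoEModel, X: np.ndarray) -> np.ndarray:
    """Gate-weighted convex combination of expert outputs (eval mode, years)."""
    X = _check_input(model, X)
    p = gate_forward(model, X)
    ys = np.stack([expert_forward(model, i, X) for i in range(model.config.n_experts)], axis=1)
    return (p * ys).sum(axis=1)


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model: MoEModel, path) -> None:
    """Serialize config + parameters + BN running stats to a single .npz."""
    arrays = {"__config__": np.frombuffer(
        json.dumps(dataclasses.asdict(model.config)).encode(), dtype=np.uint8)}
    for si, stack in enumerate([*model.experts, model.gate]):
        tag = f"e{si}" if si < model.config.n_experts else "gate"
        for li, layer in enumerate(stack):
            for key, val in layer.items():
                arr = val.data if isinstance(val, Tensor) else val
                arrays[f"{tag}.{li}.{key}"] = arr
    np.savez(path, **arrays)


def load_checkpoint(path) -> MoEModel:
    with np.load(path) as npz:
        doc = json.loads(bytes(npz["__config__"]).decode())
        doc["hidden_widths"] = tuple(doc["hidden_widths"])
        config = MoEConfig(**doc)
        model = init_model(config)
        for si, stack in enumerate([*model.experts, model.gate]):
            tag = f"e{si}" if si < config.n_experts else "gate"
            for li, layer in enumerate(stack):
                for key in list(layer):
                    arr = npz[f"{tag}.{li}.{key}"]
                    if isinstance(layer[key], Tensor):
                        layer[key].data = np.asarray(arr, dtype=np.float64)
                    else:
                        layer[key] = np.asarray(arr, dtype=np.float64)
    return model
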