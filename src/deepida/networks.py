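"""Per-view feed-forward networks producing top-layer representations.

Each view ``d`` is transformed by a multilayer perceptron
``H_d = s(W_M s(... s(W_1 X + b_1) ...) + b_M)`` whose output dimension
``o_d`` must stay below the sample size so the top-layer total
covariance is invertible.  The activation is applied on *every* layer
including the last; a linear head can be requested explicitly.

The module is deliberately framework-free: forward passes cache the
pre-activations so :func:`backward` can push a gradient with respect to
the representation back onto the weights and biases.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "ModelParams",
    "ACTIVATIONS",
    "init_params",
    "forward",
    "forward_cached",
    "backward",
    "save_model",
    "load_model",
]

LEAKY_SLOPE = 0.01


def _leaky(z):
    return np.where(z >= 0, z, LEAKY_SLOPE * z)


def _leaky_grad(z):
    return np.where(z >= 0, 1.0, LEAKY_SLOPE)


def _tanh(z):
    return np.tanh(z)


def _tanh_grad(z):
    t = np.tanh(z)
    return 1.0 - t * t


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _sigmoid_grad(z):
    s = _sigmoid(z)
    return s * (1.0 - s)


def _identity(z):
    return z


def _identity_grad(z):
    return np.ones_like(z)


ACTIVATIONS = {
    "leaky_relu": (_leaky, _leaky_grad),
    "tanh": (_tanh, _tanh_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "linear": (_identity, _identity_grad),
}


@dataclass
class NetworkSpec:
    """Architecture of one view's network."""

    input_dim: int
    hidden_dims: list[int] = field(default_factory=lambda: [256, 64])
    output_dim: int = 20
    activation: str = "leaky_relu"
    final_activation: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("all dimensions must be >= 1")
        if any(h < 1 for h in self.hidden_dims):
            raise ValueError("all dimensions must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def layer_dims(self) -> list[int]:
        return [self.input_dim, *self.hidden_dims, self.output_dim]

    @classmethod
    def preset(cls, name: str, input_dim: int, **kwargs) -> "NetworkSpec":
        """Named architectures: ``"shallow"`` (3 layers, for sample sizes
        in the hundreds) or ``"deep"`` (8 layers, for problems with both
        n and p above ~1000)."""
        presets = {
            "shallow": [256, 64],
            "deep": [1024, 512, 256, 128, 64, 64, 32],
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}")
        return cls(input_dim=input_dim, hidden_dims=presets[name], **kwargs)


@dataclass
class ModelParams:
    """Weights ``W_m`` (``c_m x c_{m-1}``) and biases ``b_m`` per layer."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "leaky_relu"
    final_activation: bool = True

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def copy(self) -> "ModelParams":
        return ModelParams(
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            self.activation,
            self.final_activation,
        )


def init_params(spec: NetworkSpec, seed: int | None = None) -> ModelParams:
    """He/Glorot-scaled random weights, zero biases, deterministic per seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dims = spec.layer_dims
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        weights.append(rng.standard_normal((fan_out, fan_in)) * scale)
        biases.append(np.zeros(fan_out))
    return ModelParams(weights, biases, spec.activation, spec.final_activation)


def _act_pair(params: ModelParams, m: int):
    last = m == params.n_layers - 1
    if last and not params.final_activation:
        return ACTIVATIONS["linear"]
    return ACTIVATIONS[params.activation]


def forward(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Apply the network row-wise: returns the ``n x o_d`` representation."""
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[1] != params.weights[0].shape[1]:
        raise ValueError(
            f"input has {A.shape[1] if A.ndim == 2 else '?'} columns, "
            f"network expects {params.weights[0].shape[1]}"
        )
    for m, (W, b) in enumerate(zip(params.weights, params.biases)):
        act, _ = _act_pair(params, m)
        A = act(A @ W.T + b)
    return A


def forward_cached(params: ModelParams, X: np.ndarray):
    """Forward pass keeping pre-activations and inputs for backprop."""
    A = np.asarray(X, dtype=float)
    if A.shape[1] != params.weights[0].shape[1]:
        raise ValueError("input width mismatch")
    inputs, preacts = [], []
    for m, (W, b) in enumerate(zip(params.weights, params.biases)):
        act, _ = _act_pair(params, m)
        inputs.append(A)
        Z = A @ W.T + b
        preacts.append(Z)
        A = act(Z)
    return A, (inputs, preacts)


def backward(params: ModelParams, cache, grad_H: np.ndarray):
    """Backpropagate ``dLoss/dH`` to per-layer weight/bias gradients."""
    inputs, preacts = cache
    grad_W = [None] * params.n_layers
    grad_b = [None] * params.n_layers
    bar = grad_H
    for m in range(params.n_layers - 1, -1, -1):
        _, dact = _act_pair(params, m)
        barZ = bar * dact(preacts[m])
        grad_W[m] = barZ.T @ inputs[m]
        grad_b[m] = barZ.sum(axis=0)
        if m > 0:
            bar = barZ @ params.weights[m]
    return grad_W, grad_b


# ---------------------------------------------------------------------------
# serialization: versioned zip with arrays + JSON header
# ---------------------------------------------------------------------------

def save_model(path, specs: list[NetworkSpec], params: list[ModelParams],
               extra: dict | None = None) -> None:
    header = {
        "format_version": 1,
        "n_views": len(specs),
        "specs": [
            {
                "input_dim": s.input_dim,
                "hidden_dims": list(s.hidden_dims),
                "output_dim": s.output_dim,
                "activation": s.activation,
                "final_activation": s.final_activation,
                "seed": s.seed,
            }
            for s in specs
        ],
        "extra": extra or {},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        for d, p in enumerate(params):
            for m, (W, b) in enumerate(zip(p.weights, p.biases)):
                zf.writestr(f"view{d}_W{m}.npy", _np_bytes(W))
                zf.writestr(f"view{d}_b{m}.npy", _np_bytes(b))


def _np_bytes(arr: np.ndarray) -> bytes:
    import io

    buf = io.BytesIO()
    np.save(buf, arr)
    return buf.getvalue()


def load_model(path):
    import io

    with zipfile.ZipFile(path, "r") as zf:
        header = json.loads(zf.read("header.json"))
        specs, params = [], []
        for d, sd in enumerate(header["specs"]):
            spec = NetworkSpec(
                input_dim=sd["input_dim"],
                hidden_dims=list(sd["hidden_dims"]),
                output_dim=sd["output_dim"],
                activation=sd["activation"],
                final_activation=sd["final_activation"],
                seed=sd["seed"],
            )
            weights, biases = [], []
            for m in range(len(spec.layer_dims) - 1):
                weights.append(np.load(io.BytesIO(zf.read(f"view{d}_W{m}.npy"))))
                biases.append(np.load(io.BytesIO(zf.read(f"view{d}_b{m}.npy"))))
            specs.append(spec)
            params.append(ModelParams(weights, biases, spec.activation,
                                      spec.final_activation))
    return specs, params, header.get("extra", {})
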