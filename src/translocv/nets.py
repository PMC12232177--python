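"""Minimal feed-forward networks with hand-written backprop.

The two machine-learning collective variables in this package (the
Fisher-discriminant CV and the multitask autoencoder CV) need three things
from their networks: a forward pass, gradients of a scalar loss with respect
to the weights, and gradients of the network output with respect to the
*inputs* (the bias force of the enhanced-sampling engine is propagated to
the physical coordinates through the CV by the chain rule).  A small dense
MLP written on numpy provides all three with no further dependencies and is
fast enough at the layer widths used here (inputs of ~69 descriptors).

Conventions: data matrices are (n_frames, n_features); a layer is
``X @ W + b`` with ``W`` of shape (fan_in, fan_out).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["MLP", "Adam", "Standardizer", "relu", "shifted_softplus"]


# ---------------------------------------------------------------------------
# activations (value + derivative as a function of the pre-activation)

def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0.0).astype(z.dtype)


def shifted_softplus(z: np.ndarray) -> np.ndarray:
    # log(1+e^z) - log 2, so that act(0) = 0; numerically stable
    return np.logaddexp(z, 0.0) - np.log(2.0)


def _shifted_softplus_grad(z: np.ndarray) -> np.ndarray:
    return expit(z)  # sigmoid, stable C implementation


_ACTIVATIONS = {
    "relu": (relu, _relu_grad),
    "shifted_softplus": (shifted_softplus, _shifted_softplus_grad),
}


class Standardizer:
    """Per-feature zero-mean / unit-variance transform fitted on training data."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        std = np.asarray(std, dtype=float)
        self.std = np.where(std > 0, std, 1.0)

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        return cls(X.mean(axis=0), X.std(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    def jacobian_diag(self) -> np.ndarray:
        """d(standardized)/d(raw), a diagonal given elementwise."""
        return 1.0 / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]))


class MLP:
    """Dense network; hidden layers share one activation, output is linear.

    ``widths`` includes input and output sizes, e.g. ``[69, 30, 20, 15, 10, 5]``
    is four hidden layers of a 69-input, 5-output network with the activation
    applied after every layer except the last.
    """

    def __init__(self, widths: list[int], activation: str, rng: np.random.Generator):
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.widths = list(widths)
        self.activation = activation
        self._act, self._act_grad = _ACTIVATIONS[activation]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init, fine for both activations
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._cache: list[np.ndarray] | None = None

    # -- forward / backward -------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        A = np.atleast_2d(np.asarray(X, dtype=float))
        acts = [A]  # post-activation of each layer (input counts as layer 0)
        zs = []
        for i in range(self.n_layers):
            Z = A @ self.W[i] + self.b[i]
            A = self._act(Z) if i < self.n_layers - 1 else Z
            zs.append(Z)
            acts.append(A)
        if cache:
            self._cache = (acts, zs)
        return A

    def backward(self, dY: np.ndarray) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        """Backprop ``dLoss/dY`` through the cached forward pass.

        Returns (dLoss/dX, dLoss/dW list, dLoss/db list).  The cache survives
        the call, so several output components can be backpropagated from one
        forward pass.
        """
        if self._cache is None:
            raise RuntimeError("forward(..., cache=True) must precede backward()")
        acts, zs = self._cache
        dZ = np.atleast_2d(np.asarray(dY, dtype=float))
        dWs: list[np.ndarray] = [np.empty(0)] * self.n_layers
        dbs: list[np.ndarray] = [np.empty(0)] * self.n_layers
        for i in range(self.n_layers - 1, -1, -1):
            dWs[i] = acts[i].T @ dZ
            dbs[i] = dZ.sum(axis=0)
            dA = dZ @ self.W[i].T
            if i > 0:
                dZ = dA * self._act_grad(zs[i - 1])
            else:
                dX = dA
        return dX, dWs, dbs

    def input_gradient(self, x: np.ndarray, component: int = 0) -> np.ndarray:
        """Gradient of one output component w.r.t. the inputs, per frame."""
        X = np.atleast_2d(np.asarray(x, dtype=float))
        out = self.forward(X, cache=True)
        dY = np.zeros_like(out)
        dY[:, component] = 1.0
        dX, _, _ = self.backward(dY)
        return dX

    def value_and_input_jacobian(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Output and full Jacobian d(out)/d(in) for a single input vector.

        The input is replicated once per output component so that a single
        backward pass seeded with the identity yields the whole Jacobian;
        this is the biased-sampling hot path.
        """
        x = np.asarray(x, dtype=float).reshape(-1)
        n_out = self.widths[-1]
        X = np.broadcast_to(x, (n_out, len(x)))
        out = self.forward(X, cache=True)
        J, _, _ = self.backward(np.eye(n_out))
        return out[0], J

    # -- parameter utilities -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def l2_penalty(self) -> float:
        return float(sum(np.sum(w * w) for w in self.W))

    def l2_gradients(self) -> list[np.ndarray]:
        return [2.0 * w for w in self.W] + [np.zeros_like(b) for b in self.b]

    def to_dict(self) -> dict:
        return {
            "widths": self.widths,
            "activation": self.activation,
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        net = cls(d["widths"], d["activation"], np.random.default_rng(0))
        net.W = [np.asarray(w, dtype=float) for w in d["W"]]
        net.b = [np.asarray(b, dtype=float) for b in d["b"]]
        return net


@dataclass
class Adam:
    """Adaptive-moment gradient descent over a flat list of parameter arrays."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list[np.ndarray] = field(default_factory=list)
    _v: list[np.ndarray] = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def save_model_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
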