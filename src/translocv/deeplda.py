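"""Fisher-discriminant neural-network CV separating two metastable states.

A feed-forward network maps the contact descriptors to a small hidden space;
a trainable direction in that space gives a scalar projection whose Fisher
ratio — between-state variance of the class means over within-state
variance — is maximized.  After training the projection is passed through a
saturating (Lorentzian) transform and affinely normalized so that the two
training states sit at +1 and -1, positive state first.  The resulting
scalar is the 1-D collective variable used to drive biased sampling between
the states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, SchemaError, TrainingDivergenceError
from .nets import MLP, Adam, Standardizer
from .tables import DescriptorTable

__all__ = ["DeepLDAConfig", "DeepLDACV", "fisher_ratio", "train_deep_lda", "evaluate_cv"]


def fisher_ratio(projections, labels, sw_reg: float = 0.0) -> float:
    """Two-class Fisher ratio of 1-D projections.

    Between-class scatter is the (equal-weight) variance of the two class
    means about their midpoint; within-class scatter is the mean of the two
    class variances, optionally inflated by ``sw_reg``.  Scale-invariant when
    ``sw_reg`` is 0.
    """
    z = np.asarray(projections, dtype=float).ravel()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise InputError(f"need exactly two label classes, got {len(classes)}")
    z0, z1 = z[labels == classes[0]], z[labels == classes[1]]
    if len(z0) == 0 or len(z1) == 0:
        raise InputError("each class needs at least one frame")
    between = 0.25 * (z0.mean() - z1.mean()) ** 2
    within = 0.5 * (z0.var() + z1.var()) + sw_reg
    if within == 0.0:
        return 0.0 if between == 0.0 else float("inf")
    return float(between / within)


@dataclass(frozen=True)
class DeepLDAConfig:
    """Training hyperparameters (defaults follow the published protocol)."""

    layer_widths: tuple = (69, 30, 20, 15, 10, 5)
    activation: str = "relu"
    epochs: int = 500
    learning_rate: float = 5.0e-4
    l2_regularization: float = 1.0e-4
    sw_regularization: float = 0.05
    lorentzian_scale: float = 40.0
    projection_regularization: float = 1.0
    positive_state: str = "PRE"
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "learning_rate", "l2_regularization",
                     "sw_regularization", "lorentzian_scale"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


def _lorentzian(z: np.ndarray, scale: float) -> np.ndarray:
    """Odd saturating transform, ~identity for |z| << scale, bounded by ±scale."""
    return z / np.sqrt(1.0 + (z / scale) ** 2)


def _lorentzian_grad(z: np.ndarray, scale: float) -> np.ndarray:
    return (1.0 + (z / scale) ** 2) ** -1.5


@dataclass
class DeepLDACV:
    """Trained 1-D discriminant CV; output bounded, positive state at +1."""

    net: MLP
    direction: np.ndarray
    standardizer: Standardizer
    lorentzian_scale: float
    offset: float  # affine normalization: cv = (L(z) - offset) / halfspan
    halfspan: float
    positive_state: str
    negative_state: str
    sign_flipped: bool
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_inputs(self) -> int:
        return self.net.widths[0]

    def _check_dim(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise SchemaError(
                f"model expects {self.n_inputs} descriptors, got {X.shape[1]}"
            )
        return X

    def raw_projection(self, X) -> np.ndarray:
        X = self._check_dim(X)
        h = self.net.forward(self.standardizer.transform(X))
        return h @ self.direction

    def evaluate(self, X) -> np.ndarray:
        """CV value(s); batched evaluation equals per-frame evaluation."""
        z = self.raw_projection(X)
        return (_lorentzian(z, self.lorentzian_scale) - self.offset) / self.halfspan

    __call__ = evaluate

    def gradient(self, x) -> np.ndarray:
        """d(cv)/d(raw descriptors) for each frame; shape (n, n_inputs)."""
        X = self._check_dim(x)
        Xs = self.standardizer.transform(X)
        h = self.net.forward(Xs, cache=True)
        z = h @ self.direction
        dcv_dz = _lorentzian_grad(z, self.lorentzian_scale) / self.halfspan
        dh = dcv_dz[:, None] * self.direction[None, :]
        dXs, _, _ = self.net.backward(dh)
        return dXs * self.standardizer.jacobian_diag()

    def value_and_jacobian(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """CV value (length-1 array) and d(cv)/d(raw descriptors), one frame."""
        Xs = (np.asarray(d, dtype=float) - self.standardizer.mean) / self.standardizer.std
        h, Jh = self.net.value_and_input_jacobian(Xs)
        z = float(h @ self.direction)
        cv = (_lorentzian(z, self.lorentzian_scale) - self.offset) / self.halfspan
        dcv_dz = _lorentzian_grad(np.array(z), self.lorentzian_scale) / self.halfspan
        J = (dcv_dz * (self.direction @ Jh) * self.standardizer.jacobian_diag())[None, :]
        return np.array([cv]), J

    # -- serialization -------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "kind": "deep_lda_cv",
            "net": self.net.to_dict(),
            "direction": self.direction.tolist(),
            "standardizer": self.standardizer.to_dict(),
            "lorentzian_scale": self.lorentzian_scale,
            "offset": self.offset,
            "halfspan": self.halfspan,
            "positive_state": self.positive_state,
            "negative_state": self.negative_state,
            "sign_flipped": self.sign_flipped,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DeepLDACV":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("kind") != "deep_lda_cv":
            raise SchemaError("not a Deep-LDA CV model file")
        return cls(
            net=MLP.from_dict(d["net"]),
            direction=np.asarray(d["direction"]),
            standardizer=Standardizer.from_dict(d["standardizer"]),
            lorentzian_scale=d["lorentzian_scale"],
            offset=d["offset"],
            halfspan=d["halfspan"],
            positive_state=d["positive_state"],
            negative_state=d["negative_state"],
            sign_flipped=d["sign_flipped"],
        )


def train_deep_lda(table: DescriptorTable, config: DeepLDAConfig | None = None) -> DeepLDACV:
    """Maximize the Fisher ratio of the network projection over two states.

    The network output layer feeds a trainable discriminant direction; the
    loss is -log(Fisher ratio) with the within-scatter regularization added
    to the denominator, plus L2 weight decay.  Optimization is full-batch
    adaptive-moment descent, which makes training deterministic for a fixed
    seed.
    """
    config = config or DeepLDAConfig()
    if table.labels is None:
        raise InputError("training table must carry state labels")
    classes = sorted(set(table.labels))
    if len(classes) != 2:
        raise InputError(f"need exactly two labeled states, got {classes}")
    if config.positive_state in classes:
        pos = config.positive_state
        neg = classes[0] if classes[1] == pos else classes[1]
    else:
        pos, neg = classes
    X = table.values()
    if X.shape[1] != config.layer_widths[0]:
        raise SchemaError(
            f"config expects {config.layer_widths[0]} descriptors, table has {X.shape[1]}"
        )
    mask_pos = table.labels == pos
    n_pos, n_neg = int(mask_pos.sum()), int((~mask_pos).sum())
    if min(n_pos, n_neg) < 100:
        raise InputError("need at least 100 frames per state")

    std = Standardizer.fit(X)
    Xs = std.transform(X)
    rng = np.random.default_rng(config.seed)
    net = MLP(list(config.layer_widths), config.activation, rng)
    w = rng.normal(0.0, 1.0, size=config.layer_widths[-1])
    opt = Adam(lr=config.learning_rate)

    idx_pos = np.flatnonzero(mask_pos)
    idx_neg = np.flatnonzero(~mask_pos)
    history = np.empty(config.epochs)

    for epoch in range(config.epochs):
        h = net.forward(Xs, cache=True)
        zraw = h @ w
        # the saturating transform is part of the objective: it bounds the
        # discriminant during training, so the CV keeps a usable gradient
        # instead of running off to the plateaus
        z = _lorentzian(zraw, config.lorentzian_scale)
        z0, z1 = z[idx_pos], z[idx_neg]
        mu0, mu1 = z0.mean(), z1.mean()
        between = 0.25 * (mu0 - mu1) ** 2
        within = 0.5 * (z0.var() + z1.var()) + config.sw_regularization
        ratio = between / within
        # keep the raw discriminant inside the responsive range of the
        # saturating transform: a CV stuck on the plateaus has no gradient
        # left to transmit bias forces
        proj_pen = config.projection_regularization * float(
            np.mean(zraw**2)
        ) / config.lorentzian_scale**2
        loss = -np.log(ratio + 1e-12) + proj_pen + config.l2_regularization * (
            net.l2_penalty() + float(w @ w)
        )
        history[epoch] = loss
        if not np.isfinite(loss):
            raise TrainingDivergenceError(f"loss became non-finite at epoch {epoch}")

        # dL/dz through ratio = B/W: dL/dB = -1/B, dL/dW = +1/W
        dz = np.zeros_like(z)
        dB = -1.0 / (between + 1e-12)
        dW = 1.0 / within
        dz[idx_pos] += dB * 0.5 * (mu0 - mu1) / n_pos
        dz[idx_neg] -= dB * 0.5 * (mu0 - mu1) / n_neg
        dz[idx_pos] += dW * 0.5 * 2.0 * (z0 - mu0) / n_pos
        dz[idx_neg] += dW * 0.5 * 2.0 * (z1 - mu1) / n_neg

        dz = dz * _lorentzian_grad(zraw, config.lorentzian_scale)
        dz += (
            config.projection_regularization
            * 2.0
            * zraw
            / (len(zraw) * config.lorentzian_scale**2)
        )
        dh = dz[:, None] * w[None, :]
        dw = h.T @ dz + 2.0 * config.l2_regularization * w
        _, dWs, dbs = net.backward(dh)
        l2g = net.l2_gradients()
        grads = [
            g + config.l2_regularization * lg for g, lg in zip(dWs, l2g[: net.n_layers])
        ] + dbs + [dw]
        opt.step(net.W + net.b + [w], grads)

    # sign convention + affine normalization: positive state -> +1, other -> -1
    h = net.forward(Xs)
    z = h @ w
    flipped = z[idx_pos].mean() < z[idx_neg].mean()
    if flipped:
        w = -w
        z = -z
    zb = _lorentzian(z, config.lorentzian_scale)
    m_pos, m_neg = zb[idx_pos].mean(), zb[idx_neg].mean()
    offset = 0.5 * (m_pos + m_neg)
    halfspan = 0.5 * (m_pos - m_neg)
    if halfspan <= 0:
        raise TrainingDivergenceError("training failed to separate the states")

    return DeepLDACV(
        net=net,
        direction=w,
        standardizer=std,
        lorentzian_scale=config.lorentzian_scale,
        offset=float(offset),
        halfspan=float(halfspan),
        positive_state=pos,
        negative_state=neg,
        sign_flipped=bool(flipped),
        loss_history=history,
    )


def evaluate_cv(model, X) -> np.ndarray:
    """Evaluate a trained CV model on raw descriptor vectors or tables."""
    if isinstance(X, DescriptorTable):
        X = X.values()
    return model.evaluate(X)
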