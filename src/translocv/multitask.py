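"""Semisupervised 2-D collective variable for the two translocation paths.

A 1-D discriminant CV can carry a system between the two end states but
cannot tell the two stepwise mechanisms apart.  This module trains a 2-D CV
as the latent space of an autoencoder optimized for two tasks at once:

* reconstruction (unsupervised) on unlabeled frames from reactive
  trajectories, so the latent space organizes the transition regions, and
* a targeted-discriminant (TDA) loss on state-labeled frames, which pins
  each metastable state's latent distribution to a preassigned Gaussian
  (center μ_tg, width σ_tg).

Default targets place PRE, INT2, INT1, POST at (-6,-6), (-3,3), (3,-3),
(6,6) with σ_tg = 0.2, so the two paths occupy opposite off-diagonal
quadrants of the CV plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, SchemaError, TrainingDivergenceError
from .nets import MLP, Adam, Standardizer
from .tables import DescriptorTable

__all__ = [
    "MultiTaskConfig",
    "MultiTaskCV",
    "reconstruction_loss",
    "tda_loss",
    "train_multitask",
]

DEFAULT_TARGET_CENTERS = {
    "PRE": (-6.0, -6.0),
    "INT2": (-3.0, 3.0),
    "INT1": (3.0, -3.0),
    "POST": (6.0, 6.0),
}


@dataclass(frozen=True)
class MultiTaskConfig:
    """Architecture, targets and loss weights of the multitask CV."""

    encoder_widths: tuple = (69, 50, 30, 15, 5, 2)
    decoder_widths: tuple = (2, 5, 15, 30, 50, 69)
    activation: str = "shifted_softplus"
    epochs: int = 500
    learning_rate: float = 1.0e-3
    target_centers: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_CENTERS))
    target_sigma: float = 0.2
    reconstruction_weight: float = 1.0
    tda_mean_weight: float = 1.0
    tda_sigma_weight: float = 1.0
    labeled_batch_per_state: int = 500
    unlabeled_batch: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.encoder_widths[-1] != 2:
            raise InputError("latent dimension must be 2")
        if self.decoder_widths[0] != 2 or self.decoder_widths[-1] != self.encoder_widths[0]:
            raise InputError("decoder must invert the encoder's shape")
        if self.target_sigma <= 0:
            raise InputError("target_sigma must be positive")
        centers = [tuple(c) for c in self.target_centers.values()]
        if len(set(centers)) != len(centers):
            raise InputError("target centers must be pairwise distinct")


@dataclass
class MultiTaskCV:
    """Trained encoder/decoder pair; the encoder output is the 2-D CV."""

    encoder: MLP
    decoder: MLP
    standardizer: Standardizer
    state_centers: dict
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_inputs(self) -> int:
        return self.encoder.widths[0]

    def _check_dim(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise SchemaError(
                f"model expects {self.n_inputs} descriptors, got {X.shape[1]}"
            )
        return X

    def evaluate(self, X) -> np.ndarray:
        """Latent CV coordinates, shape (n_frames, 2)."""
        if isinstance(X, DescriptorTable):
            X = X.values()
        X = self._check_dim(X)
        return self.encoder.forward(self.standardizer.transform(X))

    __call__ = evaluate

    def reconstruct(self, X) -> np.ndarray:
        """Decoder output in standardized descriptor space."""
        return self.decoder.forward(self.evaluate(X))

    def gradient(self, x, component: int) -> np.ndarray:
        """d(latent_component)/d(raw descriptors) per frame."""
        X = self._check_dim(x)
        Xs = self.standardizer.transform(X)
        dXs = self.encoder.input_gradient(Xs, component=component)
        return dXs * self.standardizer.jacobian_diag()

    def value_and_jacobian(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """CV value and d(cv)/d(raw descriptors) for one descriptor vector."""
        Xs = (np.asarray(d, dtype=float) - self.standardizer.mean) / self.standardizer.std
        s, J = self.encoder.value_and_input_jacobian(Xs)
        return s, J * self.standardizer.jacobian_diag()

    def save(self, path) -> None:
        payload = {
            "kind": "multitask_cv",
            "encoder": self.encoder.to_dict(),
            "decoder": self.decoder.to_dict(),
            "standardizer": self.standardizer.to_dict(),
            "state_centers": {k: list(v) for k, v in self.state_centers.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "MultiTaskCV":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("kind") != "multitask_cv":
            raise SchemaError("not a multitask CV model file")
        return cls(
            encoder=MLP.from_dict(d["encoder"]),
            decoder=MLP.from_dict(d["decoder"]),
            standardizer=Standardizer.from_dict(d["standardizer"]),
            state_centers={k: np.asarray(v) for k, v in d["state_centers"].items()},
        )


# ---------------------------------------------------------------------------
# losses

def reconstruction_loss(batch: np.ndarray, model: MultiTaskCV) -> float:
    """Mean squared reconstruction error in standardized descriptor space."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise InputError("batch must be nonempty")
    if batch.shape[1] != model.n_inputs:
        raise SchemaError("batch dimensionality does not match the model")
    Xs = model.standardizer.transform(batch)
    Xhat = model.decoder.forward(model.encoder.forward(Xs))
    return float(np.mean((Xhat - Xs) ** 2))


def tda_loss(
    latent_batch: np.ndarray,
    labels,
    target_centers: dict,
    target_sigma: float,
    mean_weight: float = 1.0,
    sigma_weight: float = 1.0,
) -> float:
    """Squared deviation of per-state latent means/SDs from their targets.

    L = sum over states and latent components of
    ``mean_weight*(mu_batch-mu_tg)^2 + sigma_weight*(sd_batch-sd_tg)^2``;
    zero iff every state hits its target exactly.
    """
    Z = np.atleast_2d(np.asarray(latent_batch, dtype=float))
    labels = np.asarray(labels)
    total = 0.0
    for state, center in target_centers.items():
        zs = Z[labels == state]
        if len(zs) < 2:
            raise InputError(f"state {state} has {len(zs)} frames in batch (need >= 2)")
        mu = zs.mean(axis=0)
        sd = zs.std(axis=0)
        total += mean_weight * np.sum((mu - np.asarray(center)) ** 2)
        total += sigma_weight * np.sum((sd - target_sigma) ** 2)
    return float(total)


# ---------------------------------------------------------------------------
# training

def _tda_latent_grad(Z, labels, centers, sigma_tg, a, b):
    """dL_TDA/dZ for the stratified labeled batch."""
    dZ = np.zeros_like(Z)
    for state, center in centers.items():
        idx = np.flatnonzero(labels == state)
        zs = Z[idx]
        n = len(idx)
        mu = zs.mean(axis=0)
        sd = zs.std(axis=0)
        dZ[idx] += a * 2.0 * (mu - np.asarray(center)) / n
        safe_sd = np.where(sd > 1e-12, sd, 1.0)
        dZ[idx] += b * 2.0 * (sd - sigma_tg) * (zs - mu) / (n * safe_sd)
    return dZ


def train_multitask(
    labeled: DescriptorTable,
    reactive: DescriptorTable | None,
    config: MultiTaskConfig | None = None,
) -> MultiTaskCV:
    """Jointly minimize reconstruction + TDA losses on the two datasets.

    Each epoch draws one stratified labeled sub-batch (equal frames per
    state) for the TDA term and one independent unlabeled sub-batch for the
    reconstruction term, then takes a single adaptive-moment step on the
    summed gradients.  When ``reactive`` is None the reconstruction task
    falls back to the labeled frames.
    """
    config = config or MultiTaskConfig()
    if labeled.labels is None:
        raise InputError("labeled table must carry state labels")
    states = list(config.target_centers)
    present = set(labeled.labels)
    missing = [s for s in states if s not in present]
    if missing:
        raise InputError(f"labeled table is missing states {missing}")
    X = labeled.values()
    if X.shape[1] != config.encoder_widths[0]:
        raise SchemaError(
            f"config expects {config.encoder_widths[0]} descriptors, table has {X.shape[1]}"
        )
    Xu = labeled.values() if reactive is None or len(reactive) == 0 else reactive.values()
    if Xu.shape[1] != X.shape[1]:
        raise SchemaError("labeled and unlabeled tables disagree on descriptor count")

    std = Standardizer.fit(np.concatenate([X, Xu]))
    Xs = std.transform(X)
    Xus = std.transform(Xu)
    state_idx = {s: np.flatnonzero(labeled.labels == s) for s in states}

    rng = np.random.default_rng(config.seed)
    enc = MLP(list(config.encoder_widths), config.activation, rng)
    dec = MLP(list(config.decoder_widths), config.activation, rng)
    opt = Adam(lr=config.learning_rate)
    centers = {s: np.asarray(c, dtype=float) for s, c in config.target_centers.items()}
    a, b = config.tda_mean_weight, config.tda_sigma_weight
    wrec = config.reconstruction_weight
    history = np.empty(config.epochs)

    for epoch in range(config.epochs):
        # --- TDA task on a stratified labeled batch
        rows = np.concatenate(
            [
                rng.choice(state_idx[s], size=min(config.labeled_batch_per_state, len(state_idx[s])), replace=False)
                for s in states
            ]
        )
        lab = labeled.labels[rows]
        Xl = Xs[rows]
        Z = enc.forward(Xl, cache=True)
        l_tda = tda_loss(Z, lab, centers, config.target_sigma, a, b)
        dZ = _tda_latent_grad(Z, lab, centers, config.target_sigma, a, b)
        _, dWe1, dbe1 = enc.backward(dZ)

        # --- reconstruction task on an unlabeled batch
        rows_u = rng.choice(len(Xus), size=min(config.unlabeled_batch, len(Xus)), replace=False)
        Xb = Xus[rows_u]
        Zu = enc.forward(Xb, cache=True)
        Xhat = dec.forward(Zu, cache=True)
        l_rec = float(np.mean((Xhat - Xb) ** 2))
        dXhat = wrec * 2.0 * (Xhat - Xb) / Xhat.size
        dZu, dWd, dbd = dec.backward(dXhat)
        _, dWe2, dbe2 = enc.backward(dZu)

        loss = l_tda + wrec * l_rec
        history[epoch] = loss
        if not np.isfinite(loss):
            raise TrainingDivergenceError(f"loss became non-finite at epoch {epoch}")

        params = enc.W + enc.b + dec.W + dec.b
        grads = (
            [g1 + g2 for g1, g2 in zip(dWe1, dWe2)]
            + [g1 + g2 for g1, g2 in zip(dbe1, dbe2)]
            + dWd
            + dbd
        )
        opt.step(params, grads)

    return MultiTaskCV(
        encoder=enc,
        decoder=dec,
        standardizer=std,
        state_centers=centers,
        loss_history=history,
    )
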