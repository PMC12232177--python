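"""On-the-fly probability enhanced sampling (OPES) on learned CVs.

The bias is built from a running kernel-density estimate p(s) of the sampled
CV distribution, driving sampling toward the well-tempered target
P_tg(s) ∝ [P(s)]^(1/γ):

    V(s) = ((γ-1)/β) [log(p(s)/Z + ε) - log ε]

with Z the maximum of the estimate over deposited kernel centers and
ε = 1/(exp(βΔE/γ) - 1), so the bias is zero in never-visited regions and
reaches exactly (1-1/γ)·ΔE where sampling is densest — ΔE is the BARRIER
parameter, the largest free-energy barrier the run is expected to overcome.
Kernels are deposited every STRIDE steps at the current CV value with a
bandwidth that starts at SIGMA and shrinks with the number of depositions;
near-coincident kernels are merged.  The biasfactor defaults to γ = βΔE.

Forces on the latent coordinates are obtained by the chain rule through the
CV model and the analytic descriptor map, which is why the surrogate's
descriptors are smooth functions of the latent state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, IntegrationError, SamplingError
from .surrogate import BASIN_CENTERS, DescriptorMap, SurrogateSystem, Trajectory

__all__ = [
    "OPESConfig",
    "OPESBias",
    "WallSpec",
    "evaluate_bias",
    "update_bias",
    "wall_energy",
    "run_opes",
    "reweight",
]


@dataclass(frozen=True)
class OPESConfig:
    """User-facing OPES parameters (BARRIER / STRIDE / SIGMA plus knobs)."""

    barrier: float = 20.0          # kcal/mol, largest barrier to overcome
    stride: int = 500              # steps between kernel depositions
    sigma: tuple = (0.1, 0.1)      # initial kernel width per CV dimension
    gamma: float | None = None     # biasfactor; default beta*barrier
    variant: str = "standard"      # "standard" (weighted kernels) | "explore"
    adaptive_sigma: bool = False   # shrink bandwidth with deposition count
    sigma_floor: float = 0.5       # smallest bandwidth, as a fraction of SIGMA
    sigma_mode: str = "fixed"      # "fixed" | "jump": widen kernels to the CV
                                   # displacement since the previous deposit
                                   # (covers regions where the CV stretches)
    sigma_cap: float = 10.0        # largest jump bandwidth, in units of SIGMA
    merge_threshold: float = 1.0   # in bandwidth units

    def __post_init__(self):
        if self.barrier <= 0:
            raise ConfigurationError("BARRIER must be positive")
        if self.stride < 1:
            raise ConfigurationError("STRIDE must be >= 1")
        if self.gamma is not None and self.gamma <= 1:
            raise ConfigurationError("biasfactor gamma must exceed 1")
        if self.variant not in ("standard", "explore"):
            raise ConfigurationError(f"unknown OPES variant {self.variant!r}")
        if self.sigma_mode not in ("fixed", "jump"):
            raise ConfigurationError(f"unknown sigma_mode {self.sigma_mode!r}")


class OPESBias:
    """Kernel-density estimate of the sampled CV distribution + derived bias."""

    def __init__(self, dim: int, beta: float, config: OPESConfig):
        sigma = np.atleast_1d(np.asarray(config.sigma, dtype=float))
        if len(sigma) == 1 and dim > 1:
            sigma = np.full(dim, sigma[0])
        if len(sigma) != dim:
            raise ConfigurationError("SIGMA dimensionality does not match the CV")
        self.dim = dim
        self.beta = beta
        self.config = config
        self.barrier = config.barrier
        self.gamma = config.gamma if config.gamma is not None else beta * config.barrier
        if self.gamma <= 1:
            raise ConfigurationError("derived biasfactor <= 1; increase BARRIER")
        self.sigma0 = sigma
        # "standard": kernels weighted by exp(beta*V) estimate the unbiased
        # distribution (fast transient forgetting); "explore": unit-weight
        # kernels estimate the biased one.  Either way epsilon is chosen so
        # the bias saturates at exactly (1 - 1/gamma)*BARRIER.
        if config.variant == "explore":
            self.prefactor = (self.gamma - 1.0) / self.beta
        else:
            self.prefactor = (1.0 - 1.0 / self.gamma) / self.beta
        cap = (1.0 - 1.0 / self.gamma) * self.barrier
        self.eps = 1.0 / np.expm1(cap / self.prefactor)
        self.centers = np.empty((0, dim))
        self.heights = np.empty(0)
        self.bandwidths = np.empty((0, dim))
        self.n_deposited = 0
        self.zmax = 1.0
        self._zmax_refresh = 25  # full recompute cadence (updates)
        self._last_deposit: np.ndarray | None = None

    # -- density -------------------------------------------------------------
    def _kde(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Normalized density estimate and its gradient at points s (n, d)."""
        s = np.atleast_2d(s)
        if len(self.centers) == 0:
            return np.zeros(len(s)), np.zeros_like(s)
        diff = (s[:, None, :] - self.centers[None, :, :]) / self.bandwidths[None, :, :]
        norm = (2.0 * np.pi) ** (self.dim / 2.0) * np.prod(self.bandwidths, axis=1)
        G = np.exp(-0.5 * np.sum(diff * diff, axis=-1)) * (self.heights / norm)[None, :]
        p = G.sum(axis=1) / self.heights.sum()
        dp = -(G[:, :, None] * diff / self.bandwidths[None, :, :]).sum(axis=1)
        dp /= self.heights.sum()
        return p, dp

    def current_bandwidth(self) -> np.ndarray:
        if not self.config.adaptive_sigma or self.n_deposited == 0:
            return self.sigma0.copy()
        n = self.n_deposited
        shrink = (n * (self.dim + 2.0) / 4.0) ** (-1.0 / (self.dim + 4.0))
        return self.sigma0 * max(shrink, self.config.sigma_floor)

    # -- bias ----------------------------------------------------------------
    def evaluate(self, s) -> tuple[np.ndarray, np.ndarray]:
        """Bias energy (kcal/mol) and gradient at CV point(s) s."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        if s.shape[1] != self.dim:
            raise ConfigurationError("CV dimensionality mismatch")
        if len(self.centers) == 0 or self.gamma == 1.0:
            return np.zeros(len(s)), np.zeros_like(s)
        p, dp = self._kde(s)
        q = p / self.zmax
        V = self.prefactor * (np.log(q + self.eps) - np.log(self.eps))
        dV = self.prefactor * (dp / self.zmax) / (q + self.eps)[:, None]
        return V, dV

    def max_bias(self) -> float:
        """The saturation level (1 - 1/gamma) * BARRIER."""
        return (1.0 - 1.0 / self.gamma) * self.barrier

    def deposit(self, s: np.ndarray) -> None:
        s = np.asarray(s, dtype=float).reshape(self.dim)
        if not np.all(np.isfinite(s)):
            raise SamplingError(f"non-finite CV sample at deposition {self.n_deposited}")
        if self.config.variant == "explore":
            new_h = 1.0
        else:
            V, _ = self.evaluate(s[None, :])
            new_h = float(np.exp(self.beta * min(V[0], self.max_bias())))
        total = self.heights.sum()
        self._dilution = total / (total + new_h) if total > 0 else 1.0
        self.n_deposited += 1
        bw = self.current_bandwidth()
        if self.config.sigma_mode == "jump" and self._last_deposit is not None:
            jump = np.abs(s - self._last_deposit)
            bw = np.clip(jump, bw, self.config.sigma_cap * self.sigma0)
        self._last_deposit = s.copy()
        if len(self.centers):
            scaled = np.abs(self.centers - s) / self.bandwidths
            dist = scaled.max(axis=1)
            k = int(np.argmin(dist))
            if dist[k] < self.config.merge_threshold:
                # moment-matching merge of the nearest kernel with the new one
                h1, h2 = self.heights[k], new_h
                mu1, mu2 = self.centers[k], s
                var1 = self.bandwidths[k] ** 2
                h = h1 + h2
                mu = (h1 * mu1 + h2 * mu2) / h
                var = (h1 * (var1 + mu1**2) + h2 * (bw**2 + mu2**2)) / h - mu**2
                self.heights[k] = h
                self.centers[k] = mu
                self.bandwidths[k] = np.sqrt(np.maximum(var, 1e-12))
                return
        self.centers = np.vstack([self.centers, s[None, :]])
        self.heights = np.append(self.heights, new_h)
        self.bandwidths = np.vstack([self.bandwidths, bw[None, :]])

    def refresh_normalization(self, full: bool | None = None) -> None:
        """Update Z = max of the density estimate over kernel centers.

        A full O(K^2) recompute runs every few updates; in between, Z is
        kept current from the density at the newest kernel (adding mass can
        only dilute the normalized estimate elsewhere).
        """
        if not len(self.centers):
            return
        if full is None:
            full = self.n_deposited % self._zmax_refresh == 0
        if full:
            p, _ = self._kde(self.centers)
            self.zmax = float(p.max())
        else:
            p_new, _ = self._kde(self.centers[-1:])
            self.zmax = max(self.zmax * self._dilution, float(p_new[0]))

    @property
    def kernel_count(self) -> int:
        return len(self.centers)


def evaluate_bias(bias: OPESBias, s) -> tuple[np.ndarray, np.ndarray]:
    """Bias energy and gradient; zero with an empty kernel list or γ = 1."""
    return bias.evaluate(s)


def update_bias(bias: OPESBias, recent_cv_samples) -> OPESBias:
    """Deposit kernels for the given CV samples and refresh the normalization."""
    samples = np.atleast_2d(np.asarray(recent_cv_samples, dtype=float))
    for s in samples:
        bias.deposit(s)
    bias.refresh_normalization()
    return bias


# ---------------------------------------------------------------------------
# repulsive walls

@dataclass(frozen=True)
class WallSpec:
    """Harmonic-by-default wall on one CV component, zero inside the limits."""

    lower: float
    upper: float
    force_constant: float = 40000.0
    exponent: int = 2

    def __post_init__(self):
        if self.force_constant < 0:
            raise ConfigurationError("wall force constant must be >= 0")
        if not self.lower < self.upper:
            raise ConfigurationError("wall requires lower < upper")


def wall_energy(spec: WallSpec, s) -> tuple[np.ndarray, np.ndarray]:
    """Energy k*(excess)^exponent and gradient; continuous at the limits."""
    s = np.asarray(s, dtype=float)
    over = np.maximum(s - spec.upper, 0.0)
    under = np.maximum(spec.lower - s, 0.0)
    k, p = spec.force_constant, spec.exponent
    energy = k * (over**p + under**p)
    grad = k * p * (over ** (p - 1)) - k * p * (under ** (p - 1))
    return energy, grad


# ---------------------------------------------------------------------------
# driving the surrogate

def _cv_and_jacobian(cv_model, d: np.ndarray, J_desc: np.ndarray):
    """CV value(s) and d(cv)/d(latent) rows via the chain rule.

    ``d`` is the descriptor vector at the current latent point, ``J_desc``
    the (n_descriptors, 2) Jacobian of the descriptor map.
    """
    s, J_cv = cv_model.value_and_jacobian(d)
    return np.atleast_1d(s), J_cv @ J_desc


def run_opes(
    system: SurrogateSystem,
    cv_model,
    opes_config: OPESConfig,
    walls: list[WallSpec] | None,
    n_steps: int,
    seed: int = 0,
    descriptor_map: DescriptorMap | None = None,
    x0=None,
    record_stride: int = 10,
    freeze_after: int | None = None,
    bias_init: OPESBias | None = None,
    record_noise: bool = False,
) -> tuple[Trajectory, OPESBias]:
    """OPES-biased Langevin run of the surrogate on a learned CV.

    Returns the recorded trajectory (CV values, instantaneous bias, and
    normalized reweighting weights) together with the final bias object.

    ``freeze_after`` stops bias updates after that many steps: the tail of
    the run then samples a *static* bias, for which umbrella reweighting is
    exact.  ``bias_init`` continues from a previously built bias (e.g. a
    build-up phase run separately).  With ``record_noise`` the *recorded*
    CV values are evaluated on noisy descriptors (as an on-the-fly CV of a
    real trajectory would be), while the bias and its forces always use the
    smooth noise-free map; the recording noise comes from an independent
    stream, so it never perturbs the dynamics.
    """
    if descriptor_map is None:
        raise ConfigurationError("descriptor_map is required to evaluate the CV")
    cfg = system.config
    x = np.array(BASIN_CENTERS["PRE"] if x0 is None else x0, dtype=float)
    rng = np.random.default_rng(seed)
    rng_rec = np.random.default_rng((seed + 7919) % 2**31)  # recording-only noise
    noise_sd = np.sqrt(2.0 * cfg.kT * cfg.timestep / cfg.friction)
    d0 = descriptor_map.means(x)
    s0, _ = _cv_and_jacobian(cv_model, d0, descriptor_map.jacobian(x))
    dim = len(s0)
    if bias_init is not None:
        if bias_init.dim != dim:
            raise ConfigurationError("bias_init dimensionality does not match the CV")
        bias = bias_init
    else:
        bias = OPESBias(dim=dim, beta=system.beta, config=opes_config)
    walls = walls or []
    if walls and len(walls) != dim:
        raise ConfigurationError("need one WallSpec per CV dimension")

    # stability guard: cap the deterministic displacement per step so that a
    # stiff wall or a steep CV region cannot fling the walker off the grid
    max_force = 0.1 * cfg.friction / cfg.timestep

    rec_t, rec_x, rec_s, rec_v, rec_w = [], [], [], [], []
    for step in range(n_steps + 1):
        d = descriptor_map.means(x)
        J = descriptor_map.jacobian(x)
        s, ds_dx = _cv_and_jacobian(cv_model, d, J)
        V, dVds = bias.evaluate(s[None, :])
        V, dVds = float(V[0]), dVds[0]
        Vwall = 0.0
        for k, wspec in enumerate(walls):
            we, wg = wall_energy(wspec, s[k])
            Vwall += float(we)
            dVds[k] += float(wg)
        if step % record_stride == 0:
            rec_t.append(step * cfg.timestep)
            rec_x.append(x.copy())
            if record_noise:
                noisy = d + rng_rec.standard_normal(len(d)) * descriptor_map.noise_sd
                s_rec = np.atleast_1d(np.asarray(cv_model.evaluate(noisy[None, :])).squeeze())
                rec_s.append(np.atleast_1d(s_rec))
            else:
                rec_s.append(s.copy())
            rec_v.append(V)
            rec_w.append(Vwall)
        if step == n_steps:
            break
        grad_latent = system.gradient(x) + dVds @ ds_dx
        gnorm = float(np.hypot(grad_latent[0], grad_latent[1]))
        if gnorm > max_force:
            grad_latent *= max_force / gnorm
        x = x + (-cfg.timestep / cfg.friction) * grad_latent + noise_sd * rng.standard_normal(2)
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 1e8):
            raise IntegrationError(f"biased dynamics diverged at step {step + 1}")
        updating = freeze_after is None or step + 1 <= freeze_after
        if updating and (step + 1) % opes_config.stride == 0:
            d = descriptor_map.means(x)
            s_now, _ = _cv_and_jacobian(cv_model, d, descriptor_map.jacobian(x))
            update_bias(bias, s_now[None, :])

    traj = Trajectory(
        times=np.asarray(rec_t),
        latent=np.asarray(rec_x),
        seed=seed,
        cv=np.asarray(rec_s),
        bias=np.asarray(rec_v),
        wall_bias=np.asarray(rec_w),
    )
    traj.weights = reweight(traj, bias)
    return traj, bias


def reweight(
    trajectory: Trajectory, final_bias: OPESBias | None, mode: str = "final"
) -> np.ndarray:
    """Normalized unbiasing weights w_t ∝ exp(+β V(s_t)); log-sum-exp guarded.

    ``mode='final'`` re-evaluates the final bias on every recorded frame
    (exact when the tail of the run sampled a frozen bias); with
    ``mode='instantaneous'`` the bias each frame actually experienced
    (recorded during the run) is used instead, which suits quasi-static
    adaptive runs.
    """
    if trajectory.cv is None:
        raise ConfigurationError("trajectory carries no CV values")
    n = len(trajectory)
    if final_bias is None or final_bias.kernel_count == 0:
        return np.full(n, 1.0 / n)
    if mode == "instantaneous":
        if trajectory.bias is None:
            raise ConfigurationError("trajectory carries no recorded bias")
        logw = final_bias.beta * np.asarray(trajectory.bias)
    elif mode == "final":
        V, _ = final_bias.evaluate(np.atleast_2d(trajectory.cv))
        logw = final_bias.beta * V
    else:
        raise ConfigurationError(f"unknown reweighting mode {mode!r}")
    logw = logw - logw.max()
    w = np.exp(logw)
    return w / w.sum()
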