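"""Synthetic surrogate for stepwise DNA translocation through a polymerase.

The real process moves double-stranded DNA through the enzyme by one base
pair after nucleotide addition.  The two strands (primer, template) can move
independently, which gives four metastable states on two progress
coordinates x = (x1, x2):

    PRE  = (0, 0)   neither strand moved
    INT1 = (1, 0)   primer strand translocated first
    INT2 = (0, 1)   template strand translocated first
    POST = (1, 1)   both strands translocated

The surrogate is an analytic 2-D potential with minima at exactly those
corners, independently tunable saddle heights on the four edges, and a large
penalty on the concerted diagonal PRE<->POST move, so the only viable
mechanisms are the two stepwise paths.  Overdamped Langevin dynamics on this
potential plays the role of the molecular-dynamics engine, and a bank of
switching-function "contact distances" plays the role of the protein-DNA
descriptor inventory.  Every quantity downstream code tries to recover
(barriers, discriminative descriptors, path preference) is therefore known
by construction.

Energies are in kcal/mol; the default thermal energy kT = 0.616 kcal/mol
corresponds to 310 K.  Latent coordinates and time are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrationError
from .tables import DescriptorTable

__all__ = [
    "SurrogateConfig",
    "SurrogateSystem",
    "Trajectory",
    "DescriptorSpec",
    "DescriptorMap",
    "build_surrogate",
    "potential_energy",
    "simulate",
    "langevin",
    "emit_descriptors",
    "default_descriptor_specs",
    "make_fixture",
    "make_multistate_fixture",
    "BASIN_CENTERS",
    "STATE_NAMES",
]

STATE_NAMES = ("PRE", "INT1", "INT2", "POST")
BASIN_CENTERS = {
    "PRE": np.array([0.0, 0.0]),
    "INT1": np.array([1.0, 0.0]),
    "INT2": np.array([0.0, 1.0]),
    "POST": np.array([1.0, 1.0]),
}

# edge name -> (state pair, scanned axis, fixed value of the other axis,
#               reference basin the saddle height is measured from)
_EDGES = {
    "PRE-INT1": (("PRE", "INT1"), 0, 0.0, "PRE"),
    "INT1-POST": (("INT1", "POST"), 1, 1.0, "PRE"),
    "PRE-INT2": (("PRE", "INT2"), 1, 0.0, "PRE"),
    "INT2-POST": (("INT2", "POST"), 0, 1.0, "INT2"),
}


@dataclass(frozen=True)
class SurrogateConfig:
    """Designed landscape + dynamics parameters (the study conditions)."""

    saddle_heights: dict = field(
        default_factory=lambda: {
            "PRE-INT1": 7.5,
            "INT1-POST": 15.0,
            "PRE-INT2": 17.0,
            "INT2-POST": 10.0,
        }
    )
    basin_depths: dict = field(
        default_factory=lambda: {"PRE": 0.0, "INT1": 3.0, "INT2": 5.0, "POST": 0.0}
    )
    diagonal_penalty: float = 10.0
    kT: float = 0.616
    friction: float = 1.0
    timestep: float = 5.0e-4
    seed: int = 0


# ---------------------------------------------------------------------------
# shape functions

def _g(u):
    """Unit double well: minima 0 at u=0,1; height 1 at u=1/2; quartic walls."""
    return 16.0 * u * u * (1.0 - u) * (1.0 - u)


def _dg(u):
    return 32.0 * u * (1.0 - u) * (1.0 - 2.0 * u)


def _smooth(u):
    """C2 quintic smoothstep clamped to [0,1]; flat (to 2nd order) at 0 and 1."""
    t = np.clip(u, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def _dsmooth(u):
    t = np.clip(u, 0.0, 1.0)
    inside = (u > 0.0) & (u < 1.0)
    return np.where(inside, 30.0 * t * t * (1.0 - t) * (1.0 - t), 0.0)


@dataclass
class SurrogateSystem:
    """Calibrated analytic landscape; see :func:`build_surrogate`."""

    config: SurrogateConfig
    # double-well barrier coefficients along x1 at x2=0 / x2=1, and along
    # x2 at x1=0 / x1=1 (calibrated so edge scans hit the designed saddles)
    a0: float = 0.0
    a1: float = 0.0
    b0: float = 0.0
    b1: float = 0.0

    @property
    def kT(self) -> float:
        return self.config.kT

    @property
    def beta(self) -> float:
        return 1.0 / self.config.kT

    # -- potential ----------------------------------------------------------
    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        x1, x2 = x[..., 0], x[..., 1]
        s1, s2 = _smooth(x1), _smooth(x2)
        d = self.config.basin_depths
        A = self.a0 * (1.0 - s2) + self.a1 * s2
        B = self.b0 * (1.0 - s1) + self.b1 * s1
        tilt = (
            d["INT1"] * s1 * (1.0 - s2)
            + d["INT2"] * (1.0 - s1) * s2
            + d["POST"] * s1 * s2
        )
        return (
            A * _g(x1)
            + B * _g(x2)
            + tilt
            + self.config.diagonal_penalty * _g(x1) * _g(x2)
        )

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        x1, x2 = x[..., 0], x[..., 1]
        s1, s2 = _smooth(x1), _smooth(x2)
        ds1, ds2 = _dsmooth(x1), _dsmooth(x2)
        g1, g2 = _g(x1), _g(x2)
        dg1, dg2 = _dg(x1), _dg(x2)
        d = self.config.basin_depths
        A = self.a0 * (1.0 - s2) + self.a1 * s2
        B = self.b0 * (1.0 - s1) + self.b1 * s1
        dA_dx2 = (self.a1 - self.a0) * ds2
        dB_dx1 = (self.b1 - self.b0) * ds1
        C = self.config.diagonal_penalty
        dV1 = (
            A * dg1
            + dB_dx1 * g2
            + (d["INT1"] * (1.0 - s2) + d["INT2"] * (-s2) + d["POST"] * s2) * ds1
            + C * dg1 * g2
        )
        dV2 = (
            dA_dx2 * g1
            + B * dg2
            + (d["INT1"] * (-s1) + d["INT2"] * (1.0 - s1) + d["POST"] * s1) * ds2
            + C * g1 * dg2
        )
        return np.stack([dV1, dV2], axis=-1)

    # -- designed geometry queries -------------------------------------------
    def edge_scan(self, edge: str, n: int = 2001) -> tuple[np.ndarray, np.ndarray]:
        """1-D potential scan along one state-connecting edge."""
        _, axis, fixed, _ = _EDGES[edge]
        t = np.linspace(0.0, 1.0, n)
        pts = np.empty((n, 2))
        pts[:, axis] = t
        pts[:, 1 - axis] = fixed
        return t, self.energy(pts)

    def designed_barrier(self, edge: str) -> float:
        """Saddle height of an edge above its reference basin (numeric scan)."""
        _, _, _, ref = _EDGES[edge]
        _, prof = self.edge_scan(edge)
        return float(prof.max() - self.energy(BASIN_CENTERS[ref]))


def build_surrogate(config: SurrogateConfig | None = None) -> SurrogateSystem:
    """Calibrate the landscape so each edge saddle hits its designed height.

    The four barrier coefficients act on disjoint edges, so each is fixed by
    an independent 1-D bisection on the corresponding edge scan.
    """
    config = config or SurrogateConfig()
    if config.kT <= 0:
        raise ConfigurationError("kT must be positive")
    if config.timestep <= 0:
        raise ConfigurationError("timestep must be positive")
    if any(h <= 0 for h in config.saddle_heights.values()):
        raise ConfigurationError("saddle heights must be positive")
    missing = set(_EDGES) - set(config.saddle_heights)
    if missing:
        raise ConfigurationError(f"missing saddle heights for edges {sorted(missing)}")

    sys = SurrogateSystem(config=config)

    def calibrate(attr: str, edge: str) -> None:
        _, _, _, ref = _EDGES[edge]
        target = config.saddle_heights[edge]
        ref_energy = lambda: float(sys.energy(BASIN_CENTERS[ref]))

        def height(coef: float) -> float:
            setattr(sys, attr, coef)
            _, prof = sys.edge_scan(edge)
            return float(prof.max()) - ref_energy()

        lo, hi = 1e-3, 10.0
        while height(hi) < target:
            hi *= 2.0
            if hi > 1e6:
                raise ConfigurationError(f"cannot reach saddle height on {edge}")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if height(mid) < target:
                lo = mid
            else:
                hi = mid
        setattr(sys, attr, 0.5 * (lo + hi))

    calibrate("a0", "PRE-INT1")
    calibrate("a1", "INT2-POST")
    calibrate("b0", "PRE-INT2")
    calibrate("b1", "INT1-POST")

    diag = float(sys.energy(np.array([0.5, 0.5])))
    worst = max(sys.designed_barrier(e) for e in _EDGES)
    if diag < worst + 10.0 * config.kT:
        raise ConfigurationError(
            "diagonal saddle does not dominate the edge saddles; "
            "increase diagonal_penalty"
        )
    return sys


def potential_energy(system: SurrogateSystem, x) -> tuple[np.ndarray, np.ndarray]:
    """Energy (kcal/mol) and gradient of the surrogate landscape at x."""
    return system.energy(x), system.gradient(x)


# ---------------------------------------------------------------------------
# dynamics

@dataclass
class Trajectory:
    """Frames of a surrogate run; arrays share the leading frame dimension."""

    times: np.ndarray
    latent: np.ndarray
    seed: int
    descriptors: pd.DataFrame | None = None
    cv: np.ndarray | None = None
    bias: np.ndarray | None = None
    wall_bias: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.times)
        for name in ("latent", "cv", "bias", "wall_bias", "weights"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ConfigurationError(f"{name} has {len(arr)} frames, expected {n}")
        if self.descriptors is not None and len(self.descriptors) != n:
            raise ConfigurationError("descriptor table frame count mismatch")
        if self.weights is not None:
            w = np.asarray(self.weights)
            if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
                raise ConfigurationError("weights must be positive and sum to 1")

    def __len__(self) -> int:
        return len(self.times)


_OVERFLOW = 1.0e8


def langevin(
    force,
    x0: np.ndarray,
    n_steps: int,
    kT: float,
    friction: float,
    dt: float,
    rng: np.random.Generator,
    record_stride: int = 1,
) -> np.ndarray:
    """Euler-Maruyama overdamped Langevin integration of dx = f/friction dt + noise.

    ``force`` maps a position array to the force (-gradient).  Returns the
    recorded positions including the initial one.
    """
    x = np.array(x0, dtype=float)
    noise_sd = np.sqrt(2.0 * kT * dt / friction)
    out = [x.copy()]
    for step in range(1, n_steps + 1):
        f = force(x)
        x = x + (dt / friction) * f + noise_sd * rng.standard_normal(x.shape)
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > _OVERFLOW):
            raise IntegrationError(f"dynamics diverged at step {step}")
        if step % record_stride == 0:
            out.append(x.copy())
    return np.asarray(out)


def simulate(
    system: SurrogateSystem,
    n_steps: int,
    bias=None,
    seed: int = 0,
    x0=None,
    record_stride: int = 1,
) -> Trajectory:
    """Unbiased (or statically biased) overdamped Langevin run on the surrogate.

    ``bias``, when given, is a callable ``x -> (energy, gradient)`` evaluated
    in latent space (e.g. a frozen CV-space bias pulled back through the
    descriptor map); its gradient is added to the potential gradient.
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    cfg = system.config
    x0 = BASIN_CENTERS["PRE"] if x0 is None else np.asarray(x0, dtype=float)
    rng = np.random.default_rng(seed)

    if bias is None:
        force = lambda x: -system.gradient(x)
    else:
        def force(x):
            _, gb = bias(x)
            return -(system.gradient(x) + gb)

    pos = langevin(
        force, x0, n_steps, cfg.kT, cfg.friction, cfg.timestep, rng,
        record_stride=record_stride,
    )
    times = np.arange(len(pos)) * cfg.timestep * record_stride
    return Trajectory(times=times, latent=pos, seed=seed)


# ---------------------------------------------------------------------------
# descriptor emulation

_DESCRIPTOR_CLASSES = (
    "informative_primer",
    "informative_template",
    "redundant_duplicate",
    "low_presence",
    "non_discriminative",
)


@dataclass(frozen=True)
class DescriptorSpec:
    """One synthetic contact distance and how it responds to the latent state.

    Switching descriptors move between two plateau distances (``d_lo`` Å,
    contact formed; ``d_hi`` Å, broken) as their axis crosses 1/2, through a
    logistic of steepness ``steepness``; ``orientation=+1`` means the contact
    is broken by translocation, ``-1`` that it is formed by it.  Flat
    descriptors sit at ``d_lo`` regardless of state.
    """

    descriptor_id: str
    dclass: str
    residue_label: str
    base_pair_label: str
    axis: int | None  # 0 -> primer progress x1, 1 -> template progress x2
    d_lo: float
    d_hi: float
    orientation: int = 1
    steepness: float = 8.0
    noise_sd: float = 0.4

    def __post_init__(self):
        if self.dclass not in _DESCRIPTOR_CLASSES:
            raise ConfigurationError(f"unknown descriptor class {self.dclass!r}")
        if self.dclass.startswith("informative") or self.dclass == "redundant_duplicate":
            if self.axis not in (0, 1):
                raise ConfigurationError(f"{self.descriptor_id}: switching descriptor needs an axis")


class DescriptorMap:
    """Vectorized analytic map latent x -> descriptor means, with Jacobian.

    Built once from a list of specs; used both to emit noisy tables and to
    propagate CV-space bias forces back to the latent coordinates.
    """

    def __init__(self, specs: list[DescriptorSpec]):
        if not specs:
            raise ConfigurationError("specs must be nonempty")
        self.specs = list(specs)
        self.ids = [s.descriptor_id for s in specs]
        n = len(specs)
        self._lo = np.array([s.d_lo for s in specs])
        self._hi = np.array([s.d_hi for s in specs])
        self._k = np.array(
            [s.orientation * s.steepness if s.axis is not None else 0.0 for s in specs]
        )
        self._axis = np.array([s.axis if s.axis is not None else 0 for s in specs])
        self._switching = np.array([s.axis is not None for s in specs])
        self.noise_sd = np.array([s.noise_sd for s in specs])

    def subset(self, ids: list[str]) -> "DescriptorMap":
        lookup = {s.descriptor_id: s for s in self.specs}
        return DescriptorMap([lookup[i] for i in ids])

    def means(self, x) -> np.ndarray:
        """Descriptor means for latent positions x (...,2) -> (...,n)."""
        x = np.asarray(x, dtype=float)
        u = x[..., self._axis]
        z = self._k * (u - 0.5)
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        vals = self._lo + (self._hi - self._lo) * sig
        return np.where(self._switching, vals, self._lo)

    def jacobian(self, x) -> np.ndarray:
        """d(means)/dx at a single latent point: shape (n_descriptors, 2)."""
        x = np.asarray(x, dtype=float)
        u = x[self._axis]
        z = self._k * (u - 0.5)
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        dvals = (self._hi - self._lo) * sig * (1.0 - sig) * self._k
        dvals = np.where(self._switching, dvals, 0.0)
        J = np.zeros((len(self.ids), 2))
        J[np.arange(len(self.ids)), self._axis] = dvals
        return J


def emit_descriptors(
    system: SurrogateSystem,
    latent_frames: np.ndarray,
    specs: list[DescriptorSpec],
    seed: int = 0,
) -> DescriptorTable:
    """Evaluate the descriptor bank on latent frames, with additive noise."""
    dmap = DescriptorMap(specs)
    latent = np.atleast_2d(np.asarray(latent_frames, dtype=float))
    vals = dmap.means(latent)
    rng = np.random.default_rng(seed)
    noisy = vals + rng.standard_normal(vals.shape) * dmap.noise_sd
    df = pd.DataFrame(noisy, columns=dmap.ids)
    return DescriptorTable(df, {s.descriptor_id: s for s in specs})


# ---------------------------------------------------------------------------
# the packaged candidate pool: 350 descriptors, 69 designed survivors

def default_descriptor_specs(seed: int = 0) -> list[DescriptorSpec]:
    """The packaged 350-column candidate pool.

    Composition (descriptor counts by class):

    * 69 informative, exactly one per (residue, base-pair) group
      (35 primer-axis + 34 template-axis),
    * 81 redundant duplicates sharing a group with an informative column but
      with a smaller between-state margin,
    * 100 low-presence columns (contact essentially never formed),
    * 100 non-discriminative columns (always formed, state-independent).

    The three-rule contact filter is designed to retain exactly the 69
    informative columns.
    """
    rng = np.random.default_rng(seed)
    specs: list[DescriptorSpec] = []
    residues = []
    resnum = 100
    for i in range(69):
        resname = "LYS" if i % 2 == 0 else "ARG"
        resnum += int(rng.integers(1, 6))
        residues.append(f"{resname}{resnum}")
    informative_groups = []
    for i, res in enumerate(residues):
        axis = 0 if i < 35 else 1
        bp = f"bp{(i % 8) + 1}"
        informative_groups.append((res, bp))
        specs.append(
            DescriptorSpec(
                descriptor_id=f"d{len(specs):03d}_{res}_{bp}",
                dclass="informative_primer" if axis == 0 else "informative_template",
                residue_label=res,
                base_pair_label=bp,
                axis=axis,
                d_lo=float(rng.uniform(3.8, 4.4)),
                d_hi=float(rng.uniform(8.6, 9.4)),
                orientation=1 if rng.random() < 0.5 else -1,
                noise_sd=0.4,
            )
        )
    # duplicates: same group (hence removable only by rule iii), weaker margin
    for j in range(81):
        res, bp = informative_groups[j % 69]
        parent_axis = 0 if (j % 69) < 35 else 1
        specs.append(
            DescriptorSpec(
                descriptor_id=f"d{len(specs):03d}_{res}_{bp}_alt",
                dclass="redundant_duplicate",
                residue_label=res,
                base_pair_label=bp,
                axis=parent_axis,
                d_lo=float(rng.uniform(4.5, 4.9)),
                d_hi=float(rng.uniform(8.1, 8.5)),
                orientation=1 if rng.random() < 0.5 else -1,
                noise_sd=0.5,
            )
        )
    for j in range(100):
        res = f"LYS{700 + j}"
        bp = f"bp{(j % 8) + 1}"
        specs.append(
            DescriptorSpec(
                descriptor_id=f"d{len(specs):03d}_{res}_{bp}_far",
                dclass="low_presence",
                residue_label=res,
                base_pair_label=bp,
                axis=None,
                d_lo=float(rng.uniform(8.5, 9.5)),
                d_hi=0.0,
                noise_sd=0.4,
            )
        )
    for j in range(100):
        res = f"ARG{900 + j}"
        bp = f"bp{(j % 8) + 1}"
        specs.append(
            DescriptorSpec(
                descriptor_id=f"d{len(specs):03d}_{res}_{bp}_flat",
                dclass="non_discriminative",
                residue_label=res,
                base_pair_label=bp,
                axis=None,
                d_lo=float(rng.uniform(4.0, 5.0)),
                d_hi=0.0,
                noise_sd=0.4,
            )
        )
    assert len(specs) == 350
    return specs


def sample_basin(
    system: SurrogateSystem, state: str, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Boltzmann frames within one basin via the local harmonic approximation.

    Valid because every designed saddle is >= 12 kT above the adjacent
    minima, so within-basin statistics are harmonic to good accuracy.
    """
    center = BASIN_CENTERS[state]
    h = 1e-4
    sd = np.empty(2)
    for ax in range(2):
        e = np.zeros(2)
        e[ax] = h
        curv = (system.energy(center + e) - 2 * system.energy(center) + system.energy(center - e)) / h**2
        sd[ax] = np.sqrt(system.kT / curv)
    return center + rng.standard_normal((n_frames, 2)) * sd


def make_fixture(
    seed: int = 0, n_frames_per_state: int = 20000
) -> tuple[DescriptorTable, DescriptorTable, np.ndarray]:
    """The packaged two-state (PRE, POST) descriptor fixture.

    Returns per-state tables over the full 350-column candidate pool plus the
    concatenated state labels (PRE block first).
    """
    system = build_surrogate(SurrogateConfig(seed=seed))
    specs = default_descriptor_specs(seed=seed)
    rng = np.random.default_rng(seed)
    tables = {}
    for state in ("PRE", "POST"):
        latent = sample_basin(system, state, n_frames_per_state, rng)
        tables[state] = emit_descriptors(
            system, latent, specs, seed=int(rng.integers(2**31))
        )
        tables[state].labels = np.full(n_frames_per_state, state)
    labels = np.concatenate([tables["PRE"].labels, tables["POST"].labels])
    return tables["PRE"], tables["POST"], labels


def _reactive_latents(system, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Frames spread along the two stepwise corridors (transition-path proxy)."""
    path = rng.integers(0, 2, size=n_frames)  # 0: via INT1, 1: via INT2
    t = rng.uniform(0.0, 2.0, size=n_frames)
    main = np.clip(t, 0.0, 1.0)
    second = np.clip(t - 1.0, 0.0, 1.0)
    x = np.where(path == 0, main, second)
    y = np.where(path == 0, second, main)
    pts = np.stack([x, y], axis=1)
    pts += rng.standard_normal(pts.shape) * 0.05
    return pts


def make_multistate_fixture(
    seed: int = 0,
    n_labeled_per_state: int = 5000,
    n_reactive: int = 10000,
) -> tuple[DescriptorTable, DescriptorTable]:
    """Four-state labeled table plus unlabeled 'reactive' table.

    The labeled table mimics per-state unbiased simulations; the unlabeled one
    mimics reactive trajectories that thread both corridors between PRE and
    POST (data the multitask CV uses for its reconstruction task).
    """
    system = build_surrogate(SurrogateConfig(seed=seed))
    specs = default_descriptor_specs(seed=seed)
    rng = np.random.default_rng(seed + 1)
    frames = []
    labels = []
    for state in STATE_NAMES:
        frames.append(sample_basin(system, state, n_labeled_per_state, rng))
        labels.append(np.full(n_labeled_per_state, state))
    labeled = emit_descriptors(
        system, np.concatenate(frames), specs, seed=int(rng.integers(2**31))
    )
    labeled.labels = np.concatenate(labels)
    reactive = emit_descriptors(
        system,
        _reactive_latents(system, n_reactive, rng),
        specs,
        seed=int(rng.integers(2**31)),
    )
    return labeled, reactive
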