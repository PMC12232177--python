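"""OPES bias construction, walls, biased dynamics and reweighting."""

import numpy as np
import pytest

from translocv import surrogate as sg
from translocv.errors import ConfigurationError, SamplingError
from translocv.opes import (
    OPESBias,
    OPESConfig,
    WallSpec,
    evaluate_bias,
    reweight,
    run_opes,
    update_bias,
    wall_energy,
)

BETA = 1.0 / 0.616


def _bias(dim=1, **kw):
    cfg = OPESConfig(sigma=tuple([0.1] * dim), **kw)
    return OPESBias(dim=dim, beta=BETA, config=cfg)


class TestBiasEvaluation:
    def test_empty_kernel_list_gives_zero_bias_and_force(self):
        b = _bias()
        V, dV = evaluate_bias(b, np.array([[0.3]]))
        assert V[0] == 0.0 and dV[0, 0] == 0.0

    def test_unit_biasfactor_means_no_bias(self):
        b = _bias(gamma=1.0 + 1e-12)
        update_bias(b, np.array([[0.0], [0.1], [0.2]]))
        V, _ = evaluate_bias(b, np.linspace(-1, 1, 9)[:, None])
        assert np.allclose(V, 0.0, atol=1e-8)

    def test_single_kernel_matches_the_closed_form(self):
        b = _bias()
        update_bias(b, np.array([[0.5]]))
        sigma = b.bandwidths[0, 0]
        for s in (0.5, 0.5 + sigma):
            # p-hat normalized to the kernel maximum; closed form of
            # V = c*[log(p/zmax + eps) - log eps]
            p = np.exp(-0.5 * ((s - 0.5) / sigma) ** 2)
            expected = b.prefactor * (np.log(p + b.eps) - np.log(b.eps))
            V, _ = evaluate_bias(b, np.array([[s]]))
            assert V[0] == pytest.approx(expected, abs=1e-8)

    def test_bias_gradient_matches_finite_differences(self):
        b = _bias(dim=2)
        rng = np.random.default_rng(0)
        update_bias(b, rng.normal(0, 0.5, size=(40, 2)))
        for s in rng.normal(0, 0.5, size=(5, 2)):
            _, dV = evaluate_bias(b, s[None, :])
            eps = 1e-6
            for k in range(2):
                ds = np.zeros(2)
                ds[k] = eps
                up, _ = evaluate_bias(b, (s + ds)[None, :])
                dn, _ = evaluate_bias(b, (s - ds)[None, :])
                assert dV[0, k] == pytest.approx((up[0] - dn[0]) / (2 * eps), rel=1e-4, abs=1e-8)


class TestBiasUpdates:
    def test_repeated_sampling_of_one_basin_grows_then_saturates_below_cap(self):
        b = _bias()
        rng = np.random.default_rng(1)
        center = np.array([[0.0]])
        history = []
        for _ in range(100):
            update_bias(b, rng.normal(0.0, 0.05, size=(1, 1)))
            history.append(float(evaluate_bias(b, center)[0][0]))
        h = np.asarray(history)
        # epoch-smoothed growth, then saturation just below the cap
        assert h[:10].mean() < h[40:50].mean() <= h[-10:].mean() + 0.1
        # the normalization is anchored at kernel centers, so peaks between
        # kernels may exceed the cap by a sliver
        assert h[-1] <= b.max_bias() + 0.01 * b.barrier

    def test_near_coincident_kernels_are_merged(self):
        b = _bias()
        update_bias(b, np.array([[0.0]]))
        n = b.kernel_count
        update_bias(b, np.array([[1e-4]]))
        assert b.kernel_count == n

    def test_distant_kernels_are_kept_separate(self):
        b = _bias()
        update_bias(b, np.array([[0.0]]))
        update_bias(b, np.array([[1.0]]))
        assert b.kernel_count == 2

    def test_non_finite_sample_is_a_sampling_error(self):
        with pytest.raises(SamplingError):
            update_bias(_bias(), np.array([[np.nan]]))

    def test_bias_cap_holds_on_a_dense_probe_grid(self):
        b = _bias()
        rng = np.random.default_rng(2)
        for _ in range(60):
            update_bias(b, rng.normal(0, 0.3, size=(1, 1)))
        V, _ = evaluate_bias(b, np.linspace(-2, 2, 400)[:, None])
        assert V.max() <= b.max_bias() + 0.1 * b.barrier


class TestWalls:
    def test_interior_is_exactly_zero(self):
        spec = WallSpec(-1.5, 1.5)
        V, g = wall_energy(spec, np.array([-1.0, 0.0, 1.49]))
        assert np.all(V == 0.0) and np.all(g == 0.0)

    def test_quadratic_penalty_value_at_the_printed_force_constant(self):
        spec = WallSpec(-1.5, 1.5, force_constant=40000.0, exponent=2)
        V, _ = wall_energy(spec, 1.6)
        assert V == pytest.approx(400.0, rel=1e-9)

    def test_energy_is_continuous_at_the_limit(self):
        spec = WallSpec(-1.5, 1.5)
        V, _ = wall_energy(spec, 1.5 + 1e-9)
        assert V < 1e-10

    def test_invalid_wall_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            WallSpec(1.0, -1.0)
        with pytest.raises(ConfigurationError):
            WallSpec(-1.0, 1.0, force_constant=-5.0)


@pytest.fixture(scope="module")
def lda_model(labeled_two_state):
    from translocv.deeplda import DeepLDAConfig, train_deep_lda

    return train_deep_lda(
        labeled_two_state,
        DeepLDAConfig(layer_widths=(69, 30, 20, 15, 10, 5), epochs=150, seed=3),
    )


class TestBiasedRuns:
    def test_same_seed_gives_identical_trajectories(self, system, lda_model, descriptor_map):
        cfg = OPESConfig(barrier=20.0, stride=200, sigma=(0.05,))
        walls = [WallSpec(-1.5, 1.5)]
        a, _ = run_opes(system, lda_model, cfg, walls, 3000, seed=4, descriptor_map=descriptor_map)
        b, _ = run_opes(system, lda_model, cfg, walls, 3000, seed=4, descriptor_map=descriptor_map)
        np.testing.assert_array_equal(a.latent, b.latent)
        np.testing.assert_array_equal(a.cv, b.cv)

    def test_null_bias_run_matches_unbiased_statistics(self, system, lda_model, descriptor_map):
        # gamma -> 1 disables the bias entirely; compare PRE-basin radial
        # exploration against a plain unbiased run (two-sample KS, alpha=0.01)
        from scipy.stats import ks_2samp

        cfg = OPESConfig(barrier=20.0, gamma=1.0 + 1e-12, stride=500, sigma=(0.05,))
        t_null, bias = run_opes(
            system, lda_model, cfg, None, 40_000, seed=5, descriptor_map=descriptor_map
        )
        assert np.allclose(t_null.bias, 0.0, atol=1e-8)
        t_free = sg.simulate(system, 40_000, seed=5, record_stride=10)
        r_null = np.linalg.norm(t_null.latent[50:], axis=1)
        r_free = np.linalg.norm(t_free.latent[50:], axis=1)
        assert ks_2samp(r_null[::20], r_free[::20]).pvalue > 0.01

    def test_zero_temperature_unbiased_descent_never_gains_energy(self, system):
        x = np.array([0.35, 0.1])  # off-minimum start
        rng = np.random.default_rng(0)
        pos = sg.langevin(
            lambda p: -system.gradient(p), x, 400, kT=0.0, friction=1.0, dt=5e-4, rng=rng
        )
        energies = system.energy(pos)
        assert np.all(np.diff(energies) <= 1e-10)

    def test_biased_run_crosses_the_low_barrier(self, system, lda_model, descriptor_map):
        from translocv.states import assign_states

        cfg = OPESConfig(barrier=20.0, stride=100, sigma=(0.05,), variant="explore")
        walls = [WallSpec(-1.5, 1.5)]
        traj, _ = run_opes(
            system, lda_model, cfg, walls, 60_000, seed=6, descriptor_map=descriptor_map
        )
        labels = set(assign_states(traj))
        assert labels - {"PRE", "TRANSIT"}, "never left the PRE basin"


class TestReweighting:
    def test_zero_bias_gives_uniform_weights(self, system):
        t = sg.simulate(system, 50, seed=0)
        t.cv = t.latent[:, :1]
        w = reweight(t, None)
        assert np.allclose(w, 1.0 / len(t))

    def test_weights_are_positive_and_normalized(self):
        b = _bias()
        rng = np.random.default_rng(3)
        update_bias(b, rng.normal(0, 0.2, size=(50, 1)))
        t = sg.Trajectory(
            times=np.arange(100.0),
            latent=np.zeros((100, 2)),
            seed=0,
            cv=rng.normal(0, 0.5, size=(100, 1)),
        )
        w = reweight(t, b)
        assert np.all(w > 0) and w.sum() == pytest.approx(1.0)

    def test_static_bias_reweighting_recovers_boltzmann_occupancy(self):
        # 1-D double well + known static bias: the reweighted occupancy of
        # the right-hand well must match the quadrature of the unbiased
        # density within 3 standard errors
        a, tilt, kT = 2.0, 0.8, 0.616
        beta = 1.0 / kT

        def U(x):
            return a * (x**2 - 1) ** 2 + tilt * x

        def Vbias(x):
            return 1.2 * np.exp(-((x + 1.0) ** 2) / 0.8)  # fills the favored well

        def force(x):
            dU = 4 * a * x * (x * x - 1.0) + tilt
            dV = 1.2 * np.exp(-((x + 1.0) ** 2) / 0.8) * (-2 * (x + 1.0) / 0.8)
            return -(dU + dV)

        rng = np.random.default_rng(8)
        pos = sg.langevin(force, np.array([-1.0]), 600_000, kT, 1.0, 0.005, rng)[10_000:]
        x = pos.ravel()
        logw = beta * Vbias(x)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        frac_right = float(w[x > 0].sum())
        xs = np.linspace(-3, 3, 4001)
        dens = np.exp(-beta * U(xs))
        expected = dens[xs > 0].sum() / dens.sum()
        blocks = np.array_split(np.arange(len(x)), 20)
        per_block = [
            w[blk][x[blk] > 0].sum() / max(w[blk].sum(), 1e-300) for blk in blocks
        ]
        se = np.std(per_block) / np.sqrt(20)
        assert abs(frac_right - expected) < 3 * max(se, 2e-3)

    def test_instantaneous_mode_uses_the_recorded_bias(self):
        b = _bias()
        update_bias(b, np.array([[0.0]]))
        t = sg.Trajectory(
            times=np.arange(3.0),
            latent=np.zeros((3, 2)),
            seed=0,
            cv=np.array([[0.0], [0.5], [2.0]]),
            bias=np.array([1.0, 0.5, 0.0]),
        )
        w = reweight(t, b, mode="instantaneous")
        expected = np.exp(BETA * np.array([1.0, 0.5, 0.0]))
        np.testing.assert_allclose(w, expected / expected.sum())


def test_opes_config_serialization_round_trip(tmp_path):
    import yaml
    from dataclasses import asdict

    cfg = OPESConfig(barrier=20.0, stride=500, sigma=(0.1, 0.1))
    path = tmp_path / "opes.yaml"
    path.write_text(yaml.safe_dump({"opes": asdict(cfg)}))
    raw = yaml.safe_load(path.read_text())["opes"]
    raw["sigma"] = tuple(raw["sigma"])
    loaded = OPESConfig(**raw)
    assert loaded == cfg
    assert loaded.barrier == 20.0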