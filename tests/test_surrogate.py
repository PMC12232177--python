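"""The designed landscape, its dynamics, and the descriptor emulator."""

import numpy as np
import pytest
from scipy import optimize

from translocv import surrogate as sg
from translocv.errors import ConfigurationError, IntegrationError

DESIGNED = {"PRE-INT1": 7.5, "INT1-POST": 15.0, "PRE-INT2": 17.0, "INT2-POST": 10.0}


class TestPotential:
    def test_minima_sit_at_the_four_state_centers(self, system):
        for state, center in sg.BASIN_CENTERS.items():
            res = optimize.minimize(lambda x: float(system.energy(x)), center + 0.02)
            assert np.linalg.norm(res.x - center) < 0.05, state

    @pytest.mark.parametrize("edge", list(DESIGNED))
    def test_edge_scans_hit_designed_saddle_heights(self, system, edge):
        assert system.designed_barrier(edge) == pytest.approx(DESIGNED[edge], abs=0.1)

    def test_symmetric_config_gives_swap_symmetric_potential(self):
        # INT2-POST is referenced to the INT2 minimum (depth 2), the other
        # edges to PRE, so 12/12/10-from-INT2 gives equal absolute saddles
        cfg = sg.SurrogateConfig(
            saddle_heights={
                "PRE-INT1": 10.0,
                "PRE-INT2": 10.0,
                "INT1-POST": 12.0,
                "INT2-POST": 10.0,
            },
            basin_depths={"PRE": 0.0, "INT1": 2.0, "INT2": 2.0, "POST": 0.0},
        )
        system = sg.build_surrogate(cfg)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.3, 1.3, size=(50, 2))
        np.testing.assert_allclose(
            system.energy(pts), system.energy(pts[:, ::-1]), rtol=1e-10
        )

    def test_energy_normalized_to_zero_at_pre(self, system):
        assert float(system.energy(sg.BASIN_CENTERS["PRE"])) == 0.0

    def test_gradient_vanishes_at_every_basin_center(self, system):
        for center in sg.BASIN_CENTERS.values():
            assert np.abs(system.gradient(center)).max() < 1e-6

    def test_gradient_matches_central_differences(self, system):
        rng = np.random.default_rng(3)
        h = 1e-5
        for x in rng.uniform(-0.4, 1.4, size=(20, 2)):
            g = system.gradient(x)
            num = [
                (system.energy(x + dx) - system.energy(x - dx)) / (2 * h)
                for dx in (np.array([h, 0.0]), np.array([0.0, h]))
            ]
            assert np.allclose(g, num, rtol=1e-4, atol=1e-6)

    def test_diagonal_crossing_dominates_every_edge_saddle(self, system):
        diag = float(system.energy(np.array([0.5, 0.5])))
        worst = max(system.designed_barrier(e) for e in DESIGNED)
        assert diag >= worst + 10.0 * system.kT

    @pytest.mark.parametrize("bad", [{"kT": -1.0}, {"timestep": 0.0}])
    def test_nonpositive_thermal_or_step_parameters_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            sg.build_surrogate(sg.SurrogateConfig(**bad))


class TestDynamics:
    def test_zero_noise_walker_stays_at_a_minimum(self, system):
        rng = np.random.default_rng(0)
        pos = sg.langevin(
            lambda x: -system.gradient(x),
            sg.BASIN_CENTERS["INT1"],
            200,
            kT=0.0,
            friction=1.0,
            dt=5e-4,
            rng=rng,
        )
        assert np.abs(pos - sg.BASIN_CENTERS["INT1"]).max() < 1e-6

    def test_harmonic_equipartition(self):
        # overdamped sampling of U = x^2/2 must satisfy <x^2> = kT
        kT = 0.616
        rng = np.random.default_rng(42)
        pos = sg.langevin(
            lambda x: -x, np.zeros(1), 1_000_000, kT=kT, friction=1.0, dt=0.01, rng=rng
        )
        var = pos[2000:].var()
        assert var == pytest.approx(kT, rel=0.05)

    def test_same_seed_reproduces_latent_path_bitwise(self, system):
        t1 = sg.simulate(system, 500, seed=9)
        t2 = sg.simulate(system, 500, seed=9)
        np.testing.assert_array_equal(t1.latent, t2.latent)

    def test_double_well_occupancy_follows_boltzmann(self):
        # 1-D tilted double well, low barrier: occupancy ratio vs quadrature
        a, b, kT = 2.0, 0.3, 0.616

        def force(x):
            return -(4 * a * x * (x * x - 1.0) + b)

        rng = np.random.default_rng(5)
        pos = sg.langevin(force, np.array([-1.0]), 400_000, kT, 1.0, 0.005, rng)[5000:]
        frac_right = float((pos > 0).mean())
        xs = np.linspace(-3, 3, 4001)
        boltz = np.exp(-(a * (xs**2 - 1) ** 2 + b * xs) / kT)
        expected = boltz[xs > 0].sum() / boltz.sum()
        # block standard error over 20 contiguous blocks
        blocks = np.array_split((pos > 0).astype(float).ravel(), 20)
        se = np.std([blk.mean() for blk in blocks]) / np.sqrt(20)
        assert abs(frac_right - expected) < 3 * max(se, 1e-3)

    def test_divergent_step_raises_with_frame_index(self, system):
        with pytest.raises(IntegrationError, match="step"):
            sg.langevin(
                lambda x: x * 1e12,  # runaway force
                np.array([1.0]),
                50,
                kT=0.0,
                friction=1.0,
                dt=1.0,
                rng=np.random.default_rng(0),
            )

    def test_weights_must_be_positive_and_normalized(self, system):
        t = sg.simulate(system, 10, seed=0)
        with pytest.raises(ConfigurationError):
            sg.Trajectory(times=t.times, latent=t.latent, seed=0, weights=np.ones(len(t)))


class TestDescriptorEmulation:
    def test_zero_noise_descriptors_are_deterministic_in_latent(self, system, specs):
        quiet = [sg.DescriptorSpec(**{**s.__dict__, "noise_sd": 0.0}) for s in specs[:10]]
        frames = np.array([[0.1, 0.9], [0.1, 0.9]])
        tab = sg.emit_descriptors(system, frames, quiet, seed=0)
        assert np.array_equal(tab.values()[0], tab.values()[1])

    def test_primer_descriptors_separate_pre_from_int1_template_do_not(self, system, specs):
        rng = np.random.default_rng(0)
        at_pre = sg.sample_basin(system, "PRE", 800, rng)
        at_int1 = sg.sample_basin(system, "INT1", 800, rng)
        t_pre = sg.emit_descriptors(system, at_pre, specs, seed=1)
        t_int1 = sg.emit_descriptors(system, at_int1, specs, seed=2)
        for col, spec in t_pre.metadata.items():
            a, b = t_pre.data[col], t_int1.data[col]
            shift = abs(a.mean() - b.mean())
            sd = max(a.std(), b.std())
            if spec.dclass == "informative_primer":
                assert shift > 2 * sd, col
            elif spec.dclass in ("informative_template", "non_discriminative", "low_presence"):
                assert shift < 2 * sd, col

    def test_candidate_pool_composition(self, specs):
        from collections import Counter

        counts = Counter(s.dclass for s in specs)
        assert len(specs) == 350
        assert counts["informative_primer"] + counts["informative_template"] == 69
        assert counts["redundant_duplicate"] == 81
        assert counts["low_presence"] == 100
        assert counts["non_discriminative"] == 100

    def test_exactly_one_informative_descriptor_per_contact_group(self, specs):
        groups = [
            (s.residue_label, s.base_pair_label)
            for s in specs
            if s.dclass.startswith("informative")
        ]
        assert len(groups) == len(set(groups))

    def test_duplicates_share_a_group_with_an_informative_column(self, specs):
        informative = {
            (s.residue_label, s.base_pair_label)
            for s in specs
            if s.dclass.startswith("informative")
        }
        for s in specs:
            if s.dclass == "redundant_duplicate":
                assert (s.residue_label, s.base_pair_label) in informative

    def test_fixture_tables_regenerate_identically_for_a_seed(self):
        a_pre, _, _ = sg.make_fixture(seed=3, n_frames_per_state=50)
        b_pre, _, _ = sg.make_fixture(seed=3, n_frames_per_state=50)
        np.testing.assert_array_equal(a_pre.values(), b_pre.values())
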