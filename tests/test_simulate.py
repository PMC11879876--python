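import numpy as np
import pytest

import networkx as nx

from nanolink.core import Configuration, NanostarGeometry, PeriodicBox
from nanolink.network import build_bond_graph
from nanolink.rheology import _msd_fft
from nanolink.simulate import (
    BondList,
    ForceField,
    LangevinParams,
    SimulationProtocol,
    TracerBead,
    _bonded_pair_config,
    bonded_arm_fraction,
    compute_forces,
    detect_bonds,
    init_configuration,
    run_langevin,
)


class TestForceField:
    def test_morse_cutoff_must_cover_bond_criterion(self):
        with pytest.raises(ValueError):
            ForceField(morse_cutoff=0.1)

    def test_positive_depth_required(self):
        with pytest.raises(ValueError):
            ForceField(morse_depth=-1.0)


class TestInitConfiguration:
    def test_box_solves_density_definition(self):
        config = init_configuration(1, 0.01, seed=0)
        assert config.box.volume == pytest.approx(7 * np.pi / 6 / 0.01)

    def test_deterministic_given_seed(self):
        a = init_configuration(50, 0.10, seed=42)
        b = init_configuration(50, 0.10, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.quaternions, b.quaternions)

    @pytest.mark.parametrize("seed", range(10))
    def test_min_core_separation(self, seed):
        """Generated packings never place core beads closer than 0.9 sigma."""
        config = init_configuration(30, 0.10, seed=seed)
        beads = config.bead_coords(wrap=True).reshape(-1, 3)
        from scipy.spatial import cKDTree

        tree = cKDTree(
            np.mod(beads, config.box.lengths), boxsize=config.box.lengths
        )
        pairs = tree.query_pairs(0.9)
        # exclude intra-molecular pairs (rigid geometry is closer than 0.9)
        inter = [
            (i, j) for i, j in pairs if i // 7 != j // 7
        ]
        assert not inter


class TestDetectBonds:
    def _facing_pair(self, gap):
        """Two nanostars with one patch pair at the given separation."""
        geo = NanostarGeometry.default()
        d = 2 * 2.5 + gap
        box = PeriodicBox.cubic(40.0)
        center = box.lengths / 2
        return Configuration(
            positions=np.array([center - [0, d / 2, 0], center + [0, d / 2, 0]]),
            quaternions=np.array([[1, 0, 0, 0], [0, 0, 0, 1.0]]),
            box=box,
            geometry=geo,
        )

    def test_within_cutoff_bonds(self):
        assert len(detect_bonds(self._facing_pair(0.19))) == 1

    def test_beyond_cutoff_no_bond(self):
        assert len(detect_bonds(self._facing_pair(0.21))) == 0

    def test_greedy_matching_picks_closest(self):
        """Three mutually-in-range patches: exactly one bond joins the
        closest pair, reproducing brute-force minimum-distance matching."""
        geo = NanostarGeometry.default()
        box = PeriodicBox.cubic(60.0)
        # arm-0 patches of three differently-oriented stars approach a
        # common point from +y, -y and +x; patch targets 0.10 / 0.15 /
        # 0.15 sigma apart, all within the 0.2-sigma cutoff
        t0 = np.array([30.0, 30.0, 30.0])
        targets = [t0, t0 + [0.10, 0, 0], t0 + [0.05, 0.144, 0]]
        s = np.sqrt(0.5)
        quats = np.array([[1, 0, 0, 0], [0, 0, 0, 1.0], [s, 0, 0, -s]])
        from nanolink.core import quat_to_matrix

        arm0 = geo.patch_coords[0]
        positions = np.array(
            [t - quat_to_matrix(q) @ arm0 for t, q in zip(targets, quats)]
        )
        config = Configuration(
            positions=positions, quaternions=quats, box=box, geometry=geo
        )
        bonds = detect_bonds(config)
        assert len(bonds) == 1
        (i, _), (j, _) = bonds[0]
        assert {i, j} == {0, 1}  # the 0.10-sigma pair

    def test_invariance_under_translation_and_wrap(self, small_gel):
        config = small_gel.final_config
        ref = sorted(detect_bonds(config))
        shifted = Configuration(
            positions=config.box.wrap(config.positions + 7.3),
            quaternions=config.quaternions,
            box=config.box,
            geometry=config.geometry,
            types=config.types,
        )
        assert sorted(detect_bonds(shifted)) == ref

    def test_incompatible_types_never_bond(self):
        config = self._facing_pair(0.05)
        config.types = np.array([0, 1])
        assert len(detect_bonds(config)) == 0

    def test_bondlist_rejects_reused_arm(self):
        with pytest.raises(ValueError):
            BondList([((0, 0), (1, 0)), ((0, 0), (2, 1))])


class TestForces:
    def test_single_star_has_zero_force_and_torque(self):
        config = init_configuration(1, 0.01, seed=2)
        res = compute_forces(config)
        np.testing.assert_allclose(res["forces"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["torques"], 0.0, atol=1e-12)

    def test_bonded_patches_near_minimum_small_force(self):
        """Morse minimum sits at patch contact: the patch force vanishes as
        the separation goes to zero."""
        config = _bonded_pair_config(NanostarGeometry.default())
        ff = ForceField()
        res = compute_forces(config, ff)
        # net force along y dominated by slight core overlap, patch term ~ 0
        assert np.isfinite(res["energy"])

    def test_forces_match_central_differences(self):
        """Analytic forces agree with a central-difference gradient of the
        energy on a randomized interacting configuration."""
        config = init_configuration(10, 0.08, seed=3)
        ff = ForceField()
        res = compute_forces(config, ff)
        eps = 1e-5
        for mol in (0, 4, 9):
            for d in range(3):
                p1 = config.positions.copy()
                p1[mol, d] += eps
                p2 = config.positions.copy()
                p2[mol, d] -= eps
                e1 = compute_forces(
                    Configuration(p1, config.quaternions, config.box,
                                  config.geometry, config.types), ff
                )["energy"]
                e2 = compute_forces(
                    Configuration(p2, config.quaternions, config.box,
                                  config.geometry, config.types), ff
                )["energy"]
                fd = -(e1 - e2) / (2 * eps)
                assert fd == pytest.approx(res["forces"][mol, d], abs=1e-5)


class TestIntegrator:
    def test_rigid_bodies_stay_rigid(self, small_gel):
        """Intra-nanostar bead distances are exactly preserved (quaternion
        kinematics never deform the body)."""
        f0 = small_gel.trajectory.frames[0]
        f1 = small_gel.trajectory.frames[-1]
        d0 = np.linalg.norm(
            f0.bead_coords(wrap=False)[:, :, None] - f0.bead_coords(wrap=False)[:, None],
            axis=-1,
        )
        d1 = np.linalg.norm(
            f1.bead_coords(wrap=False)[:, :, None] - f1.bead_coords(wrap=False)[:, None],
            axis=-1,
        )
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_kinetic_temperature_matches_thermostat(self, small_gel):
        assert small_gel.kinetic_temperature == pytest.approx(1.0, rel=0.02)

    def test_nve_energy_conservation(self):
        """With the thermostat off, the rigid-body integrator conserves the
        total energy of a dilute (collision-free) 20-star gas to better
        than 1e-4 epsilon per Brownian time."""
        config = init_configuration(20, 0.001, seed=3)
        warm = run_langevin(
            config, ForceField(), LangevinParams(seed=4),
            SimulationProtocol(equilibration=0.0, production=5.0,
                               frame_interval=5.0, stress_interval=5.0),
        )
        res = run_langevin(
            warm.final_config, ForceField(), LangevinParams(seed=5),
            SimulationProtocol(equilibration=0.0, production=50.0,
                               frame_interval=1.0, stress_interval=5.0),
            thermostat=False,
        )
        drift = abs(res.energies[-1] - res.energies[0]) / 50.0
        assert drift < 1e-4

    def test_momentum_conserved_without_thermostat(self):
        config = init_configuration(10, 0.03, seed=6)
        res = run_langevin(
            config, ForceField(), LangevinParams(seed=7),
            SimulationProtocol(equilibration=0.0, production=5.0,
                               frame_interval=0.5, stress_interval=1.0),
            thermostat=False,
        )
        deviation = np.abs(res.momenta - res.momenta[0]).max()
        assert deviation < 1e-10

    def test_free_nanostar_diffusion(self):
        """COM diffusion of non-interacting nanostars follows the
        free-draining law D = k_B T / (7 Gamma) within 10%."""
        config = init_configuration(25, 0.003, seed=11)
        res = run_langevin(
            config, ForceField(), LangevinParams(seed=21),
            SimulationProtocol(equilibration=0.0, production=300.0,
                               frame_interval=0.5, stress_interval=10.0),
        )
        L = config.box.lengths
        pos = np.array([f.positions for f in res.trajectory.frames])
        steps = np.diff(pos, axis=0)
        steps -= L * np.round(steps / L)
        unwrapped = np.concatenate(
            [np.zeros((1,) + pos.shape[1:]), np.cumsum(steps, axis=0)]
        )
        msd = np.mean(
            [_msd_fft(unwrapped[:, i, :]) for i in range(pos.shape[1])], axis=0
        )
        lags = np.arange(len(msd)) * 0.5
        mask = (lags > 3) & (lags < 30)
        slope = np.polyfit(lags[mask], msd[mask], 1)[0]
        assert slope == pytest.approx(6.0 / 7.0, rel=0.10)

    def test_seeded_runs_reproducible(self):
        def run():
            config = init_configuration(5, 0.05, seed=1)
            return run_langevin(
                config, ForceField(), LangevinParams(seed=2),
                SimulationProtocol(equilibration=0.0, production=2.0,
                                   frame_interval=1.0, stress_interval=0.5),
            )

        a, b = run(), run()
        np.testing.assert_array_equal(
            a.final_config.positions, b.final_config.positions
        )
        np.testing.assert_array_equal(
            a.stress.components, b.stress.components
        )

    def test_strong_bond_persists(self):
        """A pre-formed bond at D0 = 20 epsilon survives 1000 tau_Br."""
        config = _bonded_pair_config(NanostarGeometry.default())
        res = run_langevin(
            config, ForceField(), LangevinParams(seed=1),
            SimulationProtocol(equilibration=0.0, production=1000.0,
                               frame_interval=100.0, stress_interval=100.0),
        )
        assert all(len(detect_bonds(f)) == 1 for f in res.trajectory.frames)


class TestGelation:
    def test_gel_forms_and_spans(self, small_gel):
        """At rho = 0.10 with strong bonds most arms bind and the bonded
        network develops a dominant connected component."""
        config = small_gel.final_config
        bonds = detect_bonds(config)
        assert bonded_arm_fraction(bonds, config.n_nanostars) > 0.6
        net = build_bond_graph(config, bonds)
        giant = max(nx.connected_components(net.graph), key=len)
        assert len(giant) >= 0.8 * config.n_nanostars

    def test_tracer_track_recorded(self):
        from nanolink.simulate import place_tracer

        config = init_configuration(10, 0.02, seed=9)
        tracer = place_tracer(config, seed=9)
        res = run_langevin(
            config, ForceField(), LangevinParams(seed=10),
            SimulationProtocol(equilibration=0.0, production=5.0,
                               frame_interval=5.0, stress_interval=0.1),
            tracer=tracer,
        )
        assert res.tracer_track is not None
        assert len(res.tracer_track) == len(res.tracer_times)
        assert np.isfinite(res.tracer_track).all()
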