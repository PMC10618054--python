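"""Integrator contracts: determinism, schedules, and statistical physics."""

import numpy as np
import pytest

from chromocycle.engine import (
    AnnealingSchedule, LangevinSettings, ReplicaError,
    cold_start_configurations, langevin_step, run_replicas, run_trajectory,
)
from chromocycle.polymer_model import (
    BiasField, HomopolymerParams, StagePotential, total_energy_forces,
)


def _free_params(**kw):
    """Non-interacting beads: every potential term switched off."""
    return HomopolymerParams(bond_stiffness=0.0, angle_stiffness=0.0,
                             softcore_strength=0.0, confinement_radius=None,
                             **kw)


def _stage(n, params):
    return StagePotential("test", params, BiasField.zeros(n))


class TestLangevinStep:
    def test_fixed_point_at_zero_temperature(self):
        # relaxed straight chain, T = 0, zero velocities: nothing moves
        x = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        p = HomopolymerParams(confinement_radius=None)
        settings = LangevinSettings(temperature=0.0)
        rng = np.random.default_rng(0)
        x1, v1 = langevin_step(x, np.zeros_like(x), _stage(5, p), settings, rng)
        assert np.array_equal(x1, x)
        assert np.array_equal(v1, np.zeros_like(x))

    def test_non_finite_forces_abort_with_bead_diagnostic(self):
        x = np.column_stack([np.arange(3.0), np.zeros(3), np.zeros(3)])
        x[1] = [np.nan, 0, 0]
        p = _free_params()
        with pytest.raises(ValueError, match="non-finite"):
            langevin_step(x, np.zeros_like(x), _stage(3, p),
                          LangevinSettings(), np.random.default_rng(0))


class TestRunTrajectory:
    def test_frame_arithmetic(self):
        x = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        p = _free_params()
        traj = run_trajectory(x, _stage(4, p), LangevinSettings(seed=1),
                              duration=1.0, record_stride=0.5)
        assert traj.n_frames == 3
        assert np.allclose(traj.frame_times, [0.0, 0.5, 1.0])

    def test_same_seed_bit_identical_different_seed_not(self):
        x = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        p = _free_params()
        stage = _stage(4, p)
        t1 = run_trajectory(x, stage, LangevinSettings(seed=5), duration=0.5,
                            record_stride=0.25)
        t2 = run_trajectory(x, stage, LangevinSettings(seed=5), duration=0.5,
                            record_stride=0.25)
        t3 = run_trajectory(x, stage, LangevinSettings(seed=6), duration=0.5,
                            record_stride=0.25)
        assert np.array_equal(t1.frames, t2.frames)
        assert not np.array_equal(t1.frames, t3.frames)

    def test_annealing_temperatures_along_the_default_ramp(self):
        sched = AnnealingSchedule()  # 4 -> 1 over 250 tau, 1000 tau total
        for t, T in [(0.0, 4.0), (125.0, 2.5), (250.0, 1.0), (600.0, 1.0)]:
            assert sched.temperature_at(t) == pytest.approx(T)
        # and the recorded frame temperatures of an actual run agree
        x = np.column_stack([np.arange(2.0), np.zeros(2), np.zeros(2)])
        p = _free_params()
        traj = run_trajectory(x, _stage(2, p),
                              LangevinSettings(timestep=0.5, seed=2),
                              schedule=sched, record_stride=125.0)
        assert np.allclose(traj.frame_times[:3], [0.0, 125.0, 250.0])
        assert np.allclose(traj.frame_temperatures[:3], [4.0, 2.5, 1.0])
        assert traj.frame_temperatures[-1] == 1.0
        assert traj.sampling_window == (500.0, 1000.0)

    def test_sampling_window_is_second_half(self):
        sched = AnnealingSchedule(4.0, 1.0, 2.0, 8.0)
        x = np.column_stack([np.arange(3.0), np.zeros(3), np.zeros(3)])
        traj = run_trajectory(x, _stage(3, _free_params()),
                              LangevinSettings(timestep=0.01, seed=3),
                              schedule=sched, record_stride=1.0)
        assert traj.sampling_frames().shape[0] == 5  # t = 4..8


class TestEnergyConservation:
    def test_nve_drift_is_small(self, rng):
        # friction 0, T 0: BAOAB reduces to velocity Verlet; with the bonded
        # terms active the total energy must be conserved tightly
        n = 8
        x = np.column_stack([np.arange(float(n)), np.zeros(n), np.zeros(n)])
        x += rng.standard_normal((n, 3)) * 0.02
        p = HomopolymerParams(confinement_radius=None)
        stage = _stage(n, p)
        settings = LangevinSettings(friction=0.0, temperature=0.0)
        v = rng.standard_normal((n, 3)) * 0.05

        def total_energy(x_, v_):
            e, _ = total_energy_forces(x_, stage)
            return e + 0.5 * np.sum(v_**2)

        e0 = total_energy(x, v)
        g = np.random.default_rng(0)
        xi, vi = x, v
        for _ in range(100):
            for _ in range(100):
                xi, vi = langevin_step(xi, vi, stage, settings, g)
        drift = abs(total_energy(xi, vi) - e0)
        assert drift <= 1e-4 * n


class TestStatisticalPhysics:
    def test_free_diffusion_obeys_einstein_relation(self):
        # D = T / gamma = 0.1 sigma^2/tau at defaults; MSD(t) = 6 D t
        n = 32
        x = np.zeros((n, 3))
        x[:, 0] = np.arange(n) * 50.0
        settings = LangevinSettings(temperature=1.0, friction=10.0, seed=42)
        traj = run_trajectory(x, _stage(n, _free_params()), settings,
                              duration=400.0, record_stride=1.0)
        from chromocycle.metrics import msd
        lag = 5.0
        # free beads: COM correction only rescales by (1 - 1/n)
        measured = msd(traj, lag).mean() / (1.0 - 1.0 / n)
        expected = 6.0 * (1.0 / 10.0) * lag
        assert measured == pytest.approx(expected, rel=0.10)

    def test_harmonic_equipartition(self):
        # wall with R_c = 0 is an isotropic harmonic trap: k <x^2>/2 = T/2
        k = 20.0
        p = HomopolymerParams(bond_stiffness=0.0, angle_stiffness=0.0,
                              softcore_strength=0.0, confinement_radius=0.0,
                              wall_stiffness=k)
        n = 2
        x = np.zeros((n, 3))
        settings = LangevinSettings(temperature=1.0, seed=9)
        traj = run_trajectory(x, _stage(n, p), settings, duration=1200.0,
                              record_stride=0.5)
        frames = traj.frames[traj.frame_times > 20.0]  # discard equilibration
        per_axis = 0.5 * k * np.mean(frames**2)
        assert per_axis == pytest.approx(0.5, rel=0.05)


class TestReplicas:
    def test_distinct_seeds_and_bookkeeping(self):
        x = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        stage = _stage(4, _free_params())
        trajs = run_replicas([x], stage, LangevinSettings(seed=0),
                             duration=0.5, record_stride=0.25, n_replicas=2)
        assert len(trajs) == 2
        assert not np.array_equal(trajs[0].frames, trajs[1].frames)
        assert trajs[0].manifest["replica"] == 0

    def test_rerun_reproduces_ensemble(self):
        x = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        stage = _stage(4, _free_params())
        kw = dict(duration=0.5, record_stride=0.25, n_replicas=3)
        a = run_replicas([x], stage, LangevinSettings(seed=7), **kw)
        b = run_replicas([x], stage, LangevinSettings(seed=7), **kw)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.frames, tb.frames)

    def test_failed_replica_reports_seed_and_keeps_partials(self):
        x = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        # an absurd timestep makes the stiff bond explode to non-finite
        stage = _stage(4, HomopolymerParams(confinement_radius=None))
        bad = LangevinSettings(timestep=50.0, seed=1)
        with pytest.raises(ReplicaError, match="replica 0"):
            run_replicas([x + 0.5], stage, bad, duration=50000.0,
                         record_stride=25000.0, n_replicas=2)


class TestColdStart:
    def test_walks_are_bonded_confined_and_separated(self):
        n = 40
        p = HomopolymerParams.for_chain(n)
        rng = np.random.default_rng(3)
        confs = cold_start_configurations(n, p, rng, n_structures=3)
        for x in confs:
            bonds = np.linalg.norm(np.diff(x, axis=0), axis=1)
            assert np.all(np.abs(bonds - 1.0) < 0.3)
            assert np.all(np.linalg.norm(x, axis=1) <= p.confinement_radius * 1.05)
        assert not np.array_equal(confs[0], confs[1])
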