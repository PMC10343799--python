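import math

import numpy as np
import pytest

import pntkit as pk
from pntkit import manipulator as mdm
from pntkit.constants import FORCE_TO_ACC, KB
from conftest import free_gas, two_atom_oscillator


def make_sim(asm, springs=(), **kw):
    kw.setdefault("integrator", mdm.IntegratorParams(fixed_atoms=()))
    return mdm.Simulation(asm, springs=springs, **kw)


class TestScaffold:
    def test_spring_counts(self, chain24):
        springs = mdm.build_scaffold(chain24, pk.HelixParams(n_units=24))
        by_kind = {}
        for s in springs:
            by_kind.setdefault(s.kind, []).append(s)
        assert len(by_kind[mdm.CONTACT]) == 23
        assert len(by_kind[mdm.PITCH]) == 18
        assert len(by_kind[mdm.INNER]) == 24
        assert len(by_kind[mdm.OUTER_EVEN]) + len(by_kind[mdm.OUTER_ODD]) == 48

    def test_pitch_pairs(self, chain24):
        springs = mdm.build_scaffold(chain24, pk.HelixParams(n_units=24))
        pitch = [s for s in springs if s.kind == mdm.PITCH]
        first, last = pitch[0], pitch[-1]
        assert chain24.unit_ids[first.atom_a - 1] == 1
        assert chain24.unit_ids[first.atom_b - 1] == 7
        assert chain24.unit_ids[last.atom_a - 1] == 18
        assert chain24.unit_ids[last.atom_b - 1] == 24

    def test_inner_rest_length_offset(self, small_chain):
        springs = mdm.build_scaffold(
            small_chain, pk.HelixParams(n_units=3), inner_radius=4.0)
        inner = [s for s in springs if s.kind == mdm.INNER]
        assert all(s.rest_length == pytest.approx(2.0) for s in inner)

    def test_outer_rest_length_offset(self, small_chain):
        springs = mdm.build_scaffold(
            small_chain, pk.HelixParams(n_units=3), outer_radius=9.0)
        outer = [s for s in springs
                 if s.kind in (mdm.OUTER_EVEN, mdm.OUTER_ODD)]
        assert all(s.rest_length == pytest.approx(11.0) for s in outer)

    def test_even_odd_split(self, chain24):
        springs = mdm.build_scaffold(chain24, pk.HelixParams(n_units=24))
        even_units = {chain24.unit_ids[s.atom_a - 1]
                      for s in springs if s.kind == mdm.OUTER_EVEN}
        assert even_units == set(range(2, 25, 2))


class TestIntegrator:
    def test_free_particle_uniform_motion(self):
        asm = pk.Assembly(names=["X"], elements=["C"], unit_ids=[1],
                          residue_ids=[1], res_names=["UNK"],
                          coords=[[0.0, 0.0, 0.0]])
        sim = make_sim(asm)
        sim.v[0] = [1.0, -2.0, 0.5]
        sim.step(1000)
        np.testing.assert_allclose(sim.x[0], [1.0, -2.0, 0.5], rtol=1e-12)

    def test_oscillator_energy_conservation(self):
        asm, spring = two_atom_oscillator()
        sim = make_sim(asm, [spring])
        e0 = sim.total_energy()
        assert e0 > 0
        worst = 0.0
        for _ in range(100):
            sim.step(100)
            worst = max(worst, abs(sim.total_energy() - e0) / e0)
        assert worst <= 1e-4

    def test_oscillator_period_closed_form(self):
        asm, spring = two_atom_oscillator(separation=3.0, rest=2.0, stiffness=1.0)
        sim = make_sim(asm, [spring])
        mu = 12.011 / 2.0
        omega = math.sqrt(spring.stiffness * FORCE_TO_ACC / mu)
        for i in range(1, 3001):
            sim.step(1)
            expected = 2.0 + math.cos(omega * i * 0.001)
            assert np.linalg.norm(sim.x[0] - sim.x[1]) == pytest.approx(
                expected, abs=1e-5)

    def test_fixed_atom_never_moves(self, small_chain):
        scaffold = mdm.build_scaffold(small_chain, pk.HelixParams(n_units=3))
        sim = mdm.Simulation(
            small_chain, springs=scaffold,
            forcefield=mdm.ReducedForceField(small_chain),
            thermostat=mdm.ThermostatParams(seed=5),
            integrator=mdm.IntegratorParams(fixed_atoms=(1,)),
        )
        x0 = sim.x[0].copy()
        sim.step(500)
        np.testing.assert_array_equal(sim.x[0], x0)

    def test_blow_up_reported(self):
        asm, spring = two_atom_oscillator(separation=3.0, rest=2.0,
                                          stiffness=1e9)
        sim = make_sim(asm, [spring])
        sim.x[1, 0] = 3.0 + 1e5
        with pytest.raises(mdm.BlowUpError) as err:
            sim.step(10000)
        assert err.value.step > 0


class TestThermostat:
    def test_equipartition(self):
        sim = make_sim(free_gas(n=125),
                       thermostat=mdm.ThermostatParams(lambda_rate=5.0, seed=3))
        sim.step(5000)   # warm-up, 5 ps
        temps = []
        for _ in range(200):  # 20 ps averaging window
            sim.step(100)
            temps.append(sim.kinetic_temperature())
        assert np.mean(temps) == pytest.approx(300.0, rel=0.05)

    def test_collision_probability(self):
        lam, dt = 5.0, 0.001
        sim = make_sim(free_gas(n=400),
                       thermostat=mdm.ThermostatParams(lambda_rate=lam, seed=9))
        sim.step(2000)
        moving = (np.abs(sim.v).sum(axis=1) > 0).mean()
        # nearly every atom should have collided at least once by 2 ps
        assert moving > 1 - math.exp(-lam * 2.0) - 0.05

    def test_zero_lambda_is_nve(self):
        asm, spring = two_atom_oscillator()
        a = make_sim(asm.copy(), [spring],
                     thermostat=mdm.ThermostatParams(lambda_rate=0.0, seed=1))
        b = make_sim(asm.copy(), [spring])
        a.step(200), b.step(200)
        np.testing.assert_array_equal(a.x, b.x)


class TestRunAssembly:
    SCHEDULE = mdm.SpringSchedule(stages=[(0.001, 0.3), (0.1, 0.3)])
    INTEGRATOR = mdm.IntegratorParams(relaxation_ps=0.3, record_interval=50)

    def _run(self, chain, seed=1, mirror_impulses=False):
        scaffold = mdm.build_scaffold(chain, pk.HelixParams(n_units=chain.n_units))
        return mdm.run_assembly(
            chain, scaffold, schedule=self.SCHEDULE,
            thermostat=mdm.ThermostatParams(seed=seed),
            integrator=self.INTEGRATOR, mirror_impulses=mirror_impulses)

    def test_default_schedule_is_80ps(self):
        assert mdm.SpringSchedule().total_ps == pytest.approx(80.0)

    def test_deterministic_from_seed(self, small_chain):
        _, a = self._run(small_chain, seed=7)
        _, b = self._run(small_chain, seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_different_seeds_differ(self, small_chain):
        _, a = self._run(small_chain, seed=7)
        _, b = self._run(small_chain, seed=8)
        assert np.abs(a.coords - b.coords).max() > 1e-6

    def test_parity_equivariance(self, small_chain):
        _, plain = self._run(small_chain, seed=3)
        _, mirrored = self._run(pk.mirror(small_chain), seed=3,
                                mirror_impulses=True)
        expected = plain.coords.copy()
        expected[:, 0] = -expected[:, 0]
        assert np.abs(mirrored.coords - expected).max() <= 1e-6

    def test_trajectory_monotone_times(self, small_chain):
        traj, _ = self._run(small_chain)
        assert all(t2 > t1 for t1, t2 in zip(traj.times, traj.times[1:]))
        assert traj.release_frame is not None

    def test_schedule_validation(self):
        with pytest.raises(Exception):
            mdm.SpringSchedule(stages=[(50.0, 5.0)]).validate()
        with pytest.raises(Exception):
            mdm.SpringSchedule(stages=[(0.1, -1.0)]).validate()


class TestStabilityCheck:
    def test_frozen_trajectory_retained(self, small_chain):
        traj = mdm.Trajectory()
        for t in (0.0, 1.0, 2.0):
            traj.record(t, small_chain.coords, 0.0, 0.0)
        traj.release_frame = 0
        rep = mdm.stability_check(traj, small_chain)
        assert rep.core_rmsd == pytest.approx(0.0)
        assert rep.retained

    def test_melted_structure_not_retained(self, small_chain):
        scaffold = mdm.build_scaffold(small_chain, pk.HelixParams(n_units=3))
        traj, _ = mdm.run_assembly(
            small_chain, scaffold,
            schedule=mdm.SpringSchedule(stages=[(0.001, 0.2)]),
            thermostat=mdm.ThermostatParams(temperature=5000.0, lambda_rate=10.0,
                                            seed=2),
            integrator=mdm.IntegratorParams(relaxation_ps=2.0,
                                            record_interval=100),
            forcefield=None,  # nothing holds the melt together
        )
        rep = mdm.stability_check(traj, small_chain)
        assert not rep.retained

    def test_terminal_units_excluded(self, small_chain):
        traj = mdm.Trajectory()
        traj.record(0.0, small_chain.coords, 0.0, 0.0)
        moved = small_chain.coords.copy()
        moved[small_chain.unit_indices(1)] += 100.0  # only a terminal unit
        traj.record(1.0, moved, 0.0, 0.0)
        traj.release_frame = 0
        rep = mdm.stability_check(traj, small_chain)
        assert rep.retained
        assert rep.per_unit_drift[1] > 50


class TestRunBatch:
    def test_batch_schema_and_determinism(self, small_chain):
        scaffold = mdm.build_scaffold(small_chain, pk.HelixParams(n_units=3))
        kw = dict(
            schedule=mdm.SpringSchedule(stages=[(0.01, 0.2)]),
            integrator=mdm.IntegratorParams(relaxation_ps=0.2),
            chirality_params=pk.CalphaChiralityParams(window=4),
        )
        a = mdm.run_batch(small_chain, scaffold, 2, 100, **kw)
        b = mdm.run_batch(small_chain, scaffold, 2, 100, **kw)
        assert [r.run_id for r in a] == [1, 2]
        assert [r.seed for r in a] == [100, 101]
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.final.coords, rb.final.coords)
            assert ra.report.x_total == rb.report.x_total

    def test_mirrored_batch_flips_signs(self, small_chain):
        scaffold = mdm.build_scaffold(small_chain, pk.HelixParams(n_units=3))
        kw = dict(
            schedule=mdm.SpringSchedule(stages=[(0.01, 0.2)]),
            integrator=mdm.IntegratorParams(relaxation_ps=0.2),
            chirality_params=pk.CalphaChiralityParams(window=4),
        )
        mirrored_chain = pk.mirror(small_chain)
        m_scaffold = mdm.build_scaffold(mirrored_chain, pk.HelixParams(n_units=3))
        a = mdm.run_batch(small_chain, scaffold, 2, 5, **kw)
        b = mdm.run_batch(mirrored_chain, m_scaffold, 2, 5,
                          mirror_impulses=True, **kw)
        for ra, rb in zip(a, b):
            assert rb.report.x_total == pytest.approx(-ra.report.x_total,
                                                      rel=1e-9, abs=1e-12)

    def test_invalid_runs(self, small_chain):
        with pytest.raises(Exception):
            mdm.run_batch(small_chain, [], 0, 0)
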