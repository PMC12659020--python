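"""MD engine: symplectic integration, thermostat statistics, barostat physics."""

import math

import numpy as np
import pytest

from deltamd import RunConfig, generate_water_box, identify_molecules, run
from deltamd.md import MDState, barostat_step, csvr_factor, initialize_state
from deltamd.structures import AtomicConfiguration
from deltamd.units import KB, BAR, fs_to_internal


class ZeroPotential:
    def compute(self, positions, L):
        return 0.0, np.zeros_like(positions), np.zeros((3, 3))


class Harmonic1D:
    """Independent 3D harmonic wells, E = ½ k |r|²."""

    def __init__(self, k):
        self.k = k

    def compute(self, positions, L):
        e = 0.5 * self.k * float(np.sum(positions ** 2))
        return e, -self.k * positions, np.zeros((3, 3))


class TestVelocityVerlet:
    def test_free_particle_moves_uniformly(self):
        cfg = AtomicConfiguration(elements=["O"], positions=[[0.0, 0.0, 0.0]])
        state = initialize_state(cfg, T=298.0, seed=1, with_topology=False)
        state.velocities = np.array([[0.01, -0.02, 0.005]])
        res = run(ZeroPotential(), None,
                  RunConfig(ensemble="nve", dt=0.5, n_steps=100, stride=100),
                  state=state, with_topology=False)
        t_int = fs_to_internal(100 * 0.5)
        expect = np.array([[0.01, -0.02, 0.005]]) * t_int
        assert np.allclose(res.final_state.positions, expect, atol=1e-12)

    def test_harmonic_oscillator_period_and_energy(self):
        # period 2π√(m/k) recovered to 0.1%; energy error bounded, not drifting
        k = 2.0
        m = 15.999
        period_fs = 2 * math.pi * math.sqrt(m / k) * 10.180505710774743
        cfg = AtomicConfiguration(elements=["O"], positions=[[1.0, 0.0, 0.0]])
        state = initialize_state(cfg, T=1.0, seed=0, with_topology=False)
        state.velocities[:] = 0.0
        dt = period_fs / 100.0
        res = run(Harmonic1D(k), None,
                  RunConfig(ensemble="nve", dt=dt, n_steps=100_000, stride=1),
                  state=state, with_topology=False)
        x = np.array([f.positions[0, 0] for f in res.trajectory])
        # measure the period from zero crossings
        signs = np.sign(x)
        crossings = np.flatnonzero(np.diff(signs) < 0)
        n_cycles = len(crossings) - 1
        measured = (crossings[-1] - crossings[0]) * dt / n_cycles
        assert measured == pytest.approx(period_fs, rel=1e-3)
        # total energy oscillates within a bounded band with no secular drift
        E = (res.scalars["E_pot"] + res.scalars["E_kin"]).to_numpy()
        assert (E.max() - E.min()) / E.mean() < 1e-3
        t = res.scalars["t_ps"].to_numpy()
        secular = abs(np.polyfit(t, E, 1)[0]) * (t[-1] - t[0])
        assert secular / E.mean() < 1e-4

    def test_nve_energy_conservation_bulk_water(self, nve_run_126, ll_source):
        frame = ll_source[10]
        s = nve_run_126.scalars
        E = (s["E_pot"] + s["E_kin"]).to_numpy()
        t = s["t_ps"].to_numpy()
        drift = abs(np.polyfit(t, E, 1)[0]) / frame.n_atoms
        assert drift <= 1e-4  # eV/atom/ps

    def test_momentum_conserved(self, theory, ll_source):
        frame = ll_source[4]
        topo = identify_molecules(frame)
        pot = theory.bind("LL", frame.elements, topo)
        res = run(pot, frame, RunConfig(ensemble="nvt", n_steps=2000, stride=200, seed=8))
        st = res.final_state
        p = np.sum(st.masses[:, None] * st.velocities, axis=0)
        assert np.abs(p).max() < 1e-8


class TestCSVR:
    def test_infinite_tau_leaves_velocities_unchanged(self):
        rng = np.random.default_rng(0)
        a2 = csvr_factor(K=1.0, K_target=1.2, n_dof=300, dt_over_tau=1e-12, rng=rng)
        assert a2 == pytest.approx(1.0, abs=1e-5)

    def test_fixed_seed_is_bitwise_reproducible(self, theory, ll_source):
        frame = ll_source[6]
        topo = identify_molecules(frame)
        pot = theory.bind("LL", frame.elements, topo)
        cfg = RunConfig(ensemble="nvt", n_steps=500, stride=100, seed=77)
        r1 = run(pot, frame, cfg)
        r2 = run(pot, frame, cfg)
        assert np.array_equal(r1.final_state.positions, r2.final_state.positions)
        assert np.array_equal(r1.final_state.velocities, r2.final_state.velocities)

    def test_canonical_kinetic_energy_statistics(self, theory):
        # mean K = (3N−3)kBT/2 within 1%, variance within 10% of the χ² law;
        # a short thermostat time constant decorrelates K quickly enough for
        # tight statistics in a 30 ps run
        box = generate_water_box(64, 0.997, seed=22)
        topo = identify_molecules(box)
        pot = theory.bind("LL", box.elements, topo)
        warm = run(pot, box, RunConfig(ensemble="nvt", n_steps=3000, stride=3000, seed=50))
        res = run(pot, None, RunConfig(ensemble="nvt", n_steps=40000, stride=20,
                                       seed=51, tau_T=0.01), state=warm.final_state)
        K = res.scalars["E_kin"].iloc[100:].to_numpy()
        ndof = 3 * box.n_atoms - 3
        K_target = 0.5 * ndof * KB * 298.0
        assert K.mean() == pytest.approx(K_target, rel=0.01)
        var_expected = K_target ** 2 * 2.0 / ndof
        assert K.var(ddof=1) == pytest.approx(var_expected, rel=0.10)

    def test_conserved_quantity_drift(self, theory, ll_source):
        frame = ll_source[8]
        topo = identify_molecules(frame)
        pot = theory.bind("LL", frame.elements, topo)
        res = run(pot, frame, RunConfig(ensemble="nvt", n_steps=20000, stride=200, seed=9))
        c = res.scalars["conserved"].to_numpy()
        t = res.scalars["t_ps"].to_numpy()
        drift = abs(np.polyfit(t, c, 1)[0]) / frame.n_atoms
        assert drift <= 1e-3 * 20  # eV/atom over the whole run, scaled to 50 ps terms
        assert abs(c[-1] - c[0]) / frame.n_atoms <= 1e-2


class TestBarostat:
    def test_fixed_point_at_target_pressure(self, theory, ll_source):
        # with P_inst == P0 and the noise zeroed, the volume must not move
        frame = ll_source[0]
        state = initialize_state(frame, T=298.0, seed=0)
        L0 = state.L

        class NoNoise:
            def standard_normal(self):
                return 0.0
        state.rng = NoNoise()
        V = L0 ** 3
        K = state.kinetic_energy
        # craft a virial so that (2K + trW)/(3V) equals the target exactly
        P0 = 1.0 * BAR
        trW = 3.0 * V * P0 - 2.0 * K
        virial = np.eye(3) * trW / 3.0
        barostat_step(state, 1.0, 298.0, 1.0, 0.5, virial, 4.5e-5)
        assert state.L == pytest.approx(L0, abs=1e-12)

    def test_ideal_gas_density_matches_equation_of_state(self):
        # NPT of a non-interacting gas: ⟨N/V⟩ → P/(kBT) within 2%
        n = 216
        T, P = 298.0, 500.0
        rho_target = P * BAR / (KB * T)       # number density, Å⁻³
        L0 = (n / rho_target) ** (1 / 3)
        rng = np.random.default_rng(2)
        cfg = AtomicConfiguration(elements=["O"] * n,
                                  positions=rng.uniform(0, L0, (n, 3)),
                                  cell=np.eye(3) * L0)
        res = run(ZeroPotential(), cfg,
                  RunConfig(ensemble="npt", T=T, P=P, n_steps=100000, stride=50,
                            seed=4, compressibility=1.0 / P),
                  with_topology=False)
        dens = n / res.scalars["V"].iloc[500:].to_numpy()
        assert dens.mean() == pytest.approx(rho_target, rel=0.02)


class TestDrivers:
    def test_zero_steps_returns_initial_frame(self, theory, ll_source):
        frame = ll_source[0]
        topo = identify_molecules(frame)
        pot = theory.bind("LL", frame.elements, topo)
        res = run(pot, frame, RunConfig(ensemble="nvt", n_steps=0, stride=1, seed=0))
        assert len(res.trajectory) == 1
        assert np.allclose(res.trajectory[0].positions, frame.positions)

    def test_nvt_to_nve_restart_conserves_energy(self, theory, ll_source):
        frame = ll_source[1]
        topo = identify_molecules(frame)
        pot = theory.bind("LL", frame.elements, topo)
        nvt = run(pot, frame, RunConfig(ensemble="nvt", n_steps=1000, stride=500, seed=12))
        nve = run(pot, None, RunConfig(ensemble="nve", n_steps=4000, stride=100),
                  state=nvt.final_state)
        E = (nve.scalars["E_pot"] + nve.scalars["E_kin"]).to_numpy()
        assert (E.max() - E.min()) / frame.n_atoms < 1e-3

    def test_replicas_differ_but_agree_in_temperature(self, theory, ll_source):
        frame = ll_source[2]
        topo = identify_molecules(frame)
        pot = theory.bind("LL", frame.elements, topo)
        r1 = run(pot, frame, RunConfig(ensemble="nvt", n_steps=6000, stride=100, seed=31))
        r2 = run(pot, frame, RunConfig(ensemble="nvt", n_steps=6000, stride=100, seed=32))
        assert not np.allclose(r1.final_state.positions, r2.final_state.positions)
        t1 = r1.scalars["T"].iloc[20:]
        t2 = r2.scalars["T"].iloc[20:]
        pooled = math.sqrt(t1.sem() ** 2 + t2.sem() ** 2)
        assert abs(t1.mean() - t2.mean()) < 6 * pooled
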