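"""Velocity-Verlet dynamics with CSVR thermostat and stochastic cell rescaling.

Ensembles: NVE, NVT (canonical sampling through velocity rescaling,
Bussi–Donadio–Parrinello) and NPT (isotropic stochastic cell rescaling
with molecular-center scaling).  Positions are kept unwrapped; the
minimum-image convention inside the force kernels makes wrapping
unnecessary and leaves mean-squared displacements directly computable.

Internally time is the dynamical unit Å·sqrt(amu/eV); the public
interface is fs/ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import units
from .structures import AtomicConfiguration, MoleculeTopology, Trajectory, identify_molecules
from .units import KB


@dataclass
class RunConfig:
    """MD run settings (public units: fs, ps, K, bar)."""

    dt: float = 0.5              # fs
    T: float = 298.0             # K
    tau_T: float = 0.1           # ps
    P: float = 1.0               # bar
    tau_P: float = 1.0           # ps
    n_steps: int = 1000
    stride: int = 20             # steps between stored frames
    seed: int = 0
    ensemble: str = "nvt"        # nve | nvt | npt
    compressibility: float = 4.5e-5   # bar⁻¹, barostat mobility parameter

    def __post_init__(self):
        if self.dt <= 0 or self.tau_T <= 0 or self.tau_P <= 0:
            raise ValueError("dt, tau_T, tau_P must be positive")
        if self.ensemble not in ("nve", "nvt", "npt"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")


@dataclass
class MDState:
    """Dynamical state: unwrapped positions, velocities (Å per internal time unit)."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    elements: list
    topology: Optional[MoleculeTopology]
    L: float                     # box edge Å, <= 0 for open boundaries
    time_fs: float = 0.0
    conserved_work: float = 0.0  # thermostat/barostat accumulator, eV
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.masses[:, None] * self.velocities ** 2))

    @property
    def n_dof(self) -> int:
        n = len(self.masses)
        return 3 * n - 3 if n > 1 else 3  # center of mass removed

    @property
    def temperature(self) -> float:
        return 2.0 * self.kinetic_energy / (self.n_dof * KB)


@dataclass
class MDResult:
    trajectory: Trajectory
    scalars: pd.DataFrame        # t_ps, T, E_pot, E_kin, conserved, P_bar, V, density
    final_state: MDState


def initialize_state(cfg: AtomicConfiguration, T: float, seed: int,
                     with_topology: bool = True) -> MDState:
    """Maxwell–Boltzmann velocities at `T`, net momentum removed."""
    rng = np.random.default_rng(seed)
    masses = cfg.masses
    v = rng.standard_normal(cfg.positions.shape) * np.sqrt(KB * T / masses)[:, None]
    if len(masses) > 1:
        v -= np.sum(masses[:, None] * v, axis=0) / masses.sum()
    # rescale to hit the target kinetic energy exactly
    ke = 0.5 * float(np.sum(masses[:, None] * v ** 2))
    ndof = 3 * len(masses) - 3 if len(masses) > 1 else 3
    if ke > 0:
        v *= math.sqrt(0.5 * ndof * KB * T / ke)
    topo = identify_molecules(cfg) if with_topology else None
    L = cfg.edge if cfg.periodic else -1.0
    return MDState(positions=cfg.positions.copy(), velocities=v, masses=masses,
                   elements=list(cfg.elements), topology=topo, L=L, rng=rng)


def csvr_factor(K: float, K_target: float, n_dof: int, dt_over_tau: float,
                rng: np.random.Generator) -> float:
    """Squared velocity-rescaling factor of the CSVR thermostat.

    Canonical sampling through velocity rescaling: the new kinetic
    energy is drawn so that the canonical (chi-squared) distribution of
    K is the invariant measure, approaching plain velocity rescaling as
    dt/tau → ∞ and the identity as dt/tau → 0.
    """
    c = math.exp(-dt_over_tau)
    r1 = rng.standard_normal()
    # sum of (n_dof − 1) squared standard normals
    s = 2.0 * rng.standard_gamma(0.5 * (n_dof - 1))
    kbar_frac = K_target / (n_dof * K)
    alpha2 = (c + (1.0 - c) * (s + r1 * r1) * kbar_frac
              + 2.0 * r1 * math.sqrt(c * (1.0 - c) * kbar_frac))
    return alpha2


def csvr_rescale(state: MDState, T: float, tau_T_ps: float, dt_fs: float) -> None:
    """Apply one CSVR kinetic-energy resampling step in place."""
    K = state.kinetic_energy
    if K <= 0.0:
        return
    n_dof = state.n_dof
    K_target = 0.5 * n_dof * KB * T
    dt_over_tau = dt_fs / (tau_T_ps * 1000.0)
    alpha2 = csvr_factor(K, K_target, n_dof, dt_over_tau, state.rng)
    state.velocities *= math.sqrt(alpha2)
    state.conserved_work += K * (1.0 - alpha2)   # energy handed to the bath


def _molecular_centers(state: MDState):
    """(n_mol, 3) centers of mass and per-atom molecule map."""
    topo = state.topology
    if topo is None:
        return state.positions, np.arange(len(state.masses))
    m = state.masses
    nmol = topo.n_molecules
    com = np.zeros((nmol, 3))
    mtot = np.zeros(nmol)
    np.add.at(com, topo.molecule_of, m[:, None] * state.positions)
    np.add.at(mtot, topo.molecule_of, m)
    com /= mtot[:, None]
    return com, topo.molecule_of


def barostat_step(state: MDState, P_bar: float, T: float, tau_P_ps: float,
                  dt_fs: float, virial: np.ndarray, compressibility: float) -> float:
    """One stochastic cell-rescaling update; returns the applied scale factor.

    Propagates ε = ln V by the overdamped Langevin rule
    dε = (κ_T/τ_P)(P_inst − P₀)dt + sqrt(2 kB T κ_T/(V τ_P)) dW and
    rescales the box and the molecular centers isotropically (atoms ride
    rigidly with their molecule's center of mass).
    """
    if state.L <= 0:
        raise ValueError("barostat requires a periodic system")
    V = state.L ** 3
    K = state.kinetic_energy
    P_inst = (2.0 * K + np.trace(virial)) / (3.0 * V)      # eV/Å³
    if not np.isfinite(P_inst):
        raise FloatingPointError("non-finite instantaneous pressure")
    P0 = units.bar_to_internal(P_bar)
    kT = KB * T
    kappa = compressibility / units.BAR                     # Å³/eV
    dt = units.fs_to_internal(dt_fs)
    tau = units.fs_to_internal(tau_P_ps * 1000.0)
    deps = (kappa / tau * (P_inst - P0) * dt
            + math.sqrt(2.0 * kT * kappa / (V * tau) * dt) * state.rng.standard_normal())
    lam = math.exp(deps / 3.0)

    com, mol_of = _molecular_centers(state)
    shift = com * (lam - 1.0)
    state.positions += shift[mol_of]
    state.L *= lam
    return lam


def run(potential, initial: AtomicConfiguration, cfg: RunConfig,
        state: Optional[MDState] = None,
        with_topology: bool = True) -> MDResult:
    """Drive NVE/NVT/NPT dynamics of `potential` from `initial`.

    `potential` is any object with ``compute(positions, L) -> (E, F, W)``
    — the engine is agnostic to whether it evaluates the baseline, the
    target, or the composite surface.  A pre-existing `state` continues
    a run (e.g. NVT equilibration followed by NVE production).
    """
    if state is None:
        state = initialize_state(initial, cfg.T, cfg.seed, with_topology=with_topology)
    dt = units.fs_to_internal(cfg.dt)

    e_pot, forces, virial = potential.compute(state.positions, state.L)
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite forces at start of run")

    frames: list[AtomicConfiguration] = []
    rows: list[dict] = []

    def record():
        cell = np.eye(3) * state.L if state.L > 0 else None
        frames.append(AtomicConfiguration(
            elements=list(state.elements), positions=state.positions.copy(),
            cell=cell, energy=e_pot,
            info={"time_fs": state.time_fs, "ensemble": cfg.ensemble}))
        V = state.L ** 3 if state.L > 0 else float("nan")
        K = state.kinetic_energy
        P_inst = (2.0 * K + np.trace(virial)) / (3.0 * V) if state.L > 0 else float("nan")
        rows.append({
            "t_ps": state.time_fs / 1000.0,
            "T": state.temperature,
            "E_pot": e_pot,
            "E_kin": K,
            "conserved": e_pot + K + state.conserved_work,
            "P_bar": units.internal_to_bar(P_inst) if state.L > 0 else float("nan"),
            "V": V,
            "density": units.density_from_volume(state.masses.sum(), V) if state.L > 0 else float("nan"),
        })

    record()
    inv_m = 1.0 / state.masses[:, None]
    for step in range(cfg.n_steps):
        if cfg.ensemble == "npt":
            barostat_step(state, cfg.P, cfg.T, cfg.tau_P, cfg.dt, virial,
                          cfg.compressibility)
            # forces change little under the tiny volume move; the next
            # evaluation refreshes them at the new geometry
        # velocity Verlet: exactly one new force evaluation per step
        state.velocities += 0.5 * dt * forces * inv_m
        state.positions += dt * state.velocities
        e_pot, forces, virial = potential.compute(state.positions, state.L)
        state.velocities += 0.5 * dt * forces * inv_m
        if cfg.ensemble in ("nvt", "npt"):
            csvr_rescale(state, cfg.T, cfg.tau_T, cfg.dt)
        state.time_fs += cfg.dt
        if not np.isfinite(e_pot):
            raise FloatingPointError(f"non-finite energy at step {step}")
        if (step + 1) % cfg.stride == 0:
            record()

    scalars = pd.DataFrame(rows)
    traj = Trajectory(frames, timestep_fs=cfg.dt * cfg.stride, ensemble=cfg.ensemble)
    return MDResult(trajectory=traj, scalars=scalars, final_state=state)
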