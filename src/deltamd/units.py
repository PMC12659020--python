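"""Unit system and physical constants.

Internal units are Å (length), eV (energy), amu (mass) and the derived
dynamical time unit t0 = Å·sqrt(amu/eV) ≈ 10.1805 fs.  All public
interfaces speak fs, ps, K, bar, g/cm³ and Å²/ps; conversion happens at
the boundary.
"""

from __future__ import annotations

import math

#: Boltzmann constant, eV/K
KB = 8.617333262e-5

#: Coulomb constant k_e = 1/(4 π ε0), eV·Å/e²
COULOMB = 14.399645478425668

#: internal time unit in fs: 1 Å · sqrt(1 amu / 1 eV)
TIME_INTERNAL_FS = 1.0e-10 * math.sqrt(1.66053906660e-27 / 1.602176634e-19) / 1.0e-15

#: 1 bar in eV/Å³
BAR = 1.0e5 / 1.602176634e-19 * 1.0e-30

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: molar mass of water, g/mol
WATER_MOLAR_MASS = 18.015

#: atomic masses, amu
MASSES = {"O": 15.999, "H": 1.008}


def fs_to_internal(t_fs: float) -> float:
    """Convert a time in fs to internal dynamical units."""
    return t_fs / TIME_INTERNAL_FS


def internal_to_fs(t_int: float) -> float:
    """Convert a time in internal dynamical units to fs."""
    return t_int * TIME_INTERNAL_FS


def bar_to_internal(p_bar: float) -> float:
    """Convert a pressure in bar to eV/Å³."""
    return p_bar * BAR


def internal_to_bar(p_int: float) -> float:
    """Convert a pressure in eV/Å³ to bar."""
    return p_int / BAR


def box_edge_from_density(n_molecules: int, rho: float, molar_mass: float = WATER_MOLAR_MASS) -> float:
    """Cubic box edge (Å) holding `n_molecules` at mass density `rho` (g/cm³).

    edge = (n·M / (ρ·N_A))^(1/3), converted from cm to Å.
    """
    if n_molecules < 1 or rho <= 0.0 or molar_mass <= 0.0:
        raise ValueError("n_molecules, rho and molar_mass must be positive")
    volume_cm3 = n_molecules * molar_mass / (rho * N_AVOGADRO)
    return volume_cm3 ** (1.0 / 3.0) * 1.0e8


def density_from_box(n_molecules: int, edge: float, molar_mass: float = WATER_MOLAR_MASS) -> float:
    """Mass density (g/cm³) of `n_molecules` in a cubic box of edge Å."""
    if n_molecules < 1 or edge <= 0.0 or molar_mass <= 0.0:
        raise ValueError("n_molecules, edge and molar_mass must be positive")
    volume_cm3 = (edge * 1.0e-8) ** 3
    return n_molecules * molar_mass / (N_AVOGADRO * volume_cm3)


def density_from_volume(total_mass_amu: float, volume_A3: float) -> float:
    """Mass density (g/cm³) from total mass in amu and volume in Å³."""
    return total_mass_amu * 1.66053906660e-24 / (volume_A3 * 1.0e-24)
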