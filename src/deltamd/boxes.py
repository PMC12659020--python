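"""Initial-structure generation: periodic water boxes on a jittered lattice."""

from __future__ import annotations

import math

import numpy as np

from .structures import AtomicConfiguration
from .units import box_edge_from_density


def _water_monomer(r0: float = 0.9572, theta0_deg: float = 104.52) -> np.ndarray:
    """Ideal monomer geometry (O at origin), positions (3,3): O, H, H."""
    th = math.radians(theta0_deg)
    h1 = np.array([r0, 0.0, 0.0])
    h2 = np.array([r0 * math.cos(th), r0 * math.sin(th), 0.0])
    return np.vstack([np.zeros(3), h1, h2])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def generate_water_box(n_molecules: int, rho: float, seed: int,
                       jitter: float = 0.15) -> AtomicConfiguration:
    """Cubic box of `n_molecules` waters at density `rho` (g/cm³).

    Molecules are placed on a simple-cubic lattice with a small random
    O-site jitter and independent random orientations; atom order is
    O, H, H per molecule.  The result is a valid (if high-energy)
    starting point for equilibration, not an equilibrated liquid.
    """
    edge = box_edge_from_density(n_molecules, rho)
    rng = np.random.default_rng(seed)
    n_side = math.ceil(n_molecules ** (1.0 / 3.0))
    spacing = edge / n_side
    mono = _water_monomer()

    sites = []
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                sites.append((ix, iy, iz))
    sites = np.array(sites[:n_molecules], dtype=float)

    elements: list[str] = []
    positions = np.empty((3 * n_molecules, 3))
    for m in range(n_molecules):
        center = (sites[m] + 0.5) * spacing
        center += rng.uniform(-jitter, jitter, size=3) * spacing
        rot = _random_rotation(rng)
        atoms = mono @ rot.T + center
        positions[3 * m:3 * m + 3] = atoms
        elements += ["O", "H", "H"]

    cell = np.eye(3) * edge
    return AtomicConfiguration(elements=elements, positions=positions, cell=cell,
                               info={"density": rho, "seed": seed})
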