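"""Structural and transport observables from trajectories.

Radial distribution functions (shell-count histogram, per-frame density
normalization so NPT trajectories are handled correctly), first-peak
location by quadratic interpolation, self-diffusion from mean-squared
displacements with the Yeh–Hummer hydrodynamic finite-size correction,
block-averaged densities, and density-isobar assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numba
import numpy as np
import pandas as pd

from .structures import Trajectory, identify_molecules
from .units import KB

#: Yeh–Hummer lattice constant for cubic periodic boxes
XI_CUBIC = 2.837297


class NoPeakError(ValueError):
    """Raised when a g(r) curve has no interior maximum above 1."""


@dataclass
class RDFResult:
    pair: str                 # "O-O", "O-H", "H-H"
    r: np.ndarray             # bin centers, Å
    g: np.ndarray
    dr: float
    n_frames: int


@dataclass
class DiffusionResult:
    D_pbc: float              # Å²/ps
    D_corrected: float        # Å²/ps
    fit_window_ps: tuple
    slope_stderr: float       # Å²/ps on D
    L: float
    eta_mPas: float
    msd: Optional[pd.DataFrame] = None


@dataclass
class DensityResult:
    mean: float               # g/cm³
    stderr: float
    n_blocks: int
    equil_fraction: float


@numba.njit(cache=True, fastmath=True)
def _rdf_accumulate(posA, posB, L, dr, nbins, same, hist):
    nA = posA.shape[0]
    nB = posB.shape[0]
    rmax2 = (dr * nbins) ** 2
    for i in range(nA):
        j0 = i + 1 if same else 0
        for j in range(j0, nB):
            dx = posA[i, 0] - posB[j, 0]
            dy = posA[i, 1] - posB[j, 1]
            dz = posA[i, 2] - posB[j, 2]
            dx -= L * math.floor(dx / L + 0.5)
            dy -= L * math.floor(dy / L + 0.5)
            dz -= L * math.floor(dz / L + 0.5)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rmax2:
                k = int(math.sqrt(r2) / dr)
                if k < nbins:
                    hist[k] += 1.0


def rdf(traj: Trajectory, pair: str = "O-O", dr: float = 0.05,
        r_max: Optional[float] = None) -> RDFResult:
    """Radial distribution function of an element pair over a trajectory.

    Normalized frame-by-frame against the ideal-gas expectation at that
    frame's density, so constant-pressure trajectories (fluctuating
    cells) are averaged correctly.  `r_max` defaults to, and must not
    exceed, half the smallest box edge.
    """
    elA, elB = pair.split("-")
    L_min = min(f.edge for f in traj)
    if r_max is None:
        r_max = L_min / 2.0
    if r_max > L_min / 2.0 + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the box edge {L_min / 2.0:.3f}")
    nbins = int(r_max / dr)
    hist = np.zeros(nbins)
    norm = np.zeros(nbins)
    edges = np.arange(nbins + 1) * dr
    shell = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    same = elA == elB
    for frame in traj:
        els = np.asarray(frame.elements)
        pa = np.ascontiguousarray(frame.positions[els == elA])
        pb = np.ascontiguousarray(frame.positions[els == elB])
        L = frame.edge
        _rdf_accumulate(pa, pb, L, dr, nbins, same, hist)
        V = L ** 3
        n_pairs = len(pa) * (len(pa) - 1) / 2.0 if same else len(pa) * len(pb)
        norm += n_pairs * shell / V
    g = np.divide(hist, norm, out=np.zeros_like(hist), where=norm > 0)
    r = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(pair=pair, r=r, g=g, dr=dr, n_frames=len(traj))


def first_peak(result: RDFResult) -> tuple[float, float]:
    """Height and position of the first maximum of g(r) above 1.

    Quadratic interpolation through the maximum bin and its neighbors;
    if the maximum sits exactly at a bin center the bin value is
    returned unchanged.
    """
    g = result.g
    r = result.r
    # first interior local maximum above 1
    idx = None
    for k in range(1, len(g) - 1):
        if g[k] > 1.0 and g[k] >= g[k - 1] and g[k] >= g[k + 1]:
            idx = k
            break
    if idx is None:
        raise NoPeakError(f"no first peak above 1 found for pair {result.pair}")
    y0, y1, y2 = g[idx - 1], g[idx], g[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-14:
        return float(y1), float(r[idx])
    delta = 0.5 * (y0 - y2) / denom
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(height), float(r[idx] + delta * result.dr)


def yeh_hummer_correction(T: float, L: float, eta_mPas: float) -> float:
    """Hydrodynamic finite-size correction ξ·kB·T/(6πηL) in Å²/ps."""
    kT_J = KB * T * 1.602176634e-19
    eta_SI = eta_mPas * 1.0e-3
    L_m = L * 1.0e-10
    corr_SI = XI_CUBIC * kT_J / (6.0 * math.pi * eta_SI * L_m)   # m²/s
    return corr_SI * 1.0e8                                        # Å²/ps


def msd_oxygen(traj: Trajectory, max_lag_ps: float) -> pd.DataFrame:
    """Mean-squared displacement of O atoms over multiple time origins.

    Positions must be unwrapped (the MD engine never wraps).  Origins
    are spaced half the maximum lag apart, capping origin overlap at 50%.
    """
    dt_frame = traj.timestep_fs / 1000.0  # ps
    max_lag = int(round(max_lag_ps / dt_frame))
    if max_lag >= len(traj):
        raise ValueError(f"lag window {max_lag_ps} ps exceeds trajectory length")
    els = np.asarray(traj[0].elements)
    o_mask = els == "O"
    pos = np.array([f.positions[o_mask] for f in traj])   # (n_frames, n_O, 3)
    origin_stride = max(1, max_lag // 2)
    origins = range(0, len(traj) - max_lag, origin_stride)
    lags = np.arange(1, max_lag + 1)
    acc = np.zeros(max_lag)
    n_org = 0
    for t0 in origins:
        disp = pos[t0 + 1:t0 + max_lag + 1] - pos[t0]
        acc += np.mean(np.sum(disp ** 2, axis=2), axis=1)
        n_org += 1
    if n_org == 0:
        raise ValueError("trajectory too short for the requested window")
    return pd.DataFrame({"t_ps": lags * dt_frame, "msd": acc / n_org})


def diffusion(traj: Trajectory, fit_window_ps: tuple = (2.0, 10.0),
              eta_mPas: float = 0.896, T: float = 298.0) -> DiffusionResult:
    """Self-diffusion coefficient of water O atoms with finite-size correction.

    D_pbc = slope/6 from a least-squares fit of the multi-origin MSD
    over `fit_window_ps`; the Yeh–Hummer term ξ·kB·T/(6πηL) with the
    user-supplied shear viscosity gives D_corrected.
    """
    t_lo, t_hi = fit_window_ps
    msd = msd_oxygen(traj, t_hi)
    m = (msd["t_ps"] >= t_lo) & (msd["t_ps"] <= t_hi)
    if m.sum() < 3:
        raise ValueError("fewer than 3 MSD points in the fit window")
    t = msd.loc[m, "t_ps"].to_numpy()
    y = msd.loc[m, "msd"].to_numpy()
    A = np.column_stack([t, np.ones_like(t)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = coef[0]
    dof = len(t) - 2
    sigma2 = float(res[0]) / dof if len(res) and dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(A.T @ A)
    slope_err = math.sqrt(max(cov[0, 0], 0.0))
    L = traj[0].edge
    corr = yeh_hummer_correction(T, L, eta_mPas)
    return DiffusionResult(D_pbc=slope / 6.0, D_corrected=slope / 6.0 + corr,
                           fit_window_ps=(t_lo, t_hi), slope_stderr=slope_err / 6.0,
                           L=L, eta_mPas=eta_mPas,
                           msd=msd)


def density(traj_or_series, n_blocks: int = 10,
            equil_fraction: float = 0.2) -> DensityResult:
    """Block-averaged density of an NPT trajectory (or density series).

    Discards the first `equil_fraction` of the data, then estimates the
    standard error from `n_blocks` non-overlapping block means.
    """
    if isinstance(traj_or_series, Trajectory):
        from .units import density_from_volume
        if traj_or_series.ensemble and traj_or_series.ensemble != "npt":
            raise ValueError("density requires an NPT trajectory with cell fluctuations")
        vals = np.array([density_from_volume(f.masses.sum(), f.edge ** 3)
                         for f in traj_or_series])
    else:
        vals = np.asarray(traj_or_series, dtype=float)
    n0 = int(len(vals) * equil_fraction)
    vals = vals[n0:]
    if len(vals) < n_blocks:
        raise ValueError(f"only {len(vals)} post-equilibration samples for {n_blocks} blocks")
    usable = (len(vals) // n_blocks) * n_blocks
    blocks = vals[:usable].reshape(n_blocks, -1).mean(axis=1)
    stderr = float(blocks.std(ddof=1) / math.sqrt(n_blocks))
    return DensityResult(mean=float(vals.mean()), stderr=stderr,
                         n_blocks=n_blocks, equil_fraction=equil_fraction)


def isobar_table(temperatures: Sequence[float], densities: Sequence[float],
                 errors: Sequence[float]) -> pd.DataFrame:
    """Assemble a density-isobar table and locate an interior maximum.

    The maximum, when one exists away from the endpoints, is refined by
    a quadratic fit through the top three points; monotone data get a
    no-maximum flag.
    """
    if len(temperatures) < 2:
        raise ValueError("an isobar needs at least 2 temperatures")
    df = pd.DataFrame({"T": temperatures, "rho": densities, "err": errors})
    df = df.sort_values("T").reset_index(drop=True)
    k = int(df["rho"].idxmax())
    if k == 0 or k == len(df) - 1:
        df.attrs["T_max"] = None
        return df
    Ts = df["T"].to_numpy()[k - 1:k + 2]
    rs = df["rho"].to_numpy()[k - 1:k + 2]
    a, b, _ = np.polyfit(Ts, rs, 2)
    df.attrs["T_max"] = float(-b / (2.0 * a)) if a < 0 else float(Ts[1])
    return df


def replica_mean_err(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error over independent replica estimates."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return float(v.mean()), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(len(v)))
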