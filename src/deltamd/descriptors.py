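"""Rotation-invariant atom-centered descriptors with a 4 Å cutoff.

Per-atom features are sums of Gaussian radial basis functions (one set
per neighbor element) and angular terms (1 + λ cos θ)^ζ ·
exp(−η(r_ij² + r_ik²)) (one set per unordered neighbor-element pair),
each damped by a cosine cutoff.  The same machinery runs on open
clusters and periodic boxes (minimum image).

A companion kernel contracts the features with per-element weight
vectors and accumulates energy, analytic forces and the virial in one
pass — the Δ-model's production evaluator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba
import numpy as np


@numba.njit(cache=True, inline="always")
def _mic(d, L):
    if L > 0.0:
        return d - L * math.floor(d / L + 0.5)
    return d


@dataclass
class DescriptorSpec:
    """Feature definition: radial grid, angular set, 4 Å cutoff."""

    cutoff: float = 4.0
    radial_centers: np.ndarray = field(
        default_factory=lambda: np.arange(0.5, 4.0 + 1e-9, 0.25))
    radial_width: float = 0.25
    eta_angular: float = 0.15                # 1/Å², matches the radial envelope scale
    # (λ, ζ) combinations; λ = ±1, ζ ∈ {1, 2} span quadratics in cos θ
    angular_set: tuple = ((1.0, 1), (-1.0, 1), (1.0, 2), (-1.0, 2))

    def __post_init__(self):
        self.radial_centers = np.asarray(self.radial_centers, dtype=float)
        if np.any(self.radial_centers >= self.cutoff + 1e-9):
            raise ValueError("radial centers must lie below the cutoff")

    @property
    def n_radial(self) -> int:
        return len(self.radial_centers)

    @property
    def n_angular(self) -> int:
        return len(self.angular_set)

    @property
    def n_per_element(self) -> int:
        # 2 neighbor-element radial channels + 3 neighbor-pair angular channels
        return 2 * self.n_radial + 3 * self.n_angular

    @property
    def n_features(self) -> int:
        # two center elements: O block then H block
        return 2 * self.n_per_element

    def arrays(self):
        lam = np.array([a[0] for a in self.angular_set])
        zet = np.array([a[1] for a in self.angular_set], dtype=np.int64)
        return self.radial_centers, self.radial_width, self.eta_angular, lam, zet


@numba.njit(cache=True, fastmath=True)
def _featurize(pos, zcode, L, rc, mu, width, eta, lam_arr, zeta_arr):
    n = pos.shape[0]
    nR = mu.shape[0]
    nA = lam_arr.shape[0]
    d1 = 2 * nR + 3 * nA
    feats = np.zeros((n, d1))
    rc2 = rc * rc
    nb_idx = np.empty(n, dtype=np.int64)
    nb_d = np.empty((n, 3))
    nb_r = np.empty(n)
    for i in range(n):
        nnb = 0
        for j in range(n):
            if j == i:
                continue
            dx = _mic(pos[j, 0] - pos[i, 0], L)
            dy = _mic(pos[j, 1] - pos[i, 1], L)
            dz = _mic(pos[j, 2] - pos[i, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                nb_idx[nnb] = j
                nb_d[nnb, 0] = dx
                nb_d[nnb, 1] = dy
                nb_d[nnb, 2] = dz
                nb_r[nnb] = math.sqrt(r2)
                nnb += 1
        # radial (Gaussians beyond 5σ of a center are dropped in both the
        # featurizer and the contraction kernel, so train and deploy agree)
        for a in range(nnb):
            r = nb_r[a]
            fc = 0.5 * (1.0 + math.cos(math.pi * r / rc))
            off = zcode[nb_idx[a]] * nR
            for k in range(nR):
                dmu = r - mu[k]
                if dmu * dmu > 25.0 * width * width:
                    continue
                g = math.exp(-dmu * dmu / (2.0 * width * width))
                feats[i, off + k] += g * fc
        # angular
        for a in range(nnb):
            ra = nb_r[a]
            ga = math.exp(-eta * ra * ra) * 0.5 * (1.0 + math.cos(math.pi * ra / rc))
            za = zcode[nb_idx[a]]
            for b in range(a + 1, nnb):
                rb = nb_r[b]
                gb = math.exp(-eta * rb * rb) * 0.5 * (1.0 + math.cos(math.pi * rb / rc))
                zb = zcode[nb_idx[b]]
                ptype = za + zb  # (O,O)->0, (O,H)->1, (H,H)->2
                c = (nb_d[a, 0] * nb_d[b, 0] + nb_d[a, 1] * nb_d[b, 1]
                     + nb_d[a, 2] * nb_d[b, 2]) / (ra * rb)
                env = ga * gb
                for t in range(nA):
                    base = (1.0 + lam_arr[t] * c) ** zeta_arr[t]
                    feats[i, 2 * nR + ptype * nA + t] += base * env
    return feats


@numba.njit(cache=True, fastmath=True)
def _contract(pos, zcode, L, rc, mu, width, eta, wradO, wradH, polyO, polyH):
    """Energy/forces/virial of E = Σ_i w_{Z_i}·f_i with analytic gradients.

    The weighted angular basis Σ_t w_t (1+λ_t cosθ)^{ζ_t} is pre-expanded
    into polynomial coefficients in cosθ (polyO/polyH: 3 pair types ×
    degree+1), evaluated by Horner's rule per triplet.
    """
    n = pos.shape[0]
    nR = mu.shape[0]
    ndeg = polyO.shape[1]
    F = np.zeros((n, 3))
    W = np.zeros((3, 3))
    energy = 0.0
    rc2 = rc * rc
    nb_idx = np.empty(n, dtype=np.int64)
    nb_d = np.empty((n, 3))
    nb_r = np.empty(n)
    nb_inv = np.empty(n)
    nb_e = np.empty((n, 3))
    nb_g = np.empty(n)
    nb_dg = np.empty(n)
    inv2w2 = 1.0 / (2.0 * width * width)
    w5 = 25.0 * width * width
    for i in range(n):
        nnb = 0
        for j in range(n):
            if j == i:
                continue
            dx = _mic(pos[j, 0] - pos[i, 0], L)
            dy = _mic(pos[j, 1] - pos[i, 1], L)
            dz = _mic(pos[j, 2] - pos[i, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                nb_idx[nnb] = j
                nb_d[nnb, 0] = dx
                nb_d[nnb, 1] = dy
                nb_d[nnb, 2] = dz
                r = math.sqrt(r2)
                nb_r[nnb] = r
                inv = 1.0 / r
                nb_inv[nnb] = inv
                nb_e[nnb, 0] = dx * inv
                nb_e[nnb, 1] = dy * inv
                nb_e[nnb, 2] = dz * inv
                nnb += 1
        if zcode[i] == 0:
            w = wradO
            poly = polyO
        else:
            w = wradH
            poly = polyH
        # radial terms
        for a in range(nnb):
            j = nb_idx[a]
            r = nb_r[a]
            fc = 0.5 * (1.0 + math.cos(math.pi * r / rc))
            dfc = -0.5 * math.pi / rc * math.sin(math.pi * r / rc)
            off = zcode[j] * nR
            dEdr = 0.0
            # angular envelope g(r) = exp(−η r²)·fc and its derivative,
            # reused by the triplet loop below
            eu = math.exp(-eta * r * r)
            nb_g[a] = eu * fc
            nb_dg[a] = eu * (dfc - 2.0 * eta * r * fc)
            for k in range(nR):
                dmu = r - mu[k]
                if dmu * dmu > w5:
                    continue
                g = math.exp(-dmu * dmu * inv2w2)
                coef = w[off + k]
                energy += coef * g * fc
                dEdr += coef * g * (-dmu * 2.0 * inv2w2 * fc + dfc)
            # d = r_j − r_i ; force on j is −dE/dr · d̂
            pref = dEdr * nb_inv[a]
            fx = -pref * nb_d[a, 0]
            fy = -pref * nb_d[a, 1]
            fz = -pref * nb_d[a, 2]
            F[j, 0] += fx
            F[j, 1] += fy
            F[j, 2] += fz
            F[i, 0] -= fx
            F[i, 1] -= fy
            F[i, 2] -= fz
            W[0, 0] += nb_d[a, 0] * fx
            W[0, 1] += nb_d[a, 0] * fy
            W[0, 2] += nb_d[a, 0] * fz
            W[1, 0] += nb_d[a, 1] * fx
            W[1, 1] += nb_d[a, 1] * fy
            W[1, 2] += nb_d[a, 1] * fz
            W[2, 0] += nb_d[a, 2] * fx
            W[2, 1] += nb_d[a, 2] * fy
            W[2, 2] += nb_d[a, 2] * fz
        # angular terms
        for a in range(nnb):
            j = nb_idx[a]
            inv_ru = nb_inv[a]
            eax = nb_e[a, 0]
            eay = nb_e[a, 1]
            eaz = nb_e[a, 2]
            ux = nb_d[a, 0]
            uy = nb_d[a, 1]
            uz = nb_d[a, 2]
            gu = nb_g[a]
            dgu = nb_dg[a]
            za = zcode[j]
            for b in range(a + 1, nnb):
                env = gu * nb_g[b]
                if env < 1e-10 and env > -1e-10:
                    continue
                k = nb_idx[b]
                inv_rv = nb_inv[b]
                ebx = nb_e[b, 0]
                eby = nb_e[b, 1]
                ebz = nb_e[b, 2]
                gv = nb_g[b]
                dgv = nb_dg[b]
                zb = zcode[k]
                ptype = za + zb
                c = eax * ebx + eay * eby + eaz * ebz
                # Horner evaluation of B(c) and B'(c)
                Bsum = poly[ptype, ndeg - 1]
                dBsum = 0.0
                for t in range(ndeg - 2, -1, -1):
                    dBsum = dBsum * c + Bsum
                    Bsum = Bsum * c + poly[ptype, t]
                energy += Bsum * env
                dE_dc = dBsum * env
                pref_u = Bsum * dgu * gv
                pref_v = Bsum * gu * dgv
                cu = dE_dc * inv_ru
                cv = dE_dc * inv_rv
                gux = cu * (ebx - c * eax) + pref_u * eax
                guy = cu * (eby - c * eay) + pref_u * eay
                guz = cu * (ebz - c * eaz) + pref_u * eaz
                gvx = cv * (eax - c * ebx) + pref_v * ebx
                gvy = cv * (eay - c * eby) + pref_v * eby
                gvz = cv * (eaz - c * ebz) + pref_v * ebz
                F[j, 0] -= gux
                F[j, 1] -= guy
                F[j, 2] -= guz
                F[k, 0] -= gvx
                F[k, 1] -= gvy
                F[k, 2] -= gvz
                F[i, 0] += gux + gvx
                F[i, 1] += guy + gvy
                F[i, 2] += guz + gvz
                vx = nb_d[b, 0]
                vy = nb_d[b, 1]
                vz = nb_d[b, 2]
                W[0, 0] -= ux * gux + vx * gvx
                W[0, 1] -= ux * guy + vx * gvy
                W[0, 2] -= ux * guz + vx * gvz
                W[1, 0] -= uy * gux + vy * gvx
                W[1, 1] -= uy * guy + vy * gvy
                W[1, 2] -= uy * guz + vy * gvz
                W[2, 0] -= uz * gux + vz * gvx
                W[2, 1] -= uz * guy + vz * gvy
                W[2, 2] -= uz * guz + vz * gvz
    return energy, F, W


def featurize(positions: np.ndarray, zcode: np.ndarray, L: float,
              spec: DescriptorSpec) -> np.ndarray:
    """Per-atom feature matrix (N × n_per_element).

    The per-element feature *vector* of a configuration is obtained by
    summing rows over atoms of each element.
    """
    mu, width, eta, lam, zet = spec.arrays()
    return _featurize(np.ascontiguousarray(positions, dtype=float),
                      zcode, L, spec.cutoff, mu, width, eta, lam, zet)


def feature_sums(positions: np.ndarray, zcode: np.ndarray, L: float,
                 spec: DescriptorSpec) -> np.ndarray:
    """Summed features per center element: shape (2, n_per_element)."""
    f = featurize(positions, zcode, L, spec)
    out = np.zeros((2, spec.n_per_element))
    for z in (0, 1):
        out[z] = f[zcode == z].sum(axis=0)
    return out


def _expand_element_weights(spec: DescriptorSpec, w: np.ndarray):
    """Split one element's weight block into radial weights and the
    polynomial coefficients (in cos θ) of the weighted angular basis."""
    nR = spec.n_radial
    nA = spec.n_angular
    wrad = np.ascontiguousarray(w[:2 * nR], dtype=float)
    deg = max((int(z) for _, z in spec.angular_set), default=0)
    poly = np.zeros((3, deg + 1))
    for ptype in range(3):
        for t, (lam, zet) in enumerate(spec.angular_set):
            coef = w[2 * nR + ptype * nA + t]
            for k in range(int(zet) + 1):
                poly[ptype, k] += coef * math.comb(int(zet), k) * lam ** k
    return wrad, poly


def contract(positions: np.ndarray, zcode: np.ndarray, L: float,
             spec: DescriptorSpec, wO: np.ndarray, wH: np.ndarray):
    """Energy, forces and virial of the weighted descriptor sum."""
    mu, width, eta, lam, zet = spec.arrays()
    wradO, polyO = _expand_element_weights(spec, wO)
    wradH, polyH = _expand_element_weights(spec, wH)
    return _contract(np.ascontiguousarray(positions, dtype=float),
                     zcode, L, spec.cutoff, mu, width, eta,
                     wradO, wradH, polyO, polyH)
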