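"""Compiled force kernels for the reference potentials.

All kernels take a cubic box edge ``L`` (``L <= 0`` means open
boundaries) and return total energy (eV), per-atom forces (eV/Å) and
the virial tensor W = −Σ_terms d ⊗ ∂E/∂d (eV), from which the
instantaneous pressure is P = (2K + tr W) / (3V).

The O(N²) pair loops are deliberate: at the system sizes in scope
(≤ 400 atoms) they outperform cell lists once compiled.
"""

from __future__ import annotations

import math

import numba
import numpy as np

# parameter-vector layout for eval_water
P_KBOND, P_R0, P_KANGLE, P_THETA0 = 0, 1, 2, 3
P_QO, P_QH, P_ALPHA, P_RC_COUL = 4, 5, 6, 7
P_EPS, P_SIGMA, P_RON_LJ, P_RC_LJ = 8, 9, 10, 11
P_LAM3, P_COS0, P_ETA3, P_RC3, P_USE3 = 12, 13, 14, 15, 16
N_PARAMS = 17

COULOMB = 14.399645478425668


@numba.njit(cache=True, inline="always")
def _mic(d, L):
    if L > 0.0:
        return d - L * math.floor(d / L + 0.5)
    return d


@numba.njit(cache=True, inline="always")
def _bond_term(io, ih, hx, hy, hz, rr, kb, r0, F, W):
    e = 0.5 * kb * (rr - r0) * (rr - r0)
    fpr = -kb * (rr - r0) / rr
    fx = fpr * hx
    fy = fpr * hy
    fz = fpr * hz
    F[ih, 0] += fx
    F[ih, 1] += fy
    F[ih, 2] += fz
    F[io, 0] -= fx
    F[io, 1] -= fy
    F[io, 2] -= fz
    W[0, 0] += hx * fx
    W[0, 1] += hx * fy
    W[0, 2] += hx * fz
    W[1, 0] += hy * fx
    W[1, 1] += hy * fy
    W[1, 2] += hy * fz
    W[2, 0] += hz * fx
    W[2, 1] += hz * fy
    W[2, 2] += hz * fz
    return e


@numba.njit(cache=True, fastmath=True)
def eval_water(pos, zcode, mol_of, oxygens, hydrogens, L, p):
    """Energy, forces and virial of the flexible-water model.

    zcode: 0 for O, 1 for H.  The three-body O–O–O term is evaluated
    only when p[P_USE3] > 0.5 (the high-level surface).
    """
    n = pos.shape[0]
    nmol = oxygens.shape[0]
    F = np.zeros((n, 3))
    W = np.zeros((3, 3))
    energy = 0.0

    kb = p[P_KBOND]
    r0 = p[P_R0]
    ka = p[P_KANGLE]
    th0 = p[P_THETA0]
    qO = p[P_QO]
    qH = p[P_QH]
    alpha = p[P_ALPHA]
    rc_c = p[P_RC_COUL]
    eps = p[P_EPS]
    sig = p[P_SIGMA]
    ron = p[P_RON_LJ]
    rc_l = p[P_RC_LJ]

    # DSF Coulomb shift constants
    erfc_rc = math.erfc(alpha * rc_c)
    e_shift = erfc_rc / rc_c
    f_shift = erfc_rc / (rc_c * rc_c) + 2.0 * alpha / math.sqrt(math.pi) * math.exp(
        -alpha * alpha * rc_c * rc_c) / rc_c

    # ---- intramolecular: two bonds + one angle per molecule ----
    for m in range(nmol):
        io = oxygens[m]
        ih1 = hydrogens[m, 0]
        ih2 = hydrogens[m, 1]
        ux = _mic(pos[ih1, 0] - pos[io, 0], L)
        uy = _mic(pos[ih1, 1] - pos[io, 1], L)
        uz = _mic(pos[ih1, 2] - pos[io, 2], L)
        vx = _mic(pos[ih2, 0] - pos[io, 0], L)
        vy = _mic(pos[ih2, 1] - pos[io, 1], L)
        vz = _mic(pos[ih2, 2] - pos[io, 2], L)
        ru = math.sqrt(ux * ux + uy * uy + uz * uz)
        rv = math.sqrt(vx * vx + vy * vy + vz * vz)

        # bonds: E = ½ k (r − r0)²
        energy += _bond_term(io, ih1, ux, uy, uz, ru, kb, r0, F, W)
        energy += _bond_term(io, ih2, vx, vy, vz, rv, kb, r0, F, W)

        # angle: E = ½ k (θ − θ0)²
        dot = ux * vx + uy * vy + uz * vz
        c = dot / (ru * rv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        s = math.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        th = math.acos(c)
        energy += 0.5 * ka * (th - th0) * (th - th0)
        dE_dc = -ka * (th - th0) / s
        # dc/du and dc/dv
        inv_uv = 1.0 / (ru * rv)
        dcux = vx * inv_uv - c * ux / (ru * ru)
        dcuy = vy * inv_uv - c * uy / (ru * ru)
        dcuz = vz * inv_uv - c * uz / (ru * ru)
        dcvx = ux * inv_uv - c * vx / (rv * rv)
        dcvy = uy * inv_uv - c * vy / (rv * rv)
        dcvz = uz * inv_uv - c * vz / (rv * rv)
        f1x = -dE_dc * dcux
        f1y = -dE_dc * dcuy
        f1z = -dE_dc * dcuz
        f2x = -dE_dc * dcvx
        f2y = -dE_dc * dcvy
        f2z = -dE_dc * dcvz
        F[ih1, 0] += f1x
        F[ih1, 1] += f1y
        F[ih1, 2] += f1z
        F[ih2, 0] += f2x
        F[ih2, 1] += f2y
        F[ih2, 2] += f2z
        F[io, 0] -= f1x + f2x
        F[io, 1] -= f1y + f2y
        F[io, 2] -= f1z + f2z
        W[0, 0] += ux * f1x + vx * f2x
        W[0, 1] += ux * f1y + vx * f2y
        W[0, 2] += ux * f1z + vx * f2z
        W[1, 0] += uy * f1x + vy * f2x
        W[1, 1] += uy * f1y + vy * f2y
        W[1, 2] += uy * f1z + vy * f2z
        W[2, 0] += uz * f1x + vz * f2x
        W[2, 1] += uz * f1y + vz * f2y
        W[2, 2] += uz * f1z + vz * f2z

    # ---- intermolecular pairs: DSF Coulomb + switched LJ (O–O) ----
    rc_max = rc_c if rc_c > rc_l else rc_l
    rc_max2 = rc_max * rc_max
    for i in range(n):
        qi = qO if zcode[i] == 0 else qH
        for j in range(i + 1, n):
            if mol_of[i] == mol_of[j]:
                continue
            dx = _mic(pos[i, 0] - pos[j, 0], L)
            dy = _mic(pos[i, 1] - pos[j, 1], L)
            dz = _mic(pos[i, 2] - pos[j, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc_max2:
                continue
            r = math.sqrt(r2)
            dE_dr = 0.0  # dE/dr accumulated

            if r < rc_c:
                qj = qO if zcode[j] == 0 else qH
                qq = COULOMB * qi * qj
                er = math.erfc(alpha * r)
                energy += qq * (er / r - e_shift + f_shift * (r - rc_c))
                dE_dr += qq * (-(er / r2 + 2.0 * alpha / math.sqrt(math.pi)
                                 * math.exp(-alpha * alpha * r2) / r) + f_shift)

            if zcode[i] == 0 and zcode[j] == 0 and r < rc_l:
                sr6 = (sig / r) ** 6
                elj = 4.0 * eps * (sr6 * sr6 - sr6)
                dlj = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
                if r <= ron:
                    energy += elj
                    dE_dr += dlj
                else:
                    t = (r - ron) / (rc_l - ron)
                    sw = 1.0 - t * t * (3.0 - 2.0 * t)
                    dsw = -6.0 * t * (1.0 - t) / (rc_l - ron)
                    energy += elj * sw
                    dE_dr += dlj * sw + elj * dsw

            if dE_dr != 0.0:
                fpr = -dE_dr / r
                fx = fpr * dx
                fy = fpr * dy
                fz = fpr * dz
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                F[j, 0] -= fx
                F[j, 1] -= fy
                F[j, 2] -= fz
                W[0, 0] += dx * fx
                W[0, 1] += dx * fy
                W[0, 2] += dx * fz
                W[1, 0] += dy * fx
                W[1, 1] += dy * fy
                W[1, 2] += dy * fz
                W[2, 0] += dz * fx
                W[2, 1] += dz * fy
                W[2, 2] += dz * fz

    # ---- three-body O–O–O (high-level surface only) ----
    if p[P_USE3] > 0.5:
        lam3 = p[P_LAM3]
        c0 = p[P_COS0]
        eta3 = p[P_ETA3]
        rc3 = p[P_RC3]
        rc32 = rc3 * rc3
        max_nb = nmol
        nb_idx = np.empty(max_nb, dtype=np.int64)
        nb_d = np.empty((max_nb, 3))
        nb_r = np.empty(max_nb)
        for mi in range(nmol):
            i = oxygens[mi]
            nnb = 0
            for mj in range(nmol):
                if mj == mi:
                    continue
                j = oxygens[mj]
                dx = _mic(pos[j, 0] - pos[i, 0], L)
                dy = _mic(pos[j, 1] - pos[i, 1], L)
                dz = _mic(pos[j, 2] - pos[i, 2], L)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc32:
                    nb_idx[nnb] = j
                    nb_d[nnb, 0] = dx
                    nb_d[nnb, 1] = dy
                    nb_d[nnb, 2] = dz
                    nb_r[nnb] = math.sqrt(r2)
                    nnb += 1
            for a in range(nnb):
                j = nb_idx[a]
                ru = nb_r[a]
                ux = nb_d[a, 0]
                uy = nb_d[a, 1]
                uz = nb_d[a, 2]
                # g(r) = exp(−η r²)·fc(r), fc cosine cutoff
                eu = math.exp(-eta3 * ru * ru)
                fcu = 0.5 * (1.0 + math.cos(math.pi * ru / rc3))
                gu = eu * fcu
                dgu = eu * (-0.5 * math.pi / rc3 * math.sin(math.pi * ru / rc3)
                            - 2.0 * eta3 * ru * fcu)
                for b in range(a + 1, nnb):
                    k = nb_idx[b]
                    rv = nb_r[b]
                    vx = nb_d[b, 0]
                    vy = nb_d[b, 1]
                    vz = nb_d[b, 2]
                    ev = math.exp(-eta3 * rv * rv)
                    fcv = 0.5 * (1.0 + math.cos(math.pi * rv / rc3))
                    gv = ev * fcv
                    dgv = ev * (-0.5 * math.pi / rc3 * math.sin(math.pi * rv / rc3)
                                - 2.0 * eta3 * rv * fcv)

                    dot = ux * vx + uy * vy + uz * vz
                    c = dot / (ru * rv)
                    pc = c - c0
                    energy += lam3 * pc * pc * gu * gv

                    dE_dc = lam3 * 2.0 * pc * gu * gv
                    pref_u = lam3 * pc * pc * dgu * gv / ru
                    pref_v = lam3 * pc * pc * gu * dgv / rv
                    inv_uv = 1.0 / (ru * rv)
                    # dE/du vector
                    gux = dE_dc * (vx * inv_uv - c * ux / (ru * ru)) + pref_u * ux
                    guy = dE_dc * (vy * inv_uv - c * uy / (ru * ru)) + pref_u * uy
                    guz = dE_dc * (vz * inv_uv - c * uz / (ru * ru)) + pref_u * uz
                    gvx = dE_dc * (ux * inv_uv - c * vx / (rv * rv)) + pref_v * vx
                    gvy = dE_dc * (uy * inv_uv - c * vy / (rv * rv)) + pref_v * vy
                    gvz = dE_dc * (uz * inv_uv - c * vz / (rv * rv)) + pref_v * vz
                    F[j, 0] -= gux
                    F[j, 1] -= guy
                    F[j, 2] -= guz
                    F[k, 0] -= gvx
                    F[k, 1] -= gvy
                    F[k, 2] -= gvz
                    F[i, 0] += gux + gvx
                    F[i, 1] += guy + gvy
                    F[i, 2] += guz + gvz
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
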