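"""Numba-compiled inner loops for the Langevin engine.

The kernels evaluate the same model as :mod:`coacervmd.forcefield` (which is
the plain-numpy reference used by the test-suite oracles) over a
pre-computed Verlet pair list, and advance BAOAB Langevin dynamics in chunks
between pair-list rebuilds.  Thermostat noise is seeded per chunk so
trajectories are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RT26 = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def compute_forces(pos, frc, box, pairs, charges, lambdas, sigmas,
                   eps_lj, cutoff_sr, cutoff_elec, coulomb_pref, lambda_d,
                   bond_idx, bond_k, bond_r0,
                   angle_idx, angle_k, angle_th0,
                   hb_idx, hb_k, hb_r0):
    """Fill ``frc`` with total forces; return potential energy (kcal/mol)."""
    n = pos.shape[0]
    for a in range(n):
        frc[a, 0] = 0.0
        frc[a, 1] = 0.0
        frc[a, 2] = 0.0
    energy = 0.0
    cut_sr2 = cutoff_sr * cutoff_sr
    cut_el2 = cutoff_elec * cutoff_elec
    cut_max2 = max(cut_sr2, cut_el2)
    # nonbonded over the pair list
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cut_max2:
            continue
        r = np.sqrt(r2)
        if r < 1e-6:
            return np.inf
        du = 0.0
        if r2 <= cut_sr2:
            sig = 0.5 * (sigmas[i] + sigmas[j])
            lam = 0.5 * (lambdas[i] + lambdas[j])
            sr6 = (sig / r) ** 6
            ulj = 4.0 * eps_lj * (sr6 * sr6 - sr6)
            dulj = 4.0 * eps_lj * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            if r <= RT26 * sig:
                energy += ulj + (1.0 - lam) * eps_lj
                du += dulj
            else:
                energy += lam * ulj
                du += lam * dulj
        qq = charges[i] * charges[j]
        if qq != 0.0 and r2 <= cut_el2:
            u = coulomb_pref * qq / r * np.exp(-r / lambda_d)
            energy += u
            du += -u * (1.0 / r + 1.0 / lambda_d)
        if du != 0.0:
            f = -du / r
            frc[j, 0] += f * dx
            frc[j, 1] += f * dy
            frc[j, 2] += f * dz
            frc[i, 0] -= f * dx
            frc[i, 1] -= f * dy
            frc[i, 2] -= f * dz
    # bonds and hybridization springs
    for arrs in range(2):
        if arrs == 0:
            idx, kk, rr0 = bond_idx, bond_k, bond_r0
        else:
            idx, kk, rr0 = hb_idx, hb_k, hb_r0
        for b in range(idx.shape[0]):
            i = idx[b, 0]
            j = idx[b, 1]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - rr0[b]
            energy += kk[b] * dr * dr
            f = -2.0 * kk[b] * dr / r
            frc[j, 0] += f * dx
            frc[j, 1] += f * dy
            frc[j, 2] += f * dz
            frc[i, 0] -= f * dx
            frc[i, 1] -= f * dy
            frc[i, 2] -= f * dz
    # angles
    for a in range(angle_idx.shape[0]):
        ai = angle_idx[a, 0]
        aj = angle_idx[a, 1]
        ak = angle_idx[a, 2]
        ux = pos[ai, 0] - pos[aj, 0]
        uy = pos[ai, 1] - pos[aj, 1]
        uz = pos[ai, 2] - pos[aj, 2]
        vx = pos[ak, 0] - pos[aj, 0]
        vy = pos[ak, 1] - pos[aj, 1]
        vz = pos[ak, 2] - pos[aj, 2]
        ux -= box[0] * np.rint(ux / box[0])
        uy -= box[1] * np.rint(uy / box[1])
        uz -= box[2] * np.rint(uz / box[2])
        vx -= box[0] * np.rint(vx / box[0])
        vy -= box[1] * np.rint(vy / box[1])
        vz -= box[2] * np.rint(vz / box[2])
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ux /= nu
        uy /= nu
        uz /= nu
        vx /= nv
        vy /= nv
        vz /= nv
        cth = ux * vx + uy * vy + uz * vz
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        th = np.arccos(cth)
        dth = th - angle_th0[a]
        energy += angle_k[a] * dth * dth
        sth = np.sqrt(max(1.0 - cth * cth, 1e-12))
        g = 2.0 * angle_k[a] * dth / sth
        fix = g / nu * (vx - cth * ux)
        fiy = g / nu * (vy - cth * uy)
        fiz = g / nu * (vz - cth * uz)
        fkx = g / nv * (ux - cth * vx)
        fky = g / nv * (uy - cth * vy)
        fkz = g / nv * (uz - cth * vz)
        frc[ai, 0] += fix
        frc[ai, 1] += fiy
        frc[ai, 2] += fiz
        frc[ak, 0] += fkx
        frc[ak, 1] += fky
        frc[ak, 2] += fkz
        frc[aj, 0] -= fix + fkx
        frc[aj, 1] -= fiy + fky
        frc[aj, 2] -= fiz + fkz
    return energy


@njit(cache=True)
def integrate_chunk(pos, vel, frc, nsteps, dt, bfac, sig_v, inv_meff, box,
                    pairs, charges, lambdas, sigmas,
                    eps_lj, cutoff_sr, cutoff_elec, coulomb_pref, lambda_d,
                    bond_idx, bond_k, bond_r0,
                    angle_idx, angle_k, angle_th0,
                    hb_idx, hb_k, hb_r0, seed):
    """Advance ``nsteps`` BAOAB Langevin steps with a frozen pair list.

    ``bfac`` = exp(-gamma dt); ``sig_v`` per-bead OU noise amplitude in A/fs;
    ``inv_meff`` = 1/(m * MVSQ2E) so that F * inv_meff is in A/fs^2.
    Returns the potential energy after the last step (inf on bead overlap).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    energy = 0.0
    for _ in range(nsteps):
        for a in range(n):
            for d in range(3):
                vel[a, d] += 0.5 * dt * frc[a, d] * inv_meff[a]
                pos[a, d] += 0.5 * dt * vel[a, d]
        if sig_v[0] > 0.0 or bfac < 1.0:
            noise = np.random.standard_normal((n, 3))
            for a in range(n):
                for d in range(3):
                    vel[a, d] = bfac * vel[a, d] + sig_v[a] * noise[a, d]
        for a in range(n):
            for d in range(3):
                pos[a, d] += 0.5 * dt * vel[a, d]
        energy = compute_forces(pos, frc, box, pairs, charges, lambdas, sigmas,
                                eps_lj, cutoff_sr, cutoff_elec, coulomb_pref,
                                lambda_d, bond_idx, bond_k, bond_r0,
                                angle_idx, angle_k, angle_th0,
                                hb_idx, hb_k, hb_r0)
        if not np.isfinite(energy):
            return energy
        for a in range(n):
            for d in range(3):
                vel[a, d] += 0.5 * dt * frc[a, d] * inv_meff[a]
    return energy
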