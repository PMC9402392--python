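"""Numba kernels: potential-energy/force evaluation and Langevin propagation.

All quantities are in reduced units (lengths nm, energies in the basic
unit ε).  The excluded-volume sum is truncated and shifted at
``ev_cutoff`` (default 2.5 nm), where the unshifted term is below
1e-9 ε for the default core radius of 0.4 nm; shifting keeps the
potential continuous so analytic forces match finite differences.
The inner loops are written with scalar arithmetic only — no small
per-pair temporaries — which is what keeps a step on a few dozen beads
in the microsecond range.

Component indices used throughout:
0 bond, 1 angle, 2 dihedral, 3 dual_gaussian, 4 specific_open,
5 specific_closed, 6 excluded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_COMPONENTS = 7


@njit(cache=True)
def _accumulate(coords, forces, comps,
                bond_idx, bond_r0, k_r,
                angle_idx, angle_theta0, k_theta,
                dihedral_idx, dihedral_phi0, k_phi1, k_phi3,
                dg_idx, dg_r1, dg_r2, eps_dg, sigma_nc, gauss_width,
                spec_idx, spec_sigma, spec_strength, spec_is_closed,
                ev_idx, eps_ev, ev_cutoff):
    # bonds: K_r (r - r0)^2
    for b in range(bond_idx.shape[0]):
        i, j = bond_idx[b, 0], bond_idx[b, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        comps[0] += k_r * dr * dr
        fmag = -2.0 * k_r * dr / r
        forces[j, 0] += fmag * dx
        forces[j, 1] += fmag * dy
        forces[j, 2] += fmag * dz
        forces[i, 0] -= fmag * dx
        forces[i, 1] -= fmag * dy
        forces[i, 2] -= fmag * dz

    # angles: K_theta (theta - theta0)^2
    for a in range(angle_idx.shape[0]):
        i, j, k = angle_idx[a, 0], angle_idx[a, 1], angle_idx[a, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cost = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        dt = theta - angle_theta0[a]
        comps[1] += k_theta * dt * dt
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        coef = 2.0 * k_theta * dt / sint
        inu = 1.0 / nu
        inv = 1.0 / nv
        fix = coef * (vx * inv - cost * ux * inu) * inu
        fiy = coef * (vy * inv - cost * uy * inu) * inu
        fiz = coef * (vz * inv - cost * uz * inu) * inu
        fkx = coef * (ux * inu - cost * vx * inv) * inv
        fky = coef * (uy * inu - cost * vy * inv) * inv
        fkz = coef * (uz * inu - cost * vz * inv) * inv
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    # dihedrals: sum_{n=1,3} K_n (1 - cos n(phi - phi0))
    for t in range(dihedral_idx.shape[0]):
        i = dihedral_idx[t, 0]
        j = dihedral_idx[t, 1]
        k = dihedral_idx[t, 2]
        l = dihedral_idx[t, 3]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (mx * n2x + my * n2y + mz * n2z) / nb2
        phi = np.arctan2(y, x)
        dphi = phi - dihedral_phi0[t]
        comps[2] += (k_phi1 * (1.0 - np.cos(dphi))
                     + k_phi3 * (1.0 - np.cos(3.0 * dphi)))
        dedphi = k_phi1 * np.sin(dphi) + 3.0 * k_phi3 * np.sin(3.0 * dphi)
        sq1 = n1x * n1x + n1y * n1y + n1z * n1z
        sq2 = n2x * n2x + n2y * n2y + n2z * n2z
        if sq1 < 1e-12:
            sq1 = 1e-12
        if sq2 < 1e-12:
            sq2 = 1e-12
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        ci = -dedphi * nb2 / sq1
        cl = dedphi * nb2 / sq2
        fix = ci * n1x
        fiy = ci * n1y
        fiz = ci * n1z
        flx = cl * n2x
        fly = cl * n2y
        flz = cl * n2z
        fjx = -(1.0 + p) * fix + q * flx
        fjy = -(1.0 + p) * fiy + q * fly
        fjz = -(1.0 + p) * fiz + q * flz
        fkx = p * fix - (1.0 + q) * flx
        fky = p * fiy - (1.0 + q) * fly
        fkz = p * fiz - (1.0 + q) * flz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[j, 0] += fjx
        forces[j, 1] += fjy
        forces[j, 2] += fjz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz

    # common contacts: dual-Gaussian
    # eps_dg * ([1 + (s/r)^12][1 + G1][1 + G2] - 1), G_n = -exp(-(r-rn)^2/(2 w^2))
    w2 = gauss_width * gauss_width
    for c in range(dg_idx.shape[0]):
        i, j = dg_idx[c, 0], dg_idx[c, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        s2 = sigma_nc * sigma_nc / r2
        s4 = s2 * s2
        core = s4 * s4 * s4
        g1 = -np.exp(-((r - dg_r1[c]) ** 2) / (2.0 * w2))
        g2 = -np.exp(-((r - dg_r2[c]) ** 2) / (2.0 * w2))
        comps[3] += eps_dg * ((1.0 + core) * (1.0 + g1) * (1.0 + g2) - 1.0)
        dcore = -12.0 * core / r
        dg1 = -g1 * (r - dg_r1[c]) / w2
        dg2 = -g2 * (r - dg_r2[c]) / w2
        dudr = eps_dg * (dcore * (1.0 + g1) * (1.0 + g2)
                         + (1.0 + core) * dg1 * (1.0 + g2)
                         + (1.0 + core) * (1.0 + g1) * dg2)
        fmag = -dudr / r
        forces[j, 0] += fmag * dx
        forces[j, 1] += fmag * dy
        forces[j, 2] += fmag * dz
        forces[i, 0] -= fmag * dx
        forces[i, 1] -= fmag * dy
        forces[i, 2] -= fmag * dz

    # state-specific contacts: 10-12 wells
    for c in range(spec_idx.shape[0]):
        i, j = spec_idx[c, 0], spec_idx[c, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        sr2 = spec_sigma[c] * spec_sigma[c] / r2
        sr4 = sr2 * sr2
        sr10 = sr4 * sr4 * sr2
        sr12 = sr10 * sr2
        e = spec_strength[c] * (5.0 * sr12 - 6.0 * sr10)
        if spec_is_closed[c]:
            comps[5] += e
        else:
            comps[4] += e
        fmag = spec_strength[c] * (60.0 * sr12 - 60.0 * sr10) / r2
        forces[j, 0] += fmag * dx
        forces[j, 1] += fmag * dy
        forces[j, 2] += fmag * dz
        forces[i, 0] -= fmag * dx
        forces[i, 1] -= fmag * dy
        forces[i, 2] -= fmag * dz

    # excluded volume: eps_ev (sigma_nc/r)^12, truncated & shifted at ev_cutoff
    shift = eps_ev * (sigma_nc / ev_cutoff) ** 12
    cut2 = ev_cutoff * ev_cutoff
    sig2 = sigma_nc * sigma_nc
    for c in range(ev_idx.shape[0]):
        i, j = ev_idx[c, 0], ev_idx[c, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2:
            continue
        s2 = sig2 / r2
        s4 = s2 * s2
        e = eps_ev * s4 * s4 * s4
        comps[6] += e - shift
        fmag = 12.0 * e / r2
        forces[j, 0] += fmag * dx
        forces[j, 1] += fmag * dy
        forces[j, 2] += fmag * dz
        forces[i, 0] -= fmag * dx
        forces[i, 1] -= fmag * dy
        forces[i, 2] -= fmag * dz


@njit(cache=True)
def energy_forces(
    coords,
    bond_idx, bond_r0, k_r,
    angle_idx, angle_theta0, k_theta,
    dihedral_idx, dihedral_phi0, k_phi1, k_phi3,
    dg_idx, dg_r1, dg_r2, eps_dg, sigma_nc, gauss_width,
    spec_idx, spec_sigma, spec_strength, spec_is_closed,
    ev_idx, eps_ev, ev_cutoff,
):
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    comps = np.zeros(N_COMPONENTS)
    _accumulate(coords, forces, comps,
                bond_idx, bond_r0, k_r,
                angle_idx, angle_theta0, k_theta,
                dihedral_idx, dihedral_phi0, k_phi1, k_phi3,
                dg_idx, dg_r1, dg_r2, eps_dg, sigma_nc, gauss_width,
                spec_idx, spec_sigma, spec_strength, spec_is_closed,
                ev_idx, eps_ev, ev_cutoff)
    return comps, forces


@njit(cache=True)
def integrate_chunk(
    coords, velocities, n_steps, dt, gamma, kbt, mass, noise,
    bond_idx, bond_r0, k_r,
    angle_idx, angle_theta0, k_theta,
    dihedral_idx, dihedral_phi0, k_phi1, k_phi3,
    dg_idx, dg_r1, dg_r2, eps_dg, sigma_nc, gauss_width,
    spec_idx, spec_sigma, spec_strength, spec_is_closed,
    ev_idx, eps_ev, ev_cutoff,
):
    """BAOAB Langevin leapfrog; with gamma == 0 it reduces to velocity Verlet.

    ``noise`` has shape (n_steps, n, 3) of standard normals (ignored when
    gamma == 0).  Updates coords/velocities in place and returns the final
    energy components and forces.
    """
    n = coords.shape[0]
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kbt / mass)
    else:
        c1 = 1.0
        c2 = 0.0
    forces = np.zeros((n, 3))
    comps = np.zeros(N_COMPONENTS)
    _accumulate(coords, forces, comps,
                bond_idx, bond_r0, k_r,
                angle_idx, angle_theta0, k_theta,
                dihedral_idx, dihedral_phi0, k_phi1, k_phi3,
                dg_idx, dg_r1, dg_r2, eps_dg, sigma_nc, gauss_width,
                spec_idx, spec_sigma, spec_strength, spec_is_closed,
                ev_idx, eps_ev, ev_cutoff)
    half = 0.5 * dt
    kick = half / mass
    for s in range(n_steps):
        for i in range(n):
            for d in range(3):
                velocities[i, d] += kick * forces[i, d]
                coords[i, d] += half * velocities[i, d]
        if gamma > 0.0:
            for i in range(n):
                for d in range(3):
                    velocities[i, d] = c1 * velocities[i, d] + c2 * noise[s, i, d]
        for i in range(n):
            for d in range(3):
                coords[i, d] += half * velocities[i, d]
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        for c in range(N_COMPONENTS):
            comps[c] = 0.0
        _accumulate(coords, forces, comps,
                    bond_idx, bond_r0, k_r,
                    angle_idx, angle_theta0, k_theta,
                    dihedral_idx, dihedral_phi0, k_phi1, k_phi3,
                    dg_idx, dg_r1, dg_r2, eps_dg, sigma_nc, gauss_width,
                    spec_idx, spec_sigma, spec_strength, spec_is_closed,
                    ev_idx, eps_ev, ev_cutoff)
        for i in range(n):
            for d in range(3):
                velocities[i, d] += kick * forces[i, d]
    return comps, forces
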