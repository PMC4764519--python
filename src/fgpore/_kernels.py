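"""Numba kernels for the hot loops of the simulation engine.

These evaluate exactly the same expressions as the reference functions in
:mod:`fgpore.forcefield`; unit tests check both against numerical gradients.
"""

from __future__ import annotations

import numba as nb
import numpy as np

_F8 = nb.float64


@nb.njit(cache=True, inline="always")
def _spline_seg(x, x0, dx, coeffs):
    """Evaluate a piecewise-cubic spline; clamp outside (flat, zero slope).

    Returns (energy, dE/dx, clamped_flag).
    """
    nseg = coeffs.shape[1]
    t = (x - x0) / dx
    i = int(np.floor(t))
    clamped = 0
    if i < 0:
        i = 0
        s = 0.0
        if x < x0 - 1e-12:
            clamped = 1
    elif i >= nseg:
        i = nseg - 1
        s = dx
        if x > x0 + nseg * dx + 1e-12:
            clamped = 1
    else:
        s = x - (x0 + i * dx)
    c0 = coeffs[0, i]
    c1 = coeffs[1, i]
    c2 = coeffs[2, i]
    c3 = coeffs[3, i]
    e = ((c0 * s + c1) * s + c2) * s + c3
    de = (3.0 * c0 * s + 2.0 * c1) * s + c2
    if clamped == 1:
        de = 0.0
    return e, de, clamped


@nb.njit(cache=True)
def bend_forces(pos, triples, x0, dx, coeffs, forces):
    """Tabulated 3-bead bending term; accumulates forces, returns (E, n_clamp)."""
    e_tot = 0.0
    n_clamp = 0
    for a in range(triples.shape[0]):
        i = triples[a, 0]
        j = triples[a, 1]
        k = triples[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        e, de, cl = _spline_seg(theta, x0, dx, coeffs)
        e_tot += e
        n_clamp += cl
        st = np.sqrt(1.0 - ct * ct)
        if st < 1.0e-8:
            st = 1.0e-8
        # grad_i theta = (cos * u_hat - v_hat) / (|u| sin)
        gix = (ct * ux / nu - vx / nv) / (nu * st)
        giy = (ct * uy / nu - vy / nv) / (nu * st)
        giz = (ct * uz / nu - vz / nv) / (nu * st)
        gkx = (ct * vx / nv - ux / nu) / (nv * st)
        gky = (ct * vy / nv - uy / nu) / (nv * st)
        gkz = (ct * vz / nv - uz / nu) / (nv * st)
        forces[i, 0] -= de * gix
        forces[i, 1] -= de * giy
        forces[i, 2] -= de * giz
        forces[k, 0] -= de * gkx
        forces[k, 1] -= de * gky
        forces[k, 2] -= de * gkz
        forces[j, 0] += de * (gix + gkx)
        forces[j, 1] += de * (giy + gky)
        forces[j, 2] += de * (giz + gkz)
    return e_tot, n_clamp


@nb.njit(cache=True)
def dihedral_forces(pos, quads, x0, dx, coeffs, span, forces):
    """Tabulated 4-bead torsion term (periodic table); returns energy."""
    e_tot = 0.0
    for a in range(quads.shape[0]):
        i = quads[a, 0]
        j = quads[a, 1]
        k = quads[a, 2]
        l = quads[a, 3]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        y = (mx * b2x + my * b2y + mz * b2z) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, x)
        # wrap into the table domain
        t = phi - x0
        t = t - span * np.floor(t / span)
        e, de, _ = _spline_seg(x0 + t, x0, dx, coeffs)
        e_tot += e
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1.0e-14 or n2sq < 1.0e-14:
            continue  # degenerate (collinear) dihedral: no defined torque
        c1 = -nb2 / n1sq
        c4 = nb2 / n2sq
        g1x = c1 * n1x
        g1y = c1 * n1y
        g1z = c1 * n1z
        g4x = c4 * n2x
        g4y = c4 * n2y
        g4z = c4 * n2z
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        g2x = -(1.0 + p) * g1x + q * g4x
        g2y = -(1.0 + p) * g1y + q * g4y
        g2z = -(1.0 + p) * g1z + q * g4z
        g3x = p * g1x - (1.0 + q) * g4x
        g3y = p * g1y - (1.0 + q) * g4y
        g3z = p * g1z - (1.0 + q) * g4z
        forces[i, 0] -= de * g1x
        forces[i, 1] -= de * g1y
        forces[i, 2] -= de * g1z
        forces[j, 0] -= de * g2x
        forces[j, 1] -= de * g2y
        forces[j, 2] -= de * g2z
        forces[k, 0] -= de * g3x
        forces[k, 1] -= de * g3y
        forces[k, 2] -= de * g3z
        forces[l, 0] -= de * g4x
        forces[l, 1] -= de * g4y
        forces[l, 2] -= de * g4z
    return e_tot


@nb.njit(cache=True)
def bond_forces(pos, bonds, r0, k, forces):
    """Harmonic bonds; accumulates forces, returns energy."""
    e_tot = 0.0
    for a in range(bonds.shape[0]):
        i = bonds[a, 0]
        j = bonds[a, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        e_tot += 0.5 * k * dr * dr
        fac = k * dr / r
        forces[i, 0] += fac * dx
        forces[i, 1] += fac * dy
        forces[i, 2] += fac * dz
        forces[j, 0] -= fac * dx
        forces[j, 1] -= fac * dy
        forces[j, 2] -= fac * dz
    return e_tot


@nb.njit(cache=True)
def nonbonded_forces(
    pos, pi, pj, eps, sigma, att_shift, att_scale, sigc, sw, cut2, rep, forces
):
    """Hydrophobic / excluded-volume pair interactions over a pair list.

    Pairs with eps > 0 use the hydrophobic form (LJ sigma ``sigma``, cutoff
    sqrt(cut2), precomputed attractive shift/scale); pairs with eps == 0 use
    the purely repulsive contact form with contact distance ``sigc`` and WCA
    sigma ``sw``.  Returns the total energy.
    """
    e_tot = 0.0
    rmin_fac = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2, threshold on r^2/sigma^2
    for a in range(pi.shape[0]):
        i = pi[a]
        j = pj[a]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if eps[a] > 0.0:
            if r2 >= cut2:
                continue
            s2 = sigma[a] * sigma[a]
            sr6 = (s2 / r2) ** 3
            lj = 4.0 * (sr6 * sr6 - sr6)
            dlj_r = (24.0 * sr6 - 48.0 * sr6 * sr6) / r2  # (dlj/dr)/r
            if r2 < rmin_fac * s2:
                e = rep * (lj + 1.0) + att_scale[a] * (-1.0 - att_shift[a])
                dU_r = rep * dlj_r
            else:
                e = att_scale[a] * (lj - att_shift[a])
                dU_r = att_scale[a] * dlj_r
        else:
            if r2 >= sigc[a] * sigc[a]:
                continue
            s2 = sw[a] * sw[a]
            sr6 = (s2 / r2) ** 3
            e = rep * (4.0 * (sr6 * sr6 - sr6) + 1.0)
            dU_r = rep * (24.0 * sr6 - 48.0 * sr6 * sr6) / r2
        e_tot += e
        fx = dU_r * dx  # force on i along +d (repulsive dU_r < 0 pushes apart)
        fy = dU_r * dy
        fz = dU_r * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e_tot


@nb.njit(cache=True)
def electrostatic_forces(pos, pi, pj, pref, inv_lam, rc2, shift, forces):
    """Screened Coulomb over a pair list; pref includes C q_i q_j / eps_r."""
    e_tot = 0.0
    for a in range(pi.shape[0]):
        i = pi[a]
        j = pj[a]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = np.sqrt(r2)
        ex = np.exp(-r * inv_lam)
        e_tot += pref[a] * (ex / r - shift)
        # (dU/dr)/r
        dU_r = -pref[a] * ex * (1.0 / (r2 * r) + inv_lam / r2)
        fx = dU_r * dx
        fy = dU_r * dy
        fz = dU_r * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e_tot


@nb.njit(cache=True)
def max_displacement2(pos, ref, mask):
    """Max squared displacement of masked beads since the reference frame."""
    best = 0.0
    for i in range(pos.shape[0]):
        if not mask[i]:
            continue
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > best:
            best = d2
    return best
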