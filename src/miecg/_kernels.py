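"""Optional numba-accelerated kernels for the hot inner loops.

Pure-NumPy code paths exist for everything here; these kernels are selected
at import time when numba is available.  The reciprocal-space Ewald kernel
builds per-axis complex exponential tables by recurrence (no per-k
trigonometry) and accumulates energy, forces and the isotropic virial in a
single pass over the half k-space.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in the supported env
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True, fastmath=True)
def recip_kernel(positions, charges, box, k1, k2, k3, alpha):
    """Reciprocal-space Ewald: returns (energy, forces, virial) without the
    Coulomb prefactor (caller multiplies by COULOMB)."""
    n = positions.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    volume = lx * ly * lz
    tpi = 2.0 * np.pi

    # per-axis exponential tables e^{i 2π n x / L}, n = 0..kmax (negative n by conjugate)
    ex = np.empty((n, k1 + 1), dtype=np.complex128)
    ey = np.empty((n, k2 + 1), dtype=np.complex128)
    ez = np.empty((n, k3 + 1), dtype=np.complex128)
    for j in range(n):
        ex[j, 0] = 1.0 + 0.0j
        ey[j, 0] = 1.0 + 0.0j
        ez[j, 0] = 1.0 + 0.0j
        px = tpi * positions[j, 0] / lx
        py = tpi * positions[j, 1] / ly
        pz = tpi * positions[j, 2] / lz
        bx = complex(np.cos(px), np.sin(px))
        by = complex(np.cos(py), np.sin(py))
        bz = complex(np.cos(pz), np.sin(pz))
        for a in range(1, k1 + 1):
            ex[j, a] = ex[j, a - 1] * bx
        for a in range(1, k2 + 1):
            ey[j, a] = ey[j, a - 1] * by
        for a in range(1, k3 + 1):
            ez[j, a] = ez[j, a - 1] * bz

    energy = 0.0
    virial = 0.0
    forces = np.zeros((n, 3))
    eik = np.empty(n, dtype=np.complex128)
    inv4a2 = 1.0 / (4.0 * alpha * alpha)
    # half space: n1 > 0, or (n1 == 0, n2 > 0), or (n1 == n2 == 0, n3 > 0)
    for n1 in range(0, k1 + 1):
        kx = tpi * n1 / lx
        start2 = -k2 if n1 > 0 else 0
        for n2 in range(start2, k2 + 1):
            ky = tpi * n2 / ly
            if n1 == 0 and n2 == 0:
                start3 = 1
            elif n1 == 0:
                start3 = -k3 if n2 > 0 else k3 + 1  # n2<0 cannot occur here
            else:
                start3 = -k3
            for n3 in range(start3, k3 + 1):
                kz = tpi * n3 / lz
                ksq = kx * kx + ky * ky + kz * kz
                if ksq == 0.0:
                    continue
                pref = 2.0 * (tpi / volume) * np.exp(-ksq * inv4a2) / ksq
                s_re = 0.0
                s_im = 0.0
                for j in range(n):
                    e = ex[j, n1]
                    if n2 >= 0:
                        e = e * ey[j, n2]
                    else:
                        e = e * np.conj(ey[j, -n2])
                    if n3 >= 0:
                        e = e * ez[j, n3]
                    else:
                        e = e * np.conj(ez[j, -n3])
                    eik[j] = e
                    s_re += charges[j] * e.real
                    s_im += charges[j] * e.imag
                ssq = s_re * s_re + s_im * s_im
                energy += pref * ssq
                virial += pref * ssq * (1.0 - ksq / (2.0 * alpha * alpha))
                for j in range(n):
                    # Im(e^{ik·r_j} S*) = im_j·s_re − re_j·s_im
                    c = 2.0 * pref * charges[j] * (eik[j].imag * s_re - eik[j].real * s_im)
                    forces[j, 0] += c * kx
                    forces[j, 1] += c * ky
                    forces[j, 2] += c * kz
    return energy, forces, virial


@njit(cache=True, fastmath=True)
def shake_kernel(pos_new, r_old, pi, pj, inv_mi, inv_mj, d_sq, tol, max_iter):
    """SHAKE distance constraints; returns iterations used or -1 on failure."""
    nc = pi.shape[0]
    for it in range(max_iter):
        worst = 0.0
        for c in range(nc):
            i = pi[c]
            j = pj[c]
            dx = pos_new[i, 0] - pos_new[j, 0]
            dy = pos_new[i, 1] - pos_new[j, 1]
            dz = pos_new[i, 2] - pos_new[j, 2]
            diff = dx * dx + dy * dy + dz * dz - d_sq[c]
            ad = abs(diff)
            if ad > worst:
                worst = ad
            if ad > tol:
                dot = (dx * r_old[c, 0] + dy * r_old[c, 1] + dz * r_old[c, 2])
                if abs(dot) < 1e-12:  # constraint gradient degenerate
                    return -1
                g = diff / (2.0 * dot * (inv_mi[c] + inv_mj[c]))
                pos_new[i, 0] -= g * r_old[c, 0] * inv_mi[c]
                pos_new[i, 1] -= g * r_old[c, 1] * inv_mi[c]
                pos_new[i, 2] -= g * r_old[c, 2] * inv_mi[c]
                pos_new[j, 0] += g * r_old[c, 0] * inv_mj[c]
                pos_new[j, 1] += g * r_old[c, 1] * inv_mj[c]
                pos_new[j, 2] += g * r_old[c, 2] * inv_mj[c]
        if worst <= tol:
            return it
    return -1


@njit(cache=True, fastmath=True)
def rattle_kernel(positions, velocities, pi, pj, inv_mi, inv_mj, tol, max_iter):
    """RATTLE velocity projection; returns iterations used or -1 on failure."""
    nc = pi.shape[0]
    for it in range(max_iter):
        worst = 0.0
        for c in range(nc):
            i = pi[c]
            j = pj[c]
            rx = positions[i, 0] - positions[j, 0]
            ry = positions[i, 1] - positions[j, 1]
            rz = positions[i, 2] - positions[j, 2]
            r_sq = rx * rx + ry * ry + rz * rz
            vx = velocities[i, 0] - velocities[j, 0]
            vy = velocities[i, 1] - velocities[j, 1]
            vz = velocities[i, 2] - velocities[j, 2]
            dot = vx * rx + vy * ry + vz * rz
            viol = abs(dot) / np.sqrt(r_sq)
            if viol > worst:
                worst = viol
            if viol > tol:
                g = dot / (r_sq * (inv_mi[c] + inv_mj[c]))
                velocities[i, 0] -= g * rx * inv_mi[c]
                velocities[i, 1] -= g * ry * inv_mi[c]
                velocities[i, 2] -= g * rz * inv_mi[c]
                velocities[j, 0] += g * rx * inv_mj[c]
                velocities[j, 1] += g * ry * inv_mj[c]
                velocities[j, 2] += g * rz * inv_mj[c]
        if worst <= tol:
            return it
    return -1


@njit(cache=True, fastmath=True)
def _ipow(x, n):
    out = 1.0
    for _ in range(n):
        out *= x
    return out


@njit(cache=True, fastmath=True)
def pair_kernel(positions, box, ii, jj, tid, eps_t, n_t, m_t, r0_t, charges,
                cutoff, switch_width, alpha, coulomb_pref):
    """Fused Mie + real-space-Ewald pass over a pair list.

    Returns (e_mie, e_real, forces, virial, bad_pair_index).  Exponents are
    assumed integer-valued (the mixing rule rounds them).  ``bad_pair_index``
    is -1 unless two sites overlap below 1e-6 Å.
    """
    n_sites = positions.shape[0]
    forces = np.zeros((n_sites, 3))
    e_mie = 0.0
    e_real = 0.0
    virial = 0.0
    cut_sq = cutoff * cutoff
    r_on = cutoff - switch_width
    two_over_sqrt_pi = 2.0 / np.sqrt(np.pi)
    for p in range(ii.shape[0]):
        a = ii[p]
        b = jj[p]
        dx = positions[a, 0] - positions[b, 0]
        dy = positions[a, 1] - positions[b, 1]
        dz = positions[a, 2] - positions[b, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r_sq = dx * dx + dy * dy + dz * dz
        if r_sq > cut_sq:
            continue
        if r_sq < 1e-12:
            return e_mie, e_real, forces, virial, p
        r = np.sqrt(r_sq)
        fmag = 0.0
        ta = tid[a]
        tb = tid[b]
        eps = eps_t[ta, tb]
        if eps > 0.0:
            nn = int(n_t[ta, tb])
            mm = int(m_t[ta, tb])
            x = r0_t[ta, tb] / r
            xm = _ipow(x, mm)
            xn = _ipow(x, nn - mm) * xm
            pref = eps / (nn - mm)
            u = pref * (mm * xn - nn * xm)
            fm = pref * nn * mm * (xn - xm) / r
            if r > r_on:
                t = (r - r_on) / switch_width
                s = 1.0 - t * t * t * (10.0 - 15.0 * t + 6.0 * t * t)
                ds = -30.0 * t * t * (1.0 - t) * (1.0 - t) / switch_width
                fm = fm * s - u * ds
                u = u * s
            e_mie += u
            fmag += fm
        qq = charges[a] * charges[b]
        if coulomb_pref != 0.0 and qq != 0.0:
            ec = math.erfc(alpha * r)
            e_real += coulomb_pref * qq * ec / r
            fmag += coulomb_pref * qq * (
                ec / r_sq + two_over_sqrt_pi * alpha * np.exp(-alpha * alpha * r_sq) / r
            )
        if fmag != 0.0:
            virial += fmag * r
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            forces[a, 0] += fx
            forces[a, 1] += fy
            forces[a, 2] += fz
            forces[b, 0] -= fx
            forces[b, 1] -= fy
            forces[b, 2] -= fz
    return e_mie, e_real, forces, virial, -1
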