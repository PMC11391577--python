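"""Numba-compiled nonbonded inner loops.

One kernel serves both the direct O(N²) path and the Verlet-list path:
the caller supplies the pair index arrays (all i<j pairs, or the current
neighbor list with exclusions already removed).  The kernel applies the
minimum-image convention, a plain LJ cutoff with an optional energy
shift, and one of three Coulomb treatments (none / force-shifted /
Ewald real space).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_C96 = 27.0 / 4.0
_C124 = 3.0 * math.sqrt(3.0) / 2.0
_TWO_OVER_SQRTPI = 2.0 / math.sqrt(math.pi)

COUL_NONE = 0
COUL_SHIFTED = 1
COUL_EWALD_REAL = 2


@njit(cache=True)
def nb_kernel(pos, box, tidx, pi, pj, eps, sig, form, ushift, q,
              coul_pref, rc, coul_mode, alpha):
    """Accumulate nonbonded forces, energy and virial over a pair list.

    Returns (forces, energy, virial, min_r2, min_i, min_j); the minimum
    pair distance lets the caller detect overlapping beads.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    energy = 0.0
    rc2 = rc * rc
    min_r2 = 1e300
    min_i = -1
    min_j = -1
    for m in range(pi.shape[0]):
        i = pi[m]
        j = pj[m]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        ti = tidx[i]
        tj = tidx[j]
        e = eps[ti, tj]
        interacting = e > 1e-9 or (coul_mode != COUL_NONE and q[i] * q[j] != 0.0)
        if interacting and r2 < min_r2:
            min_r2 = r2
            min_i = i
            min_j = j
        if r2 > rc2:
            continue
        r = math.sqrt(r2)
        u = 0.0
        fr = 0.0  # -dU/dr
        if e > 0.0:
            s = sig[ti, tj]
            sr = s / r
            if form[ti, tj] == 0:
                sr3 = sr * sr * sr
                sr6 = sr3 * sr3
                sr9 = sr6 * sr3
                u = _C96 * e * (sr9 - sr6) - ushift[ti, tj]
                fr = _C96 * e * (9.0 * sr9 - 6.0 * sr6) / r
            else:
                sr2 = sr * sr
                sr4 = sr2 * sr2
                sr12 = sr4 * sr4 * sr4
                u = _C124 * e * (sr12 - sr4) - ushift[ti, tj]
                fr = _C124 * e * (12.0 * sr12 - 4.0 * sr4) / r
        if coul_mode != COUL_NONE:
            qq = q[i] * q[j]
            if qq != 0.0:
                pref = coul_pref * qq
                if coul_mode == COUL_SHIFTED:
                    u += pref * (1.0 / r - 1.0 / rc + (r - rc) / rc2)
                    fr += pref * (1.0 / r2 - 1.0 / rc2)
                else:
                    er = math.erfc(alpha * r)
                    u += pref * er / r
                    fr += pref * (er / r2
                                  + _TWO_OVER_SQRTPI * alpha
                                  * math.exp(-alpha * alpha * r2) / r)
        energy += u
        fx = fr * dx / r
        fy = fr * dy / r
        fz = fr * dz / r
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        virial[0, 0] += dx * fx
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 0] += dy * fx
        virial[1, 1] += dy * fy
        virial[1, 2] += dy * fz
        virial[2, 0] += dz * fx
        virial[2, 1] += dz * fy
        virial[2, 2] += dz * fz
    return forces, energy, virial, min_r2, min_i, min_j


@njit(cache=True)
def min_image_dist2(pos, box):
    """All-pairs minimum periodic distance (squared) — used by packing."""
    n = pos.shape[0]
    best = 1e300
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < best:
                best = r2
    return best
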