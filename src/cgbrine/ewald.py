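"""Classic Ewald summation for orthorhombic periodic boxes.

The pairwise real-space part (erfc-damped) lives in the nonbonded kernel;
this module provides the reciprocal-space sum, the self term and the
erf correction for bonded exclusions, each with energy, per-bead forces
and the full virial tensor.

Charges are screened by the relative permittivity through the prefactor
``C / eps_r`` passed in by the caller; all energies are kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EwaldParams:
    alpha: float  # Å⁻¹ splitting parameter
    nmax: tuple[int, int, int]  # reciprocal-space image bounds per axis

    @classmethod
    def for_box(cls, box: np.ndarray, cutoff: float, accuracy: float = 3.0) -> "EwaldParams":
        """Choose alpha so erfc(alpha*rc) ~ erfc(accuracy), and nmax so the
        reciprocal Gaussians are cut at the matching accuracy."""
        alpha = accuracy / cutoff
        nmax = tuple(int(math.ceil(accuracy * alpha * L / math.pi)) for L in box)
        return cls(alpha, nmax)


def k_vectors(box: np.ndarray, nmax: tuple[int, int, int]) -> np.ndarray:
    """All nonzero reciprocal vectors 2*pi*n/L within the index bounds."""
    nx, ny, nz = nmax
    grid = np.array(np.meshgrid(np.arange(-nx, nx + 1),
                                np.arange(-ny, ny + 1),
                                np.arange(-nz, nz + 1), indexing="ij"))
    n = grid.reshape(3, -1).T.astype(float)
    n = n[np.any(n != 0, axis=1)]
    return 2.0 * math.pi * n / np.asarray(box)


def reciprocal(positions: np.ndarray, charges: np.ndarray, box: np.ndarray,
               params: EwaldParams, prefactor: float):
    """Reciprocal-space energy, forces and virial tensor.

    ``prefactor`` is C/eps_r in kcal·Å/(mol·e²).
    """
    V = float(np.prod(box))
    k = k_vectors(box, params.nmax)
    k2 = np.einsum("ij,ij->i", k, k)
    ak = prefactor * (2.0 * math.pi / V) * np.exp(-k2 / (4.0 * params.alpha**2)) / k2
    phase = k @ positions.T  # (K, N)
    cos_p = np.cos(phase)
    sin_p = np.sin(phase)
    re_s = cos_p @ charges
    im_s = sin_p @ charges
    s2 = re_s**2 + im_s**2
    energy = float(np.sum(ak * s2))
    # F_j = sum_k 2 A_k q_j k [sin(k r_j) Re S - cos(k r_j) Im S]
    w = 2.0 * ak
    coef = (sin_p * re_s[:, None] - cos_p * im_s[:, None])  # (K, N)
    forces = np.einsum("k,ka,kj->ja", w, k, coef) * charges[:, None]
    # virial tensor
    fac = 2.0 * (1.0 / k2 + 1.0 / (4.0 * params.alpha**2))
    vir = (np.eye(3)[None, :, :] * np.ones(len(k))[:, None, None]
           - fac[:, None, None] * k[:, :, None] * k[:, None, :])
    virial = np.einsum("k,kab->ab", ak * s2, vir)
    return energy, forces, virial


def self_energy(charges: np.ndarray, params: EwaldParams, prefactor: float) -> float:
    return -prefactor * params.alpha / math.sqrt(math.pi) * float(np.sum(charges**2))


def background_energy(charges: np.ndarray, box: np.ndarray, params: EwaldParams,
                      prefactor: float) -> float:
    """Neutralizing-background term for a net-charged cell (0 for neutral)."""
    q_tot = float(np.sum(charges))
    if q_tot == 0.0:
        return 0.0
    V = float(np.prod(box))
    return -prefactor * math.pi / (2.0 * params.alpha**2 * V) * q_tot**2


def exclusion_correction(positions: np.ndarray, charges: np.ndarray,
                         box: np.ndarray, pairs: np.ndarray,
                         params: EwaldParams, prefactor: float):
    """Remove the reciprocal-space interaction of excluded (bonded) pairs.

    Subtracts erf(alpha r)/r for each excluded pair so the total Coulomb
    interaction between 1-2/1-3 neighbors is exactly zero.
    """
    n = len(positions)
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    energy = 0.0
    a = params.alpha
    for i, j in pairs:
        qq = charges[i] * charges[j]
        if qq == 0.0:
            continue
        d = positions[j] - positions[i]
        d -= box * np.round(d / box)
        r = float(np.linalg.norm(d))
        energy -= prefactor * qq * math.erf(a * r) / r
        # force on j from the subtracted term
        dudr = prefactor * qq * (2.0 * a / math.sqrt(math.pi) * math.exp(-(a * r)**2) / r
                                 - math.erf(a * r) / r**2)
        fj = dudr * d / r  # -d(-U)/dr_j
        forces[j] += fj
        forces[i] -= fj
        virial += np.outer(d, fj)
    return energy, forces, virial
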