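"""Shared fixtures: small force-field tables and toy systems."""

import numpy as np
import pytest

from cgbrine import (BeadType, ElectrostaticsSpec, ForceFieldTable, Frame,
                     PairPotential)


@pytest.fixture
def lj_ff() -> ForceFieldTable:
    """One neutral LJ 9-6 species with a short cutoff (fast tests)."""
    ff = ForceFieldTable(electrostatics=ElectrostaticsSpec(
        method="cutoff_shifted", real_space_cutoff=12.0))
    ff.add_bead(BeadType("A", 50.0, 0.0, "other"))
    ff.add_pair(PairPotential("A", "A", 0.3, 4.0, "lj9_6"))
    return ff


@pytest.fixture
def ionic_ff() -> ForceFieldTable:
    """Charged pair species (force-shifted Coulomb)."""
    ff = ForceFieldTable(electrostatics=ElectrostaticsSpec(
        method="cutoff_shifted", real_space_cutoff=10.0))
    ff.add_bead(BeadType("P", 30.0, +1.0, "cation"))
    ff.add_bead(BeadType("M", 40.0, -1.0, "anion"))
    ff.add_pair(PairPotential("P", "P", 0.3, 3.0))
    ff.add_pair(PairPotential("M", "M", 0.4, 4.0))
    ff.add_pair(PairPotential("P", "M", 0.35, 3.5))
    return ff


def grid_frame(n: int, spacing: float, box_edge: float, name: str = "A") -> Frame:
    """Deterministic non-overlapping configuration on a cubic grid."""
    side = int(np.ceil(n ** (1 / 3)))
    g = np.array(np.meshgrid(*[np.arange(side)] * 3)).reshape(3, -1).T[:n]
    pos = g * spacing + 1.0
    box = np.array([box_edge] * 3)
    return Frame(pos.astype(float), np.zeros((n, 3)), box, 0.0, [name] * n)


@pytest.fixture
def random_ionic_frame(ionic_ff):
    def make(n: int, edge: float, seed: int) -> Frame:
        rng = np.random.default_rng(seed)
        # jittered grid keeps pairs off the hard floor
        side = int(np.ceil(n ** (1 / 3)))
        g = np.array(np.meshgrid(*[np.arange(side)] * 3)).reshape(3, -1).T[:n]
        pos = g * (edge / side) + rng.random((n, 3)) * 0.3 * (edge / side)
        names = ["P" if i % 2 == 0 else "M" for i in range(n)]
        return Frame(pos, np.zeros((n, 3)), np.array([edge] * 3), 0.0, names)
    return make
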