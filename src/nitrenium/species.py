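"""Construction of nitrenium cation candidates from a neutral amine.

The nitrenium ion is generated by deleting one amine hydrogen from the
optimised neutral geometry and optimising the remaining atoms with net
charge +1 (hydrogen deletion is the portable equivalent of replacing the
atom with a non-interacting dummy).  Both amine hydrogens are tried and
the lower-energy result kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem


@dataclass
class CationCandidate:
    removed_h: int            # atom index (in the neutral) that was deleted
    numbers: list[int]
    coords: np.ndarray
    charge: int = 1


def amine_hydrogens(mol: Chem.Mol, n_index: int) -> list[int]:
    """Indices of the hydrogens on the amine nitrogen."""
    atom = mol.GetAtomWithIdx(n_index)
    return [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1]


def build_nitrenium_candidates(mol: Chem.Mol, coords: np.ndarray,
                               n_index: int) -> list[CationCandidate]:
    """One +1 start geometry per amine hydrogen of the site.

    ``coords`` is the optimised neutral geometry in the atom order of
    ``mol``.  The site must carry exactly two hydrogens (a primary amine).
    """
    h_idx = amine_hydrogens(mol, n_index)
    if len(h_idx) != 2:
        raise ValueError(
            f"amine site {n_index} has {len(h_idx)} hydrogens; expected 2")
    numbers = [a.GetAtomicNum() for a in mol.GetAtoms()]
    coords = np.asarray(coords, dtype=float)
    out = []
    for h in h_idx:
        nums = [z for i, z in enumerate(numbers) if i != h]
        geo = np.delete(coords, h, axis=0)
        out.append(CationCandidate(h, nums, geo))
    return out


def aromatic_ring_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Bonds that belong to an aromatic ring, as atom-index pairs."""
    out = []
    ri = mol.GetRingInfo()
    for bond in mol.GetBonds():
        if bond.GetIsAromatic() and ri.NumBondRings(bond.GetIdx()):
            out.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    return out


def drop_atom(pairs: list[tuple[int, int]], removed: int) -> list[tuple[int, int]]:
    """Re-index bond pairs after deletion of one atom."""
    out = []
    for i, j in pairs:
        if removed in (i, j):
            continue
        out.append((i - (i > removed), j - (j > removed)))
    return out
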