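"""Engine abstraction: geometry optimisation returning a heat of formation.

An engine takes atomic numbers, Cartesian coordinates (Angstrom) and a net
charge, performs an AM1-Hamiltonian geometry optimisation on the
closed-shell singlet surface, and reports the final heat of formation in
kcal/mol.  Engines are swappable: the built-in pure-Python AM1 engine, an
external MOPAC-dialect executable, or a scripted mock for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

# single-bond covalent radii (Angstrom), Pyykko-style consensus values for
# the elements the scorer supports
COVALENT_RADII = {1: 0.32, 6: 0.75, 7: 0.71, 8: 0.63, 9: 0.64,
                  16: 1.03, 17: 0.99, 35: 1.14}


@dataclass
class QMResult:
    """Outcome of one geometry optimisation."""
    converged: bool
    heat_of_formation: float | None = None  # kcal/mol
    coords: np.ndarray | None = None        # Angstrom
    ring_intact: bool | None = None         # set by ring-integrity check
    engine_log: str = ""


class Engine(Protocol):
    """Minimal driver interface every adapter implements."""

    fingerprint: str

    def optimize(self, numbers: Sequence[int], coords: np.ndarray,
                 charge: int = 0) -> QMResult:
        ...


def check_ring_integrity(numbers: Sequence[int],
                         ring_bonds: Sequence[tuple[int, int]],
                         coords: np.ndarray,
                         tolerance: float = 1.25) -> bool:
    """True if every aromatic-ring bond survived the optimisation.

    Connectivity is re-perceived from the optimised geometry: two atoms are
    considered bonded when their distance is below ``tolerance`` times the
    sum of their covalent radii.  A bond that belonged to an aromatic ring
    in the input topology and is no longer within bonding distance signals
    a ring opening.  Acyclic species pass vacuously.
    """
    coords = np.asarray(coords)
    for i, j in ring_bonds:
        rmax = tolerance * (COVALENT_RADII[int(numbers[i])]
                            + COVALENT_RADII[int(numbers[j])])
        if np.linalg.norm(coords[i] - coords[j]) > rmax:
            return False
    return True
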