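"""Scripted mock engine for testing the pipeline without quantum chemistry.

The mock returns heats of formation from a lookup keyed on
(molecular formula, charge); entries can also be scripted to fail
convergence or to report a distorted geometry, exercising the NaN and
ring-opening remark paths downstream.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np

from .base import QMResult

_SYMBOL = {1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 16: "S", 17: "Cl", 35: "Br"}


def formula_key(numbers: Sequence[int], charge: int) -> str:
    counts = Counter(_SYMBOL.get(int(z), str(z)) for z in numbers)
    body = "".join(f"{el}{counts[el]}" for el in sorted(counts))
    return f"{body}{charge:+d}"


class MockEngine:
    """Engine stub with scripted energies.

    ``energies`` maps formula keys (see :func:`formula_key`) to heats of
    formation in kcal/mol.  Keys listed in ``fail`` simulate SCF failure;
    keys in ``explode`` return geometries scaled far apart so that the
    ring-integrity check fails.
    """

    fingerprint = "mock-1.0"

    def __init__(self, energies=None, fail=(), explode=(), default=None):
        self.energies = dict(energies or {})
        self.fail = set(fail)
        self.explode = set(explode)
        self.default = default
        self.calls: list[str] = []

    def optimize(self, numbers: Sequence[int], coords: np.ndarray,
                 charge: int = 0) -> QMResult:
        key = formula_key(numbers, charge)
        self.calls.append(key)
        if key in self.fail:
            return QMResult(converged=False, engine_log="scripted failure")
        coords = np.asarray(coords, dtype=float)
        if key in self.explode:
            coords = coords * 4.0
        hof = self.energies.get(key, self.default)
        if hof is None:
            return QMResult(converged=False,
                            engine_log=f"no scripted energy for {key}")
        return QMResult(converged=True, heat_of_formation=float(hof),
                        coords=coords, engine_log="scripted")
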