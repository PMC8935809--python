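"""Built-in AM1 engine adapter."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..base import QMResult
from .optimizer import optimize_geometry
from .params import SUPPORTED_ELEMENTS
from .scf import UnsupportedElementError


class AM1Engine:
    """Geometry optimisation with the package's own AM1 implementation.

    ``gtol`` (eV/A) and ``maxiter`` control the Cartesian minimisation.
    """

    fingerprint = "builtin-am1-1.0"

    def __init__(self, gtol: float = 0.012, maxiter: int = 400):
        self.gtol = gtol
        self.maxiter = maxiter

    def optimize(self, numbers: Sequence[int], coords: np.ndarray,
                 charge: int = 0) -> QMResult:
        try:
            res = optimize_geometry(numbers, coords, charge=charge,
                                    gtol=self.gtol, maxiter=self.maxiter)
        except UnsupportedElementError as exc:
            return QMResult(converged=False, engine_log=str(exc))
        return QMResult(converged=res.converged,
                        heat_of_formation=res.hof,
                        coords=res.coords,
                        engine_log=res.message)

    @staticmethod
    def supports(numbers: Sequence[int]) -> bool:
        return all(int(z) in SUPPORTED_ELEMENTS for z in numbers)
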