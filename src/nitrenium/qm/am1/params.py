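"""AM1 semi-empirical parameters and derived per-element quantities.

Parameters are the published AM1 values (Dewar, Zoebisch, Healy & Stewart's
original H/C/N/O set and the later halogen and sulfur extensions).  Energies
are in eV, orbital exponents in bohr^-1, the core-repulsion alpha in 1/A and
the Gaussian core corrections (a_i, b_i, c_i) in eV*A, 1/A^2 and A.

Derived quantities (atomic electronic energy ``eisol``, multipole charge
separations ``dd``/``qq`` and Klopman-Ohno additive radii ``rho0/1/2``) are
computed from the primary parameters at import time, not tabulated, so the
table carries a single source of truth per element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

# Legacy conversion constants matching classic MOPAC builds.
BOHR = 0.529167  # A per bohr
EV = 27.21  # eV per hartree
KCAL_PER_EV = 23.061


@dataclass(frozen=True)
class ElementParams:
    symbol: str
    z: int  # atomic number
    zval: float  # core charge (valence electrons)
    nq: int  # principal quantum number of the valence shell
    uss: float
    upp: float
    zs: float
    zp: float
    betas: float
    betap: float
    alpha: float
    gss: float
    gsp: float
    gpp: float
    gp2: float
    hsp: float
    gaussians: tuple[tuple[float, float, float], ...]  # (a, b, c)
    eheat: float  # experimental atomic heat of formation, kcal/mol
    # derived, filled in __post_init__
    eisol: float = field(default=0.0, compare=False)
    dd: float = field(default=0.0, compare=False)  # sp dipole separation, bohr
    qq: float = field(default=0.0, compare=False)  # pp quadrupole separation, bohr
    rho0: float = field(default=0.0, compare=False)  # bohr
    rho1: float = field(default=0.0, compare=False)
    rho2: float = field(default=0.0, compare=False)

    @property
    def norb(self) -> int:
        return 1 if self.zp == 0.0 else 4

    def __post_init__(self):
        object.__setattr__(self, "eisol", _eisol(self))
        dd, qq = _multipole_separations(self)
        object.__setattr__(self, "dd", dd)
        object.__setattr__(self, "qq", qq)
        r0, r1, r2 = _klopman_radii(self, dd, qq)
        object.__setattr__(self, "rho0", r0)
        object.__setattr__(self, "rho1", r1)
        object.__setattr__(self, "rho2", r2)


def _p_occupations(np_elec: int) -> list[int]:
    """Hund-rule occupations of the three p orbitals."""
    occ = [0, 0, 0]
    for i in range(np_elec):
        occ[i % 3] += 1
    return sorted(occ, reverse=True)


def _eisol(p: "ElementParams") -> float:
    """Electronic energy of the neutral atom ground configuration (eV).

    Pair-energy sum over the s^ns p^np configuration with Hund-rule p
    occupation; exchange between same-spin electrons in different p
    orbitals is (gpp - gp2)/2.
    """
    ns = min(2, int(p.zval))
    np_elec = int(p.zval) - ns
    e = ns * p.uss + np_elec * p.upp
    if ns == 2:
        e += p.gss
    # s-p: Coulomb for every pair, exchange hsp for each same-spin pair.
    e += ns * np_elec * p.gsp
    if ns == 2:
        e -= np_elec * p.hsp  # each p electron has one same-spin s partner
    kpp = 0.5 * (p.gpp - p.gp2)
    occ = _p_occupations(np_elec)
    for i in range(3):
        if occ[i] == 2:
            e += p.gpp
        for j in range(i + 1, 3):
            e += occ[i] * occ[j] * p.gp2
            # same-spin cross pairs: 2 if both doubly occupied, else min(occ)
            if occ[i] and occ[j]:
                e -= kpp * (2 if occ[i] == 2 and occ[j] == 2 else 1)
    return e


def _multipole_separations(p: "ElementParams") -> tuple[float, float]:
    """Charge separations (bohr) of the sp dipole and pp quadrupole."""
    if p.zp == 0.0:
        return 0.0, 0.0
    n = p.nq
    dd = ((2 * n + 1) * (4 * p.zs * p.zp) ** (n + 0.5)
          / (p.zs + p.zp) ** (2 * n + 2)) / math.sqrt(3.0)
    qq = math.sqrt((4 * n * n + 6 * n + 2) / 20.0) / p.zp
    return dd, qq


def _klopman_radii(p: "ElementParams", dd: float, qq: float) -> tuple[float, float, float]:
    """Additive radii rho_l (bohr) matching the one-centre integrals.

    rho0 reproduces gss as the monopole self-energy; rho1 and rho2 are the
    roots of the dipole and quadrupole self-energy conditions (hsp and
    (gpp - gp2)/2 respectively).
    """
    gss_au = p.gss / EV
    rho0 = 0.5 / gss_au
    if p.zp == 0.0:
        return rho0, 0.0, 0.0

    hsp_au = p.hsp / EV

    def f1(r):
        return 0.25 * (1.0 / r - 1.0 / math.sqrt(dd * dd + r * r)) - hsp_au

    hpp_au = 0.5 * (p.gpp - p.gp2) / EV

    def f2(r):
        return (0.125 / r
                - 0.25 / math.sqrt(qq * qq + r * r)
                + 0.125 / math.sqrt(2.0 * qq * qq + r * r)) - hpp_au

    rho1 = brentq(f1, 1e-4, 50.0, xtol=1e-12)
    rho2 = brentq(f2, 1e-4, 50.0, xtol=1e-12)
    return rho0, rho1, rho2


AM1: dict[int, ElementParams] = {}


def _add(symbol, z, zval, nq, uss, upp, zs, zp, betas, betap, alpha,
         gss, gsp, gpp, gp2, hsp, gaussians, eheat):
    AM1[z] = ElementParams(symbol, z, zval, nq, uss, upp, zs, zp, betas,
                           betap, alpha, gss, gsp, gpp, gp2, hsp,
                           tuple(gaussians), eheat)


_add("H", 1, 1, 1,
     -11.396427, 0.0, 1.188078, 0.0, -6.173787, 0.0, 2.882324,
     12.848, 0.0, 0.0, 0.0, 0.0,
     [(0.122796, 5.0, 1.2), (0.005090, 5.0, 1.8), (-0.018336, 2.0, 2.1)],
     52.102)

_add("C", 6, 4, 2,
     -52.028658, -39.614239, 1.808665, 1.685116, -15.715783, -7.719283,
     2.648274,
     12.23, 11.47, 11.08, 9.84, 2.43,
     [(0.011355, 5.0, 1.6), (0.045924, 5.0, 1.85),
      (-0.020061, 5.0, 2.05), (-0.001260, 5.0, 2.65)],
     170.89)

_add("N", 7, 5, 2,
     -71.860000, -57.167581, 2.315410, 2.157940, -20.299110, -18.238666,
     2.947286,
     13.59, 12.66, 12.98, 11.59, 3.14,
     [(0.025251, 5.0, 1.5), (0.028953, 5.0, 2.1), (-0.005806, 2.0, 2.4)],
     113.00)

_add("O", 8, 6, 2,
     -97.830000, -78.262380, 3.108032, 2.524039, -29.272773, -29.272773,
     4.455371,
     15.42, 14.48, 14.52, 12.98, 3.94,
     [(0.280962, 5.0, 0.847918), (0.081430, 7.0, 1.445071)],
     59.559)

_add("F", 9, 7, 2,
     -136.105579, -104.889885, 3.770082, 2.494670, -69.590277, -27.922360,
     5.517800,
     16.92, 17.25, 16.71, 14.91, 4.83,
     [(0.242079, 4.8, 0.93), (0.003607, 4.6, 1.66)],
     18.89)

_add("S", 16, 6, 3,
     -56.694056, -48.717049, 2.366515, 1.667263, -3.920566, -7.905278,
     2.461648,
     11.786329, 8.663127, 10.039308, 7.781688, 2.532137,
     [(-0.509195, 4.593691, 0.770665), (-0.011863, 5.865731, 1.503313),
      (0.012334, 13.557336, 2.009173)],
     66.40)

_add("Cl", 17, 7, 3,
     -111.613948, -76.640107, 3.631376, 2.076799, -24.594670, -14.637216,
     2.919368,
     15.03, 13.16, 11.30, 9.97, 2.42,
     [(0.094243, 4.0, 1.3), (0.027168, 4.0, 2.1)],
     28.99)

_add("Br", 35, 7, 4,
     -104.656063, -74.930052, 3.064133, 2.038333, -19.399880, -8.957195,
     2.576546,
     15.03643948, 13.03468242, 11.27632539, 9.85442552, 2.45586832,
     [(0.066685, 4.0, 1.5), (0.025568, 4.0, 2.3)],
     26.74)


SUPPORTED_ELEMENTS = frozenset(AM1)
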