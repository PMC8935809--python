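"""Slater-orbital overlap integrals for s/p valence shells.

Overlaps are evaluated analytically in prolate-spheroidal coordinates.  For
a pair of Slater orbitals r^(n-1) exp(-zeta r) Y_lm on centres A and B the
integrand reduces to a polynomial in (xi, eta) times exp(-p xi - q eta), so
the integral is a finite sum of products A_i(p) B_j(q) of the standard
auxiliary integrals.  Orbitals are expressed in a local frame whose z axis
points from A to B; both sigma orbitals point along +z (global convention),
which introduces one sign flip for the B-centre sigma lobe.

All quantities in atomic units.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

# Gauss-Legendre rule for the B_j auxiliary integrals: exact to machine
# precision for the exponents met here (|q| < ~40).
_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)
# powers[j, k] = w_k * x_k^j for the B_j quadrature, precomputed up to j=14
_GL_POWERS = _GL_W * np.vander(_GL_X, 15, increasing=True).T

_SIGMA, _PI = 0, 1  # local |m| labels


def _a_aux(nmax: int, p: float) -> np.ndarray:
    """A_i(p) = int_1^inf x^i exp(-p x) dx for i = 0..nmax."""
    a = np.empty(nmax + 1)
    ep = math.exp(-p)
    a[0] = ep / p
    for i in range(1, nmax + 1):
        a[i] = (ep + i * a[i - 1]) / p
    return a


def _b_aux(nmax: int, q: float) -> np.ndarray:
    """B_j(q) = int_-1^1 x^j exp(-q x) dx for j = 0..nmax."""
    return _GL_POWERS[: nmax + 1] @ np.exp(-q * _GL_X)


def _poly_mul(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Product of two bivariate polynomials stored as coeff[i, j] xi^i eta^j."""
    out = np.zeros((p1.shape[0] + p2.shape[0] - 1,
                    p1.shape[1] + p2.shape[1] - 1))
    for (i, j), c in np.ndenumerate(p1):
        if c:
            out[i:i + p2.shape[0], j:j + p2.shape[1]] += c * p2
    return out


def _binom_poly(sign: float, power: int) -> np.ndarray:
    """(xi + sign*eta)^power as a coefficient array."""
    out = np.zeros((power + 1, power + 1))
    for k in range(power + 1):
        out[power - k, k] = math.comb(power, k) * sign ** k
    return out


@lru_cache(maxsize=None)
def _overlap_poly(na: int, la: int, nb: int, lb: int, m: int) -> tuple:
    """Coefficient array and angular constant for one local overlap type.

    Returns (coeffs, const) with S = const * (R/2)^(na+nb+1) * N_A N_B *
    sum_ij coeffs[i, j] A_i(p) B_j(q).
    """
    ep = na  # exponent of (xi + eta): (na-1) radial + 1 volume
    em = nb
    num = np.ones((1, 1))
    const = 1.0 / (4.0 * math.pi)
    sign = 1.0
    if m == _PI:
        # sin(theta_A) sin(theta_B) = (xi^2-1)(1-eta^2) / ((xi+eta)(xi-eta))
        ep -= 1
        em -= 1
        # (xi^2-1)(1-eta^2) = xi^2 - 1 - xi^2 eta^2 + eta^2
        t2 = np.zeros((3, 3))
        t2[2, 0], t2[0, 0], t2[2, 2], t2[0, 2] = 1.0, -1.0, -1.0, 1.0
        num = _poly_mul(num, t2)
        const *= 3.0  # two sqrt(3/4pi)*... normalisations -> 3/(4pi); pi from phi
        phi = math.pi
    else:
        phi = 2.0 * math.pi
        if la == 1:  # sigma on A: cos(theta_A) = (1+xi eta)/(xi+eta)
            ep -= 1
            t = np.zeros((2, 2))
            t[0, 0], t[1, 1] = 1.0, 1.0
            num = _poly_mul(num, t)
            const *= math.sqrt(3.0)
        if lb == 1:  # sigma on B pointing along global +z: -(1-xi eta)/(xi-eta)
            em -= 1
            t = np.zeros((2, 2))
            t[0, 0], t[1, 1] = 1.0, -1.0
            num = _poly_mul(num, t)
            const *= math.sqrt(3.0)
            sign = -1.0
    num = _poly_mul(num, _binom_poly(1.0, ep))
    num = _poly_mul(num, _binom_poly(-1.0, em))
    return num, const * phi * sign


def _radial_norm(n: int, zeta: float) -> float:
    return (2.0 * zeta) ** (n + 0.5) / math.sqrt(math.factorial(2 * n))


def overlap_local(na: int, la: int, za: float, nb: int, lb: int, zb: float,
                  r: float, m: int) -> float:
    """Overlap of two local-frame STOs separated by r (bohr).

    la/lb in {0, 1}; m is the shared |m| (_SIGMA or _PI; p orbitals only
    for m = _PI).
    """
    coeffs, const = _overlap_poly(na, la, nb, lb, m)
    p = 0.5 * r * (za + zb)
    q = 0.5 * r * (za - zb)
    nmax = coeffs.shape[0] - 1
    mmax = coeffs.shape[1] - 1
    av = _a_aux(nmax, p)
    bv = _b_aux(mmax, q)
    s = float(av[: nmax + 1] @ coeffs @ bv[: mmax + 1])
    pref = (_radial_norm(na, za) * _radial_norm(nb, zb)
            * (0.5 * r) ** (na + nb + 1))
    return const * pref * s


def diatomic_overlap(pa, pb, r: float) -> np.ndarray:
    """Local-frame overlap block between the valence shells of two atoms.

    ``pa``/``pb`` are ElementParams; returns an (norb_a, norb_b) array in
    the local orbital order (s, p_sigma, p_pi, p_pi').
    """
    sa = np.zeros((pa.norb, pb.norb))
    sa[0, 0] = overlap_local(pa.nq, 0, pa.zs, pb.nq, 0, pb.zs, r, _SIGMA)
    if pb.norb > 1:
        sa[0, 1] = overlap_local(pa.nq, 0, pa.zs, pb.nq, 1, pb.zp, r, _SIGMA)
    if pa.norb > 1:
        sa[1, 0] = overlap_local(pa.nq, 1, pa.zp, pb.nq, 0, pb.zs, r, _SIGMA)
    if pa.norb > 1 and pb.norb > 1:
        sa[1, 1] = overlap_local(pa.nq, 1, pa.zp, pb.nq, 1, pb.zp, r, _SIGMA)
        spi = overlap_local(pa.nq, 1, pa.zp, pb.nq, 1, pb.zp, r, _PI)
        sa[2, 2] = spi
        sa[3, 3] = spi
    return sa
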