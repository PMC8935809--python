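"""NDDO two-centre repulsion integrals via the point-charge multipole model.

Every charge distribution mu*nu within one valence shell is decomposed into
point-charge multipoles (monopole, dipole, linear and square quadrupoles)
whose components carry Klopman-Ohno additive radii rho_l; the interaction
between two distributions is the damped Coulomb sum over their point
charges.  Local-frame z points from atom A to atom B.

For each ordered element pair the charge-pair lists are flattened once into
arrays (coefficient, axial offset, transverse-plus-damping term), making a
full 4x4x4x4 local integral tensor a single vectorised evaluation per
geometry.  The electron-core attractions and the core-core repulsion reuse
the same (ss|ss)-type integrals.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .params import AM1, EV

_X, _Y, _Z = 0, 1, 2


def _components(p):
    """Multipole components of the 10 unique distributions of one shell.

    Returns dict {(mu, nu): [(l, [(q, xyz), ...]), ...]} with orbital
    indices 0=s, 1=px, 2=py, 3=pz in the local frame.
    """
    comps = {(0, 0): [(0, [(1.0, (0.0, 0.0, 0.0))])]}
    if p.norb == 1:
        return comps
    d1, d2 = p.dd, p.qq
    for ax in (_X, _Y, _Z):
        e = [0.0, 0.0, 0.0]
        e[ax] = d1
        comps[(0, ax + 1)] = [(1, [(0.5, tuple(e)), (-0.5, tuple(-v for v in e))])]
        e2 = [0.0, 0.0, 0.0]
        e2[ax] = 2.0 * d2
        comps[(ax + 1, ax + 1)] = [
            (0, [(1.0, (0.0, 0.0, 0.0))]),
            (2, [(0.25, tuple(e2)), (0.25, tuple(-v for v in e2)),
                 (-0.5, (0.0, 0.0, 0.0))]),
        ]
    for a, b in ((_X, _Y), (_X, _Z), (_Y, _Z)):
        pts = []
        for sa in (1.0, -1.0):
            for sb in (1.0, -1.0):
                e = [0.0, 0.0, 0.0]
                e[a] = sa * d2
                e[b] = sb * d2
                pts.append((0.25 * sa * sb, tuple(e)))
        comps[(a + 1, b + 1)] = [(2, pts)]
    return comps


@lru_cache(maxsize=None)
def _pair_terms(za: int, zb: int):
    """Flattened interaction terms for an ordered element pair.

    Returns (coef, zoff, trans2, idx, norba, norbb): the local integral
    g[i] = sum over terms t with idx[t] == i of
    coef[t] / sqrt((R + zoff[t])^2 + trans2[t]),   R in bohr, g in hartree.
    """
    pa, pb = AM1[za], AM1[zb]
    ca, cb = _components(pa), _components(pb)
    rhoa = {0: pa.rho0, 1: pa.rho1, 2: pa.rho2}
    rhob = {0: pb.rho0, 1: pb.rho1, 2: pb.rho2}
    coef, zoff, trans2, idx = [], [], [], []
    index_of = {}
    for (mn, dista) in ca.items():
        for (ls, distb) in cb.items():
            slot = len(index_of)
            index_of[(mn, ls)] = slot
            for la, pts_a in dista:
                for lb, pts_b in distb:
                    damp2 = (rhoa[la] + rhob[lb]) ** 2
                    for qa, ra in pts_a:
                        for qb, rb in pts_b:
                            coef.append(qa * qb)
                            zoff.append(rb[2] - ra[2])
                            trans2.append((ra[0] - rb[0]) ** 2
                                          + (ra[1] - rb[1]) ** 2 + damp2)
                            idx.append(slot)
    na, nb = pa.norb, pb.norb
    # scatter indices: each unique local integral fills its 4 symmetric
    # positions of the flattened (na, na, nb, nb) tensor
    slots, flat_pos = [], []
    for ((m, n), (l, s)), slot in index_of.items():
        for mm, nn in {(m, n), (n, m)}:
            for ll, ss in {(l, s), (s, l)}:
                slots.append(slot)
                flat_pos.append(((mm * na) + nn) * nb * nb + ll * nb + ss)
    return (np.array(coef), np.array(zoff), np.array(trans2),
            np.array(idx), len(index_of), np.array(slots),
            np.array(flat_pos), na, nb)


def local_eri(za: int, zb: int, r_bohr: float) -> np.ndarray:
    """Local-frame two-centre ERI tensor (norb_a, norb_a, norb_b, norb_b), eV."""
    coef, zoff, trans2, idx, nslot, slots, flat_pos, na, nb = _pair_terms(za, zb)
    vals = coef / np.sqrt((r_bohr + zoff) ** 2 + trans2)
    g = np.bincount(idx, weights=vals, minlength=nslot) * EV
    out = np.zeros(na * na * nb * nb)
    out[flat_pos] = g[slots]
    return out.reshape(na, na, nb, nb)


def one_centre_eri(z: int) -> np.ndarray:
    """One-centre ERI tensor (norb^4), eV; orbital order s, px, py, pz."""
    p = AM1[z]
    n = p.norb
    g = np.zeros((n, n, n, n))
    g[0, 0, 0, 0] = p.gss
    if n > 1:
        hpp = 0.5 * (p.gpp - p.gp2)
        for i in range(1, 4):
            g[0, 0, i, i] = g[i, i, 0, 0] = p.gsp
            g[i, i, i, i] = p.gpp
            g[0, i, 0, i] = g[i, 0, 0, i] = g[0, i, i, 0] = g[i, 0, i, 0] = p.hsp
            for j in range(1, 4):
                if i != j:
                    g[i, i, j, j] = p.gp2
                    g[i, j, i, j] = g[i, j, j, i] = hpp
    return g


def core_core(za: int, zb: int, r_ang: float, gss_ss: float) -> float:
    """Core-core repulsion (eV) for one atom pair.

    ``gss_ss`` is the (s_A s_A | s_B s_B) integral in eV.  The classic
    N-H / O-H exception multiplies the heavy-atom exponential by R, and the
    AM1 Gaussian corrections are added on top.
    """
    pa, pb = AM1[za], AM1[zb]
    ea = np.exp(-pa.alpha * r_ang)
    eb = np.exp(-pb.alpha * r_ang)
    if za == 1 and zb in (7, 8):
        eb *= r_ang
    elif zb == 1 and za in (7, 8):
        ea *= r_ang
    enuc = pa.zval * pb.zval * gss_ss * (1.0 + ea + eb)
    gauss = 0.0
    for a, b, c in pa.gaussians:
        gauss += a * np.exp(-b * (r_ang - c) ** 2)
    for a, b, c in pb.gaussians:
        gauss += a * np.exp(-b * (r_ang - c) ** 2)
    enuc += pa.zval * pb.zval / r_ang * gauss
    return float(enuc)
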