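"""Restricted Hartree-Fock SCF over the AM1 Hamiltonian.

Works in the NDDO orthogonalised valence basis (the overlap enters only the
resonance term of the core Hamiltonian).  Geometry in Angstrom, energies in
eV unless noted; heats of formation in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_EYE1 = np.eye(1)

from .params import AM1, BOHR, EV, KCAL_PER_EV, SUPPORTED_ELEMENTS
from .multipole import core_core, local_eri, one_centre_eri
from .slater import diatomic_overlap


class UnsupportedElementError(ValueError):
    pass


def _cross(a, b):
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _local_axes(u: np.ndarray) -> np.ndarray:
    """Orthogonal matrix M with columns (x_loc, y_loc, z_loc=u)."""
    ref = np.zeros(3)
    ref[np.argmin(np.abs(u))] = 1.0
    v1 = _cross(u, ref)
    v1 /= math.sqrt(v1 @ v1)
    v2 = _cross(u, v1)
    return np.column_stack([v1, v2, u])


@dataclass
class PairIntegrals:
    ia: int
    ib: int
    s_block: np.ndarray     # resonance-scaled overlap: 0.5*(beta_mu+beta_nu)*S
    g: np.ndarray           # two-centre ERIs, global frame (eV)
    enuc: float


class AM1System:
    """Integral and SCF driver for one molecule (fixed atom list)."""

    def __init__(self, numbers):
        numbers = [int(z) for z in numbers]
        bad = {z for z in numbers if z not in SUPPORTED_ELEMENTS}
        if bad:
            raise UnsupportedElementError(
                f"no AM1 parameters for atomic numbers {sorted(bad)}")
        self.numbers = numbers
        self.params = [AM1[z] for z in numbers]
        offs = []
        n = 0
        for p in self.params:
            offs.append(n)
            n += p.norb
        self.offsets = offs
        self.norb = n
        self.g_onec = [one_centre_eri(z) for z in numbers]
        self.eisol_sum = sum(p.eisol for p in self.params)
        self.eheat_sum = sum(p.eheat for p in self.params)
        self.zval = np.array([p.zval for p in self.params])
        self._beta = []
        for p in self.params:
            b = [p.betas] + [p.betap] * (p.norb - 1)
            self._beta.append(np.array(b))
        self._udiag = np.concatenate(
            [[p.uss] + [p.upp] * (p.norb - 1) for p in self.params])

    # ---- integrals ------------------------------------------------------
    def _pair(self, ia: int, ib: int, vec: np.ndarray) -> PairIntegrals:
        """Integrals for one atom pair; ``vec`` points from A to B (Angstrom)."""
        pa, pb = self.params[ia], self.params[ib]
        r = float(np.linalg.norm(vec))
        u = vec / r
        m = _local_axes(u)
        s_loc = diatomic_overlap(pa, pb, r / BOHR)
        # reorder local (s, psig, ppi, ppi') -> (s, px, py, pz=sigma)
        na, nb = pa.norb, pb.norb
        sl = np.zeros((na, nb))
        sl[0, 0] = s_loc[0, 0]
        if nb > 1:
            sl[0, 3] = s_loc[0, 1]
        if na > 1:
            sl[3, 0] = s_loc[1, 0]
        if na > 1 and nb > 1:
            sl[3, 3] = s_loc[1, 1]
            sl[1, 1] = s_loc[2, 2]
            sl[2, 2] = s_loc[3, 3]
        rot = np.zeros((4, 4))
        rot[0, 0] = 1.0
        rot[1:, 1:] = m
        oa = _EYE1 if na == 1 else rot
        ob = _EYE1 if nb == 1 else rot
        s_glob = oa @ sl @ ob.T
        g_loc = local_eri(pa.z, pb.z, r / BOHR)
        # rotate (ab|cd) -> global frame via sequential small matmuls
        g = np.tensordot(oa, g_loc, (1, 0))          # m,b,c,d
        g = np.tensordot(oa, g, (1, 1))              # n,m,c,d
        g = np.tensordot(g, ob, (3, 1))              # n,m,c,s
        g = np.tensordot(g, ob, (2, 1))              # n,m,s,l
        g_glob = g.transpose(1, 0, 3, 2)             # m,n,l,s
        enuc = core_core(pa.z, pb.z, r, float(g_glob[0, 0, 0, 0]))
        sres = 0.5 * (self._beta[ia][:, None] + self._beta[ib][None, :]) * s_glob
        return PairIntegrals(ia, ib, sres, g_glob, enuc)

    def build(self, coords: np.ndarray):
        """Core Hamiltonian, pair ERI list and nuclear repulsion."""
        coords = np.asarray(coords, dtype=float)
        n = self.norb
        h = np.zeros((n, n))
        np.fill_diagonal(h, self._udiag)
        pairs = []
        enuc = 0.0
        for ia in range(len(self.numbers)):
            for ib in range(ia + 1, len(self.numbers)):
                pr = self._pair(ia, ib, coords[ib] - coords[ia])
                pairs.append(pr)
                enuc += pr.enuc
                a0, b0 = self.offsets[ia], self.offsets[ib]
                na, nb = self.params[ia].norb, self.params[ib].norb
                h[a0:a0 + na, b0:b0 + nb] += pr.s_block
                h[b0:b0 + nb, a0:a0 + na] += pr.s_block.T
                # electron-core attractions
                h[a0:a0 + na, a0:a0 + na] -= self.params[ib].zval * pr.g[:, :, 0, 0]
                h[b0:b0 + nb, b0:b0 + nb] -= self.params[ia].zval * pr.g[0, 0, :, :]
        return h, pairs, enuc

    # ---- Fock and SCF ---------------------------------------------------
    def _fock(self, h, pairs, p_mat):
        f = h.copy()
        for ia, g in enumerate(self.g_onec):
            a0 = self.offsets[ia]
            na = self.params[ia].norb
            pa = p_mat[a0:a0 + na, a0:a0 + na]
            coul = (g.reshape(na * na, na * na) @ pa.ravel()).reshape(na, na)
            exch = (g.transpose(0, 2, 1, 3).reshape(na * na, na * na)
                    @ pa.ravel()).reshape(na, na)
            f[a0:a0 + na, a0:a0 + na] += coul - 0.5 * exch
        for pr in pairs:
            a0, b0 = self.offsets[pr.ia], self.offsets[pr.ib]
            na, nb = self.params[pr.ia].norb, self.params[pr.ib].norb
            paa = p_mat[a0:a0 + na, a0:a0 + na]
            pbb = p_mat[b0:b0 + nb, b0:b0 + nb]
            pab = p_mat[a0:a0 + na, b0:b0 + nb]
            gmat = pr.g.reshape(na * na, nb * nb)
            f[a0:a0 + na, a0:a0 + na] += (gmat @ pbb.ravel()).reshape(na, na)
            f[b0:b0 + nb, b0:b0 + nb] += (paa.ravel() @ gmat).reshape(nb, nb)
            # exchange over the AB block: (mu lambda | nu sigma)
            gx = pr.g.transpose(0, 2, 1, 3).reshape(na * nb, na * nb)
            x = -0.5 * (gx @ pab.ravel()).reshape(na, nb)
            f[a0:a0 + na, b0:b0 + nb] += x
            f[b0:b0 + nb, a0:a0 + na] += x.T
        return f

    def guess_density(self, charge: int) -> np.ndarray:
        nelec = self.zval.sum() - charge
        diag = np.concatenate([
            np.full(p.norb, p.zval / p.norb) for p in self.params])
        diag *= nelec / diag.sum()
        return np.diag(diag)

    def scf(self, coords, charge=0, p0=None, max_iter=200, tol=1e-8):
        """Converge the closed-shell SCF; returns (result dict)."""
        h, pairs, enuc = self.build(coords)
        nelec = int(round(self.zval.sum())) - charge
        if nelec % 2:
            raise ValueError("odd electron count; only closed shells supported")
        nocc = nelec // 2
        p_mat = self.guess_density(charge) if p0 is None else p0.copy()
        e_old = None
        diis_f, diis_e = [], []
        converged = False
        e_elec = 0.0
        for it in range(max_iter):
            f = self._fock(h, pairs, p_mat)
            e_elec = 0.5 * np.sum(p_mat * (h + f))
            err = f @ p_mat - p_mat @ f
            err_norm = np.max(np.abs(err))
            if e_old is not None and abs(e_elec - e_old) < tol and err_norm < 1e-5:
                converged = True
                break
            e_old = e_elec
            # DIIS extrapolation
            diis_f.append(f)
            diis_e.append(err)
            if len(diis_f) > 8:
                diis_f.pop(0)
                diis_e.pop(0)
            if len(diis_f) > 1:
                k = len(diis_f)
                b = -np.ones((k + 1, k + 1))
                b[k, k] = 0.0
                for i in range(k):
                    for j in range(k):
                        b[i, j] = np.sum(diis_e[i] * diis_e[j])
                rhs = np.zeros(k + 1)
                rhs[k] = -1.0
                try:
                    c = np.linalg.solve(b, rhs)[:k]
                    f = sum(ci * fi for ci, fi in zip(c, diis_f))
                except np.linalg.LinAlgError:
                    pass
            _, vecs = np.linalg.eigh(f)
            c_occ = vecs[:, :nocc]
            p_new = 2.0 * c_occ @ c_occ.T
            if it < 2 and len(diis_f) < 2:
                p_new = 0.5 * (p_new + p_mat)  # light damping at start
            p_mat = p_new
        e_total = e_elec + enuc
        hof = (e_total - self.eisol_sum) * KCAL_PER_EV + self.eheat_sum
        return {
            "converged": converged,
            "iterations": it + 1,
            "e_elec": e_elec,
            "e_nuc": enuc,
            "e_total": e_total,
            "hof": hof,
            "density": p_mat,
        }

    # ---- frozen-density energy decomposition (for gradients) -----------
    def pair_energy(self, ia, ib, vec, paa, pbb, pab) -> float:
        """Geometry-dependent energy of one atom pair at frozen density (eV)."""
        pr = self._pair(ia, ib, vec)
        na = paa.shape[0]
        nb = pbb.shape[0]
        e = pr.enuc
        e += 2.0 * float(np.sum(pab * pr.s_block))
        e -= self.params[ib].zval * float(np.sum(paa * pr.g[:, :, 0, 0]))
        e -= self.params[ia].zval * float(np.sum(pbb * pr.g[0, 0, :, :]))
        gmat = pr.g.reshape(na * na, nb * nb)
        e += float(paa.ravel() @ gmat @ pbb.ravel())
        gx = pr.g.transpose(0, 2, 1, 3).reshape(na * nb, na * nb)
        v = pab.ravel()
        e -= 0.5 * float(v @ gx @ v)
        return e

    def gradient(self, coords, p_mat, step=2e-4) -> np.ndarray:
        """dE/dR (eV/Angstrom) at frozen SCF density, pairwise central FD."""
        coords = np.asarray(coords, dtype=float)
        nat = len(self.numbers)
        grad = np.zeros((nat, 3))
        for ia in range(nat):
            a0 = self.offsets[ia]
            na = self.params[ia].norb
            for ib in range(ia + 1, nat):
                b0 = self.offsets[ib]
                nb = self.params[ib].norb
                paa = p_mat[a0:a0 + na, a0:a0 + na]
                pbb = p_mat[b0:b0 + nb, b0:b0 + nb]
                pab = p_mat[a0:a0 + na, b0:b0 + nb]
                vec = coords[ib] - coords[ia]
                for k in range(3):
                    dv = np.zeros(3)
                    dv[k] = step
                    ep = self.pair_energy(ia, ib, vec + dv, paa, pbb, pab)
                    em = self.pair_energy(ia, ib, vec - dv, paa, pbb, pab)
                    d = (ep - em) / (2.0 * step)
                    grad[ib, k] += d
                    grad[ia, k] -= d
        return grad
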