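"""Force-field conformer enumeration for the neutral amine.

Stochastic distance-geometry embedding followed by MMFF94 minimisation,
duplicate removal at a heavy-atom RMSD threshold and an energy window
above the ensemble minimum.  The lowest-energy member seeds the AM1
refinement; the ensemble (not just the minimum) can seed the cation search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign

from .chem_io import MoleculeRecord
from .config import ScoreConfig


class EmbeddingError(RuntimeError):
    """3D construction failed; maps to the NaN remark downstream."""


@dataclass
class Conformer:
    coords: np.ndarray   # (natoms, 3) Angstrom, hydrogens included
    energy: float        # force-field energy, kcal/mol


@dataclass
class ConformerEnsemble:
    parent: MoleculeRecord
    conformers: list[Conformer]
    window: float

    def __len__(self):
        return len(self.conformers)

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])


def _n_trials(mol: Chem.Mol, config: ScoreConfig) -> int:
    from rdkit.Chem import rdMolDescriptors
    nrot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    n = config.min_trials + config.trials_per_rotatable * nrot
    return int(min(config.max_trials, max(config.min_trials, n)))


def enumerate_conformers(record: MoleculeRecord,
                         config: ScoreConfig | None = None,
                         seed: int | None = None) -> ConformerEnsemble:
    """Embed, minimise and prune conformers of the (neutral) molecule.

    Returns members sorted by force-field energy ascending, all within
    ``config.window`` kcal/mol of the minimum, no two closer than
    ``config.rmsd_threshold`` heavy-atom RMSD.  Same seed, same ensemble.
    """
    config = config or ScoreConfig()
    if seed is None:
        seed = config.seed
    if record.mol is None:
        raise EmbeddingError(f"record {record.id} has no structure")
    mol = Chem.Mol(record.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    params.pruneRmsThresh = -1.0
    params.useRandomCoords = False
    n_trials = _n_trials(mol, config)
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_trials,
                                          params=params)
    if len(conf_ids) == 0:
        # retry once with random coordinates before giving up
        params.useRandomCoords = True
        conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_trials,
                                              params=params)
    if len(conf_ids) == 0:
        raise EmbeddingError(f"3D construction failed for {record.id}")
    energies = _minimise(mol)
    order = sorted(range(len(energies)), key=lambda i: energies[i])
    emin = energies[order[0]]
    heavy = Chem.RemoveHs(mol)
    kept: list[int] = []
    for i in order:
        if energies[i] - emin > config.window:
            break
        if all(_heavy_rmsd(heavy, conf_ids[i], conf_ids[j])
               > config.rmsd_threshold for j in kept):
            kept.append(i)
    members = [
        Conformer(np.array(mol.GetConformer(conf_ids[i]).GetPositions()),
                  energies[i])
        for i in kept
    ]
    return ConformerEnsemble(record, members, config.window)


def _minimise(mol: Chem.Mol) -> list[float]:
    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=2000)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=2000)
    return [e for (_code, e) in results]


def _heavy_rmsd(heavy_mol: Chem.Mol, cid_a: int, cid_b: int) -> float:
    return rdMolAlign.GetBestRMS(heavy_mol, heavy_mol, prbId=cid_a,
                                 refId=cid_b)


def select_lowest(ensemble: ConformerEnsemble) -> Conformer:
    """Member with minimal energy; ties go to the first generated."""
    if not ensemble.conformers:
        raise ValueError("empty ensemble")
    best = ensemble.conformers[0]
    for c in ensemble.conformers[1:]:
        if c.energy < best.energy - 1e-12:
            best = c
    return best
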