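"""Dataset-eligibility criteria and aromatic-amine site location.

The scorer's applicability domain is defined by six structural criteria:
(i) no formal charge, (ii) molecular weight below 500 Da, (iii) at most
one stereocentre, (iv) fewer than 10 rotatable bonds, (v) exactly one
primary aromatic amine, (vi) no aromatic nitro group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem_io import MoleculeRecord

CRITERIA = ("i", "ii", "iii", "iv", "v", "vi")

CRITERION_TEXT = {
    "i": "no formal charge",
    "ii": "molecular weight < 500 Da",
    "iii": "maximum one stereocenter",
    "iv": "< 10 rotatable bonds",
    "v": "only one aromatic amine functionality",
    "vi": "no aromatic nitro groups",
}

# trivalent uncharged N with two hydrogens; aromatic-carbon attachment is
# verified on the matched neighbourhood
_AMINE_QUERY = Chem.MolFromSmarts("[NX3;H2;+0]")
_NITRO_QUERY = Chem.MolFromSmarts("[$([NX3+](=O)[O-]),$([NX3](=O)=O)]")


@dataclass
class EligibilityResult:
    eligible: bool
    failed_criteria: tuple[str, ...]
    amine_sites: list[tuple[int, int]] = field(default_factory=list)
    mw: float = 0.0
    n_rotatable: int = 0
    n_stereocenters: int = 0
    net_formal_charge: int = 0


def find_primary_aromatic_amines(mol: Chem.Mol) -> list[tuple[int, int]]:
    """(nitrogen index, attached aromatic carbon index) for each NH2-c site.

    A site is a trivalent uncharged nitrogen bearing exactly two hydrogens
    whose single heavy neighbour is an aromatic carbon.
    """
    sites = []
    for (n_idx,) in mol.GetSubstructMatches(_AMINE_QUERY):
        atom = mol.GetAtomWithIdx(n_idx)
        heavy = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1]
        if len(heavy) == 1 and heavy[0].GetIsAromatic() \
                and heavy[0].GetAtomicNum() == 6:
            sites.append((n_idx, heavy[0].GetIdx()))
    return sites


_AMIDE_QUERY = Chem.MolFromSmarts("[CX3](=O)[NX3]")


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Single non-ring bonds between non-terminal heavy atoms, amide C-N
    excluded."""
    amide_bonds = set()
    for c_idx, _o, n_idx in mol.GetSubstructMatches(_AMIDE_QUERY):
        amide_bonds.add(frozenset((c_idx, n_idx)))
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        if frozenset((a.GetIdx(), b.GetIdx())) in amide_bonds:
            continue
        heavy_deg = [sum(nb.GetAtomicNum() > 1 for nb in at.GetNeighbors())
                     for at in (a, b)]
        if min(heavy_deg) >= 2:
            n += 1
    return n


def _has_aromatic_nitro(mol: Chem.Mol) -> bool:
    for (n_idx,) in mol.GetSubstructMatches(_NITRO_QUERY):
        atom = mol.GetAtomWithIdx(n_idx)
        if any(nb.GetIsAromatic() for nb in atom.GetNeighbors()
               if nb.GetAtomicNum() != 8):
            return True
    return False


def check_eligibility(record: MoleculeRecord) -> EligibilityResult:
    """Evaluate all six criteria independently; every failure is reported."""
    mol = record.mol
    if mol is None:
        raise ValueError(f"record {record.id} has no parsed structure")
    mw = Descriptors.MolWt(mol)
    n_rot = count_rotatable_bonds(mol)
    stereo = Chem.FindMolChiralCenters(mol, includeUnassigned=True,
                                       useLegacyImplementation=False)
    charge = Chem.GetFormalCharge(mol)
    sites = find_primary_aromatic_amines(mol)
    failed = []
    if charge != 0:
        failed.append("i")
    if not mw < 500.0:
        failed.append("ii")
    if len(stereo) > 1:
        failed.append("iii")
    if not n_rot < 10:
        failed.append("iv")
    if len(sites) != 1:
        failed.append("v")
    if _has_aromatic_nitro(mol):
        failed.append("vi")
    return EligibilityResult(
        eligible=not failed,
        failed_criteria=tuple(failed),
        amine_sites=sites,
        mw=mw,
        n_rotatable=n_rot,
        n_stereocenters=len(stereo),
        net_formal_charge=charge,
    )
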