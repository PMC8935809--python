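"""Structure input, normalisation and CSV report output.

Input formats are SMILES lists (one record per line, optional
whitespace-separated identifier) and SD files (V2000).  Salts and mixtures
are reduced to their largest organic fragment before any downstream check,
so e.g. aniline hydrochloride scores as aniline.  The report is a CSV with
a closed remark vocabulary so downstream tools can filter mechanically.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

REMARK_NONE = ""
REMARK_NAN = "NaN"
REMARK_RING_OPENING = "aromatic ring opening"
REMARK_NO_AMINE = "no aromatic amine"
REMARK_PARSE_ERROR = "parse error"
REMARK_INELIGIBLE_PREFIX = "ineligible:"

#: every remark the report may carry (ineligible remarks carry a criterion
#: suffix, e.g. "ineligible:vi")
CLOSED_REMARKS = (REMARK_NONE, REMARK_NAN, REMARK_RING_OPENING,
                  REMARK_NO_AMINE, REMARK_PARSE_ERROR)

PRED_MUTAGENIC = "mutagenic"
PRED_NONMUTAGENIC = "nonmutagenic"
PRED_INCONCLUSIVE = "inconclusive"


@dataclass
class MoleculeRecord:
    """One parsed input structure."""
    id: str
    mol: Chem.Mol | None     # with explicit hydrogens; None on parse failure
    source: str              # "smiles" | "sdf"
    name: str = ""
    error: str = ""          # parse-stage remark, empty when mol is valid

    @property
    def ok(self) -> bool:
        return self.mol is not None and not self.error


@dataclass
class ReportRow:
    id: str
    ddE: float | None
    prediction: str
    remark: str
    provenance: dict = field(default_factory=dict)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment, preferring organic (carbon-bearing) ones."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol

    def key(f):
        has_c = any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        return (has_c, f.GetNumHeavyAtoms())

    return max(frags, key=key)


def normalize_mol(mol: Chem.Mol) -> Chem.Mol:
    """Salt-strip, sanitise, perceive aromaticity and add explicit H."""
    mol = _largest_fragment(mol)
    Chem.SanitizeMol(mol)
    mol = Chem.AddHs(mol)
    return mol


def _record_from_mol(mol, rid, source, name=""):
    if mol is None:
        return MoleculeRecord(rid, None, source, name,
                              error=REMARK_PARSE_ERROR)
    try:
        mol = normalize_mol(mol)
    except Exception:
        return MoleculeRecord(rid, None, source, name,
                              error=REMARK_PARSE_ERROR)
    return MoleculeRecord(rid, mol, source, name)


def parse_smiles_string(smiles: str, rid: str, name: str = "") -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    return _record_from_mol(mol, rid, "smiles", name)


def parse_structures(path: str | Path, fmt: str) -> list[MoleculeRecord]:
    """Read a SMILES list or SD file into molecule records.

    Malformed entries produce records carrying a parse-error remark; the
    run never aborts on a single bad structure.  Identifiers default to
    the 1-based position in the file and must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt not in ("smiles", "sdf"):
        raise ValueError(f"unsupported format '{fmt}'")
    records: list[MoleculeRecord] = []
    if fmt == "smiles":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                rid = parts[1].strip() if len(parts) > 1 else str(i)
                records.append(parse_smiles_string(smiles, rid))
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False,
                                      sanitize=False)
        for i, mol in enumerate(supplier, start=1):
            rid = str(i)
            name = ""
            if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name"):
                name = mol.GetProp("_Name")
                rid = name
            records.append(_record_from_mol(mol, rid, "sdf", name))
    if not records:
        log.warning("no records parsed from %s", path)
    seen: dict[str, int] = {}
    for rec in records:
        n = seen.get(rec.id, 0)
        seen[rec.id] = n + 1
        if n:
            rec.id = f"{rec.id}_{n + 1}"
    return records


def write_report(rows: list[ReportRow], path: str | Path) -> None:
    """Write the prediction report (ddE to one decimal, remark always present)."""
    if not rows:
        raise ValueError("no rows to write")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "ddE_kcal_per_mol", "prediction", "remark"])
        for row in rows:
            dde = "" if row.ddE is None else f"{row.ddE:.1f}"
            writer.writerow([row.id, dde, row.prediction, row.remark])


def read_labeled_csv(path: str | Path) -> list[dict]:
    """Benchmark input: columns id, smiles, ames, optional ddE."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            if "ddE" in row and row["ddE"] not in (None, ""):
                row["ddE"] = float(row["ddE"])
            out.append(row)
    return out
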