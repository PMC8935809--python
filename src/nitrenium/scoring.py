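"""ddE scoring against the aniline reference and classification.

The score of a primary aromatic amine ArNH2 is

    ddE = dE(ArNH+) + dE(PhNH2) - dE(ArNH2) - dE(PhNH+)   [kcal/mol]

with every dE an AM1 heat of formation of an optimised structure.  By
construction aniline scores exactly 0; a negative ddE (nitrenium more
stabilised than aniline's) predicts a mutagen, a positive one a
nonmutagen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import species
from .chem_io import (MoleculeRecord, ReportRow, parse_smiles_string,
                      PRED_INCONCLUSIVE, PRED_MUTAGENIC, PRED_NONMUTAGENIC,
                      REMARK_INELIGIBLE_PREFIX, REMARK_NAN, REMARK_NO_AMINE,
                      REMARK_RING_OPENING)
from .config import ScoreConfig, make_engine
from .conformers import EmbeddingError, enumerate_conformers
from .eligibility import check_eligibility, find_primary_aromatic_amines
from .qm.base import Engine, check_ring_integrity

log = logging.getLogger(__name__)

ANILINE_SMILES = "Nc1ccccc1"


@dataclass
class ReferenceEnergies:
    """Aniline neutral/nitrenium pair defining the zero of the ddE scale."""
    e_neutral: float      # kcal/mol
    e_cation: float       # kcal/mol
    fingerprint: str

    def __post_init__(self):
        if self.e_cation <= self.e_neutral:
            raise ValueError("cation heat of formation must exceed neutral")


@dataclass
class DdEResult:
    id: str
    ddE: float | None
    prediction: str
    remark: str
    provenance: dict = field(default_factory=dict)

    def as_report_row(self) -> ReportRow:
        return ReportRow(self.id, self.ddE, self.prediction, self.remark,
                         self.provenance)


_REFERENCE_CACHE: dict[str, ReferenceEnergies] = {}


def reference_energies(engine: Engine,
                       config: ScoreConfig | None = None) -> ReferenceEnergies:
    """Aniline energies for ``engine``, cached per engine fingerprint."""
    key = engine.fingerprint
    if key in _REFERENCE_CACHE:
        return _REFERENCE_CACHE[key]
    config = config or ScoreConfig()
    record = parse_smiles_string(ANILINE_SMILES, "aniline")
    pair = _score_species(record, engine, config)
    if pair is None or pair[2]:
        raise RuntimeError(
            "engine failed on the aniline reference; nothing downstream "
            f"is meaningful (engine={key}, detail={pair and pair[2]})")
    ref = ReferenceEnergies(pair[0], pair[1], key)
    _REFERENCE_CACHE[key] = ref
    return ref


def clear_reference_cache() -> None:
    _REFERENCE_CACHE.clear()


def _score_species(record: MoleculeRecord, engine: Engine,
                   config: ScoreConfig):
    """(E_neutral, E_cation, error_remark) for one molecule.

    error_remark is empty on success; on failure the energies are None.
    """
    mol = record.mol
    sites = find_primary_aromatic_amines(mol)
    if not sites:
        return None, None, REMARK_NO_AMINE
    try:
        ensemble = enumerate_conformers(record, config)
    except EmbeddingError:
        return None, None, REMARK_NAN
    ring_bonds = species.aromatic_ring_bonds(mol)
    numbers = [a.GetAtomicNum() for a in mol.GetAtoms()]

    neutral_results = []
    for conf in ensemble.conformers:
        res = engine.optimize(numbers, conf.coords, charge=0)
        if res.converged:
            res.ring_intact = check_ring_integrity(numbers, ring_bonds,
                                                   res.coords)
            neutral_results.append(res)
    if not neutral_results:
        return None, None, REMARK_NAN
    if any(not r.ring_intact for r in neutral_results):
        return None, None, REMARK_RING_OPENING

    order = np.argsort([r.heat_of_formation for r in neutral_results])
    e_neutral = neutral_results[order[0]].heat_of_formation
    if config.cation_from_all_conformers:
        cation_seeds = [neutral_results[i] for i in order]
    else:
        cation_seeds = [neutral_results[order[0]]]

    best_cation = None
    ring_opened = False
    for n_idx, _c_idx in sites:
        for seed_res in cation_seeds:
            for cand in species.build_nitrenium_candidates(
                    mol, seed_res.coords, n_idx):
                res = engine.optimize(cand.numbers, cand.coords, charge=1)
                if not res.converged:
                    continue
                res.ring_intact = check_ring_integrity(
                    cand.numbers,
                    species.drop_atom(ring_bonds, cand.removed_h),
                    res.coords)
                if not res.ring_intact:
                    ring_opened = True
                    continue
                if best_cation is None or \
                        res.heat_of_formation < best_cation:
                    best_cation = res.heat_of_formation
    if best_cation is None:
        return None, None, (REMARK_RING_OPENING if ring_opened
                            else REMARK_NAN)
    return float(e_neutral), float(best_cation), ""


def classify(ddE: float, cutoff: float = 0.0) -> str:
    """Sign rule: mutagenic iff ddE < cutoff (boundary -> nonmutagenic)."""
    return PRED_MUTAGENIC if ddE < cutoff else PRED_NONMUTAGENIC


def compute_ddE(record: MoleculeRecord, ref: ReferenceEnergies,
                engine: Engine, config: ScoreConfig | None = None) -> DdEResult:
    """Score one molecule; failures become remarks, never exceptions."""
    config = config or ScoreConfig()
    if not record.ok:
        return DdEResult(record.id, None, PRED_INCONCLUSIVE,
                         record.error or REMARK_NAN)
    elig = check_eligibility(record)
    if not elig.amine_sites:
        return DdEResult(record.id, None, PRED_INCONCLUSIVE, REMARK_NO_AMINE)
    if not elig.eligible and not config.force:
        remark = REMARK_INELIGIBLE_PREFIX + ",".join(elig.failed_criteria)
        return DdEResult(record.id, None, PRED_INCONCLUSIVE, remark)
    try:
        e_neutral, e_cation, err = _score_species(record, engine, config)
    except Exception as exc:  # batch runs must complete
        log.exception("scoring failed for %s", record.id)
        return DdEResult(record.id, None, PRED_INCONCLUSIVE, REMARK_NAN,
                         {"error": str(exc)})
    if err:
        return DdEResult(record.id, None, PRED_INCONCLUSIVE, err)
    dde = (e_cation - e_neutral) - (ref.e_cation - ref.e_neutral)
    prediction = classify(dde, config.cutoff)
    if config.equivocal_band is not None and abs(dde) < config.equivocal_band:
        prediction = "equivocal"
    prov = {"seed": config.seed, "engine": engine.fingerprint,
            "cutoff": config.cutoff}
    return DdEResult(record.id, float(dde), prediction, "", prov)


def predict_records(records: list[MoleculeRecord],
                    config: ScoreConfig | None = None,
                    engine: Engine | None = None) -> list[DdEResult]:
    """Score a batch of records with a shared aniline reference."""
    config = config or ScoreConfig()
    engine = engine or make_engine(config)
    ref = reference_energies(engine, config)
    return [compute_ddE(rec, ref, engine, config) for rec in records]


def predict_smiles(smiles: str, rid: str = "query",
                   config: ScoreConfig | None = None,
                   engine: Engine | None = None) -> DdEResult:
    """Convenience single-molecule entry point."""
    record = parse_smiles_string(smiles, rid)
    return predict_records([record], config, engine)[0]
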