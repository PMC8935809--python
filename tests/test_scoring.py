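import numpy as np
import pytest

from nitrenium.chem_io import (parse_smiles_string, PRED_INCONCLUSIVE,
                               PRED_MUTAGENIC, PRED_NONMUTAGENIC,
                               REMARK_NAN, REMARK_NO_AMINE,
                               REMARK_RING_OPENING)
from nitrenium.config import ScoreConfig
from nitrenium.qm.mock import MockEngine
from nitrenium.scoring import (DdEResult, ReferenceEnergies, classify,
                               compute_ddE, predict_records,
                               reference_energies)

ANILINE_PAIR = {"C6H7N1+0": 20.1, "C6H6N1+1": 246.4}


def _score(smiles, engine, config=None, rid="x"):
    config = config or ScoreConfig(min_trials=5, max_trials=10)
    ref = reference_energies(engine, config)
    return compute_ddE(parse_smiles_string(smiles, rid), ref, engine, config)


class TestClassify:
    @pytest.mark.parametrize("dde,cutoff,expected", [
        (-5.6, 0.0, PRED_MUTAGENIC),
        (24.1, 0.0, PRED_NONMUTAGENIC),
        (0.0, 0.0, PRED_NONMUTAGENIC),   # boundary goes to nonmutagenic
        (0.4, 2.5, PRED_MUTAGENIC),      # alternative cutoff
        (2.5, 2.5, PRED_NONMUTAGENIC),
        (-1e-9, 0.0, PRED_MUTAGENIC),    # strictly below cutoff
    ])
    def test_sign_rule(self, dde, cutoff, expected):
        assert classify(dde, cutoff) == expected


class TestReference:
    def test_cache_avoids_second_engine_run(self, fast_config):
        eng = MockEngine(energies=ANILINE_PAIR)
        ref1 = reference_energies(eng, fast_config)
        n_calls = len(eng.calls)
        ref2 = reference_energies(eng, fast_config)
        assert ref2 is ref1
        assert len(eng.calls) == n_calls

    def test_new_fingerprint_recomputes(self, fast_config):
        eng1 = MockEngine(energies=ANILINE_PAIR)
        reference_energies(eng1, fast_config)
        eng2 = MockEngine(energies=ANILINE_PAIR)
        eng2.fingerprint = "mock-2.0"
        reference_energies(eng2, fast_config)
        assert eng2.calls  # engine actually ran

    def test_engine_failure_on_aniline_is_fatal(self, fast_config):
        eng = MockEngine(fail={"C6H7N1+0", "C6H6N1+1"})
        with pytest.raises(RuntimeError):
            reference_energies(eng, fast_config)

    def test_unphysical_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceEnergies(e_neutral=100.0, e_cation=50.0,
                              fingerprint="x")


class TestComputeDdE:
    def test_aniline_scores_exactly_zero(self, mock_engine, fast_config):
        res = _score("Nc1ccccc1", mock_engine, fast_config, "aniline")
        assert res.ddE == 0.0
        assert res.prediction == PRED_NONMUTAGENIC

    def test_scripted_o_toluidine(self, mock_engine, fast_config):
        res = _score("Cc1ccccc1N", mock_engine, fast_config)
        assert res.ddE == pytest.approx(-5.7, abs=1e-9)
        assert res.prediction == PRED_MUTAGENIC
        assert res.remark == ""

    def test_no_aromatic_amine_remark(self, mock_engine, fast_config):
        res = _score("Cc1ccccc1", mock_engine, fast_config)  # toluene
        assert res.ddE is None
        assert res.prediction == PRED_INCONCLUSIVE
        assert res.remark == REMARK_NO_AMINE

    def test_cation_scf_failure_gives_nan(self, fast_config):
        eng = MockEngine(energies={**ANILINE_PAIR, "C7H9N1+0": 12.9},
                         fail={"C7H8N1+1"})
        res = _score("Cc1ccccc1N", eng, fast_config)
        assert res.ddE is None
        assert res.remark == REMARK_NAN

    def test_neutral_scf_failure_gives_nan(self, fast_config):
        eng = MockEngine(energies=ANILINE_PAIR, fail={"C7H9N1+0"})
        res = _score("Cc1ccccc1N", eng, fast_config)
        assert res.remark == REMARK_NAN

    def test_ring_opening_detected(self, fast_config):
        # cation geometries blow up (scripted): ring bonds exceed the
        # covalent criterion and the compound is reported inconclusive
        eng = MockEngine(energies={**ANILINE_PAIR, "C7H9N1+0": 12.9,
                                   "C7H8N1+1": 233.5},
                         explode={"C7H8N1+1"})
        res = _score("Cc1ccccc1N", eng, fast_config)
        assert res.ddE is None
        assert res.remark == REMARK_RING_OPENING

    def test_ineligible_not_scored_by_default(self, mock_engine,
                                              fast_config):
        res = _score("Nc1ccc(N)cc1", mock_engine, fast_config)  # diamine
        assert res.ddE is None
        assert res.remark.startswith("ineligible:")
        assert "v" in res.remark

    def test_force_scores_ineligible(self, fast_config):
        cfg = ScoreConfig(min_trials=5, max_trials=10, force=True)
        eng = MockEngine(energies={**ANILINE_PAIR, "C6H8N2+0": 30.0,
                                   "C6H7N2+1": 240.0})
        res = _score("Nc1ccc(N)cc1", eng, cfg)
        assert res.ddE == pytest.approx((240.0 - 30.0) - 226.3)
        assert res.prediction == PRED_MUTAGENIC

    def test_equivocal_band(self, mock_engine):
        cfg = ScoreConfig(min_trials=5, max_trials=10, equivocal_band=6.0)
        res = _score("Cc1ccccc1N", mock_engine, cfg)  # ddE = -5.7, in band
        assert res.prediction == "equivocal"

    def test_parse_failure_propagates_as_remark(self, mock_engine,
                                                fast_config):
        rec = parse_smiles_string("not_a_smiles", "bad")
        ref = reference_energies(mock_engine, fast_config)
        res = compute_ddE(rec, ref, mock_engine, fast_config)
        assert res.prediction == PRED_INCONCLUSIVE
        assert res.ddE is None

    def test_batch_completes_despite_failures(self, fast_config):
        eng = MockEngine(energies={**ANILINE_PAIR, "C7H9N1+0": 12.9,
                                   "C7H8N1+1": 233.5})
        records = [parse_smiles_string(s, str(i)) for i, s in enumerate(
            ["Cc1ccccc1N", "junk_smiles", "Cc1ccccc1", "Nc1ccccc1"])]
        results = predict_records(records, fast_config, eng)
        assert len(results) == len(records)
        assert results[0].ddE is not None
        assert results[1].ddE is None
        assert results[2].remark == REMARK_NO_AMINE
        assert results[3].ddE == 0.0

    def test_result_invariants(self, mock_engine, fast_config):
        for smiles in ["Cc1ccccc1N", "Cc1ccccc1", "Nc1ccc(N)cc1"]:
            res = _score(smiles, mock_engine, fast_config)
            if res.ddE is not None:
                assert res.prediction in (PRED_MUTAGENIC, PRED_NONMUTAGENIC)
                assert res.remark == ""
            else:
                assert res.prediction == PRED_INCONCLUSIVE
                assert res.remark != ""


class TestEndToEndAM1:
    """Scoring through the real built-in AM1 engine (small, rigid cases)."""

    def test_aniline_zero_and_smiles_order_invariance(self):
        from nitrenium.config import make_engine
        cfg = ScoreConfig()
        engine = make_engine(cfg)
        ref = reference_energies(engine, cfg)
        res = compute_ddE(parse_smiles_string("Nc1ccccc1", "a1"), ref,
                          engine, cfg)
        assert res.ddE == 0.0
        # same molecule written with a rotated atom order / kekulized form
        res2 = compute_ddE(parse_smiles_string("c1ccc(N)cc1", "a2"), ref,
                           engine, cfg)
        assert res2.ddE == pytest.approx(0.0, abs=0.1)

    def test_symmetry_equivalent_hydrogens_agree(self):
        """Deleting either amine hydrogen of aniline gives the same
        optimised nitrenium energy (the two H's are mirror images)."""
        from rdkit import Chem
        from rdkit.Chem import AllChem
        from nitrenium.config import make_engine
        from nitrenium.eligibility import find_primary_aromatic_amines
        from nitrenium.species import build_nitrenium_candidates

        rec = parse_smiles_string("Nc1ccccc1", "aniline")
        mol = Chem.Mol(rec.mol)
        AllChem.EmbedMolecule(mol, randomSeed=7)
        AllChem.MMFFOptimizeMolecule(mol)
        engine = make_engine(ScoreConfig())
        numbers = [a.GetAtomicNum() for a in mol.GetAtoms()]
        neutral = engine.optimize(numbers,
                                  np.array(mol.GetConformer().GetPositions()))
        assert neutral.converged
        ((n_idx, _),) = find_primary_aromatic_amines(mol)
        hofs = []
        for cand in build_nitrenium_candidates(mol, neutral.coords, n_idx):
            res = engine.optimize(cand.numbers, cand.coords, charge=1)
            assert res.converged
            hofs.append(res.heat_of_formation)
        assert len(hofs) == 2
        assert abs(hofs[0] - hofs[1]) < 0.1
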