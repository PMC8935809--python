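# nitrenium

Mutagenicity scoring of primary aromatic amines from nitrenium-ion
stability.

Aromatic amines are ubiquitous synthesis intermediates and therefore
recurring impurities and metabolites in drug development, and their Ames
mutagenicity is notoriously hard for general-purpose (Q)SAR tools.
Mechanistically, mutagenicity runs through metabolic activation to a
DNA-reactive nitrenium ion ArNH⁺, so the *stability* of that cation is a
quantitative, mechanism-based predictor. This package implements that
local QSAR for genotoxicologists and cheminformaticians doing ICH M7
style impurity assessment: it complements qualitative SAR-fingerprint
reasoning with a number, which is what you need when activating and
deactivating substituents sit on the same ring.

## The score

For a compound ArNH₂ the package computes

```
ΔΔE = ΔE(ArNH⁺) + ΔE(PhNH₂) − ΔE(ArNH₂) − ΔE(PhNH⁺)    [kcal/mol]
```

where every ΔE is the AM1 heat of formation of a geometry-optimised
species (neutral amine, and the nitrenium obtained by deleting one amine
hydrogen at charge +1). Aniline (PhNH₂) anchors the scale at exactly 0.
ΔΔE < 0 means the compound's nitrenium is more stabilised than aniline's:
predicted **mutagenic**; ΔΔE ≥ 0 predicted **nonmutagenic**. Electron
donors (methyl, methoxy) push the score negative, electron acceptors
(sulfonate, sulfonamide, CF₃, ester) push it positive, and disubstituted
scores are approximately additive in the mono-substituted ones.

The pipeline: SMILES/SDF input → salt stripping → six
applicability-domain criteria (no charge, MW < 500, ≤ 1 stereocentre,
< 10 rotatable bonds, exactly one primary aromatic amine, no aromatic
nitro) → seeded conformer search (MMFF94, 7 kcal/mol window) → AM1
optimisation of every windowed neutral conformer and both H-deleted
cations → minimum-energy ΔΔE → CSV report with an error-remark column
(`NaN`, `aromatic ring opening`, `no aromatic amine`, …).

A complete AM1 (NDDO/RHF) implementation for H, C, N, O, F, S, Cl and Br
is built in (`nitrenium.qm.am1`), so no external quantum-chemistry
program is required; an adapter for external MOPAC-dialect binaries is
included for cross-checking. See `docs/methods.md` for the model,
validation and limitations.

## Worked example

```
$ cat amines.smi
Nc1ccccc1      aniline
Cc1ccccc1N     o-toluidine
Nc1ccc(cc1)S(=O)(=O)O  sulfanilic-acid
$ nitrenium predict --in amines.smi --format smiles --out report.csv
scored 3/3 compounds -> report.csv
$ cat report.csv
id,ddE_kcal_per_mol,prediction,remark
aniline,0.0,nonmutagenic,
o-toluidine,-5.6,mutagenic,
sulfanilic-acid,24.1,nonmutagenic,
```

Aniline is the reference (0.0 by construction). The *ortho*-methyl group
of o-toluidine stabilises the nitrenium by 5.6 kcal/mol — predicted
mutagenic, and indeed an Ames positive. The para-sulfonate of sulfanilic
acid destabilises it by 24 kcal/mol — predicted (and measured)
nonmutagenic. The same numbers are exposed programmatically:

```python
>>> from nitrenium import predict_smiles
>>> res = predict_smiles("Cc1ccccc1N", "o-toluidine")
>>> round(res.ddE, 1), res.prediction
(-5.6, 'mutagenic')
```

Benchmarking against Ames labels and sweeping the classification cutoff
(`id,smiles,ames[,ddE]` CSV):

```
nitrenium benchmark --in labeled.csv --out metrics.csv
nitrenium sweep --in labeled.csv --grid -10:10:2.5 --out sweep.csv
```

which report accuracy, sensitivity, specificity, PPV, NPV, MCC and
coverage per cutoff (inconclusive predictions are excluded from the
confusion matrix and accounted via coverage).

The bundled 23-compound reference panel (CAS numbers, Ames calls and
reference ΔΔE values) is available as `nitrenium.reference_set()`.

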