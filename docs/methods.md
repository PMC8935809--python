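# Methods

## The score

Primary aromatic amines become mutagenic through metabolic activation:
N-hydroxylation followed by conjugation and heterolysis yields a nitrenium
ion ArNH+ that reacts covalently with DNA. The thermodynamic stability of
that cation is therefore a mechanistic predictor of Ames mutagenicity. The
package scores a compound by the relative stabilisation energy of its
nitrenium ion against aniline's,

    ddE = dE(ArNH+) + dE(PhNH2) - dE(ArNH2) - dE(PhNH+)   [kcal/mol]

where each dE is the AM1 heat of formation of a geometry-optimised
species. Aniline defines the zero of the scale by construction. A compound
with ddE < 0 (nitrenium more stabilised than aniline's) is predicted
mutagenic, ddE >= 0 nonmutagenic; the cutoff is user-adjustable (a +2.5
kcal/mol cutoff gave the best accuracy on the original validation set and
is exposed as `--cutoff 2.5`, never applied silently).

Electron-donating ring substituents (methyl, methoxy) stabilise the cation
and drive ddE negative; electron-withdrawing groups (sulfonate,
sulfonamide, trifluoromethyl, ester) destabilise it and drive ddE
positive. Scores of a disubstituted aniline are approximately additive in
the mono-substituted scores, which is what makes the scale useful for
expert review when activating and deactivating groups coexist.

## Pipeline

1. **Input and normalisation** (`chem_io`). SMILES lists or SDF (V2000).
   Salts/mixtures are reduced to the largest organic fragment before any
   check (aniline hydrochloride scores as aniline). Unparsable entries
   yield report rows with a `parse error` remark; a batch never aborts on
   one bad record. The report remark vocabulary is closed: `""`, `NaN`,
   `aromatic ring opening`, `no aromatic amine`, `parse error`,
   `ineligible:<criteria>`. (`parse error` is an addition to the original
   remark set, which had no notion of unparsable input.)
2. **Eligibility** (`eligibility`). Six applicability-domain criteria:
   (i) no net formal charge, (ii) MW < 500 Da (average masses, strict
   inequality), (iii) at most one tetrahedral stereocentre (assigned or
   unassigned), (iv) fewer than 10 rotatable bonds, (v) exactly one
   primary aromatic amine site, (vi) no aromatic nitro group. A rotatable
   bond is a single, non-ring bond between two non-terminal heavy atoms,
   excluding amide C-N; this definition is implemented directly rather
   than taken from a descriptor library because common library variants
   count the aniline C-N bond, which the terminal-atom rule excludes.
   Ineligible compounds are reported, not scored, unless `--force` is
   given. A molecule with *zero* amine sites always reports
   `no aromatic amine` (the more specific remark) rather than
   `ineligible:v`.
3. **Conformers** (`conformers`). Stochastic distance-geometry embedding
   (ETKDGv3, seeded) with MMFF94 minimisation stands in for the
   low-mode-MD/MMFF94x search of the original protocol; the step's only
   role is to find the low-energy conformers of the neutral amine.
   Trial count is 20 + 30 per rotatable bond, capped at 300; duplicates
   are removed at 0.5 A heavy-atom best RMSD; members more than
   7 kcal/mol above the minimum are discarded.
4. **AM1 refinement** (`qm`). Every windowed conformer is
   geometry-optimised at AM1 (closed-shell RHF singlet); the lowest heat
   of formation defines dE(ArNH2). From each optimised neutral conformer,
   both amine hydrogens are deleted in turn (charge +1, no
   pre-relaxation) and the cations optimised; the global minimum over
   conformers, sites and hydrogens defines dE(ArNH+). This "lowest value
   over the whole ensemble" reading is the default
   (`cation_from_all_conformers=True`); the single-most-stable-conformer
   reading is available behind the flag. Nitrenium ions are even-electron
   species and are treated as closed-shell singlets.
5. **Checks and remarks** (`scoring`). SCF or geometry non-convergence
   anywhere maps to `NaN`. After each optimisation, connectivity is
   re-perceived from the final geometry (bond = distance below 1.25x the
   sum of single-bond covalent radii); loss of any input aromatic-ring
   bond maps to `aromatic ring opening`. All failures are remarks in the
   CSV report, never exceptions.

## The built-in AM1 engine

No semi-empirical engine is assumed on the host: the package carries its
own AM1 implementation (`nitrenium.qm.am1`), an NDDO restricted
Hartree-Fock over the published AM1 parameter sets for H, C, N, O, F, S,
Cl and Br.

* **Integrals.** Slater s/p valence overlaps are evaluated analytically in
  prolate-spheroidal coordinates (A/B auxiliary integrals; the B integrals
  by 64-point Gauss-Legendre quadrature, machine-precision for the
  exponents that occur). Two-centre repulsion integrals use the classic
  point-charge multipole model with Klopman-Ohno damping; the additive
  radii rho_0/1/2, the charge separations D1/D2 and the atomic electronic
  energies are derived from the primary parameters at import time rather
  than tabulated. Core-electron attractions reuse the (mu nu|ss)
  integrals; the core-core term carries the AM1 Gaussian corrections and
  the classic N-H/O-H exponential exception. Legacy conversion constants
  (a0 = 0.529167 A, 27.21 eV/hartree, 23.061 kcal/eV) match the era of
  the published parameterisation.
* **SCF.** Closed-shell RHF in the orthogonalised NDDO basis, DIIS with
  light initial damping; energy convergence 1e-9 eV (1e-8 default
  single-point). Odd-electron systems are rejected: every species scored
  here is closed-shell.
* **Gradients and optimisation.** At the converged (variational) density
  the geometric gradient is the derivative of the energy at frozen
  density; it is assembled pairwise by central differences of each atom
  pair's geometry-dependent energy terms, giving analytic-quality
  gradients (checked to ~1e-5 eV/A against finite differences of the full
  SCF energy) at a cost independent of SCF. Cartesian L-BFGS with
  gtol = 0.012 eV/A (~0.28 kcal/mol/A) leaves residual energy errors well
  below 0.05 kcal/mol for these shallow organic minima.
* **Validation.** Optimised heats of formation reproduce published AM1
  values for H2 (-5.2), CH4 (-8.8), H2O (-59.2), NH3 (-7.3), ethane
  (-17.4) and benzene (22.0 kcal/mol, with the published 1.395/1.100 A
  geometry) to ~0.2 kcal/mol or better, and the 23-compound reference
  panel's printed ddE column to a Spearman rank correlation of 0.9998
  with 22 of 23 values inside 1.0 kcal/mol (the outlier, m-anisidine,
  deviates 1.5 kcal/mol; the sign is unaffected). Systematic residuals of
  the Hamiltonian cancel in ddE, which is a difference of differences.

The engine abstraction also ships an adapter that writes MOPAC-dialect
input decks and parses `FINAL HEAT OF FORMATION` from an external binary
(for cross-checking against a reference implementation where one is
installed), and a scripted mock engine that makes the whole pipeline
testable in milliseconds.

## Performance metrics

`performance` computes accuracy, sensitivity, specificity, positive and
negative prediction values, MCC and coverage from a confusion table in
which inconclusive and out-of-domain predictions are excluded from the
four cells and surface only through coverage — the only reading
consistent with a tool reporting both partial coverage and defined
accuracy. A metric whose denominator is zero is reported absent ("N/A"),
never as 0. Display rounding is one decimal, half-up; comparisons in
tests use full precision. The cutoff sweep evaluates a grid (default -10
to +10 kcal/mol in 2.5 steps) and selects the best row by accuracy, ties
broken by larger MCC and then smaller |cutoff|.

The original 85-compound industrial validation set (51 mutagens, 34
nonmutagens) is not disclosed and is **not** bundled or approximated
here; its published metric row (accuracy 69.4%, MCC 0.4, etc.) is covered
as a formula worked-example on the reconstructed confusion table
(TP=38, FP=13, FN=13, TN=21) only. Panel-scale end-to-end metrics say
nothing about performance on proprietary chemical space.

## Synthetic scores

`fixtures.synthetic_scores` draws class-conditional Gaussian scores
(defaults: mutagens at -8, nonmutagens at +8, sd 5 kcal/mol) mimicking
the observed separation of the two classes on the score axis, sized by
default like the original validation set (51/34). It exercises the metric
and sweep layers deterministically under a seed. It does not emulate
structure at all — no chemistry, no score-structure correlation, no
class-imbalanced tails — so passing sweep/metric tests demonstrates
correctness of the statistics, not predictive performance on real
compounds.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `window` | 7.0 | kcal/mol | conformer energy window above the minimum |
| `rmsd_threshold` | 0.5 | A | heavy-atom RMSD duplicate threshold |
| `min_trials`/`max_trials` | 20/300 | — | embedding attempts (scaled by rotatable bonds) |
| `seed` | 20220321 | — | embedding seed; same seed, same ensemble |
| `cation_from_all_conformers` | True | — | cation minimum over all windowed conformers |
| `cutoff` | 0.0 | kcal/mol | classification cutoff (ddE < cutoff = mutagenic) |
| `equivocal_band` | off | kcal/mol | optionally report \|ddE\| < band as equivocal |
| `gtol` | 0.012 | eV/A | geometry-optimiser gradient criterion |
| `timeout` | 300 | s | per-species limit for external engines |

## Numerical and design choices

* ddE exactly at the cutoff classifies as nonmutagenic (aniline, at 0, is
  a nonmutagen).
* Ionisable groups (sulfonic acids, anthranilates) are scored as neutral
  species, consistent with the no-formal-charge domain criterion.
* Conformer-selection ties (within 1e-12 kcal/mol) resolve to the first
  generated member, so reruns under one seed are bit-stable.
* If eligibility is forced for a multi-site polyamine, candidates are
  generated per site and the global minimum ddE is taken.
* Scores in the range of about +-5 kcal/mol were hard to call in the
  original validation; the optional `equivocal_band` surfaces that zone
  without changing the default sign rule.
* Reported ddE is rounded to one decimal in the CSV; full precision is
  kept internally and in the API.

## Problem sizes

The test suite scores the full 23-compound panel end to end with the
built-in engine (roughly 15-17 minutes on one CPU; about 6 AM1
optimisations per compound on average), plus fast integral-, metric- and
pipeline-level checks against independent oracles (grid integration for
overlaps, finite differences for gradients, brute-force recounts and
scikit-learn for metrics, a torsion-grid scan for the conformer search).
The acceptance script scores aniline plus the eight rigid panel targets,
about three minutes on one CPU.

## Known limitations

* AM1 with an s/p basis describes hypervalent sulfur crudely; sulfonate
  ddE values are nevertheless reproduced because the error largely
  cancels between neutral and cation.
* The score ignores steric shielding of the amine and effects on the
  *kinetics* of metabolic activation — bulky or strongly
  electron-withdrawing substituents can make a thermodynamically
  "mutagenic" nitrenium unreachable in vivo, a known source of false
  positives.
* No solvation, no thermochemical corrections, no tautomer or protomer
  enumeration; secondary/tertiary aromatic amines are out of scope by
  design.
* Open-shell species are not supported; a hypothetical triplet nitrenium
  is outside the model.
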