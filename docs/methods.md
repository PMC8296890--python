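# Methods

## Problem and model

The package estimates the association between reactive-metabolite structural
alerts and drug-induced autoimmune disease (AD), and turns those alerts —
together with a daily-dose threshold — into a predictive flag. Three layers
of inference sit on one data model (drugs with SMILES, daily dose in mg/day,
and a binary AD label):

1. **Per-flag 2×2 association.** Any binary flag f (an alert match, the
   high-dose rule, their conjunction, or the any-alert union) is crossed
   with the AD label into (tp, fn, fp, tn). We report sensitivity, PPV, FPR
   (plus specificity/NPV), the cross-product odds ratio
   OR = (tp·tn)/(fn·fp), and a two-sided Fisher exact p-value.
2. **Classification.** A gradient-boosted tree ensemble over the binary
   feature vector (dose flag first, one column per alert), scored by
   balanced accuracy to handle the ~1:7 class imbalance, and validated with
   a label-permutation null.
3. **Reactivity.** Conceptual-DFT descriptors η, μ, ω computed from
   externally supplied HOMO/LUMO energies, ranking candidate metabolites by
   electrophilicity.

## Alert library

Alerts are Daylight-style SMARTS evaluated under RDKit's default aromaticity
model. The builtin library carries the aromatic-amine family — any nitrogen
on a benzene ring (`[#7]c1ccccc1`) and its two/one/no N-H variants, which
are mutually exclusive per nitrogen and each imply the any-pattern — plus
alkenes, benzylic halides, phenols, halogenated carbons, methoxy/methyl
arene motifs, and the decomposed `nitrogen_compound` (`[#7]`) and
`benzene_ring` patterns used for mechanistic comparison. Published alert
collections describe most patterns verbally rather than as machine-readable
strings, so the builtin SMARTS are this package's own transcriptions of the
named motifs; user libraries load from CSV (`alert_id,smarts,description
[,family,source]`) and are validated on load (unique ids, compiling SMARTS).

## Screening conventions

Structures are standardized before matching: the largest covalent fragment
(by molecular weight, then heavy-atom count) is kept — stripping salts and
counter-ions — and stereochemistry is dropped, since alerts are 2-D
patterns. Unparsable SMILES are excluded from batch screens with a logged
report rather than aborting the run. Aromatic-amine classing counts
implicit + explicit hydrogens on each nitrogen bonded to a benzene-ring
carbon; a molecule with several such nitrogens is flagged for every class
present. The dose rule is inclusive: 100 mg/day counts as high-dose. A
missing dose follows a configurable policy (exclude-and-report by default).

## Statistical choices

- **Odds ratio.** The uncorrected cross-product estimator, because it is
  the convention for screening tables of this kind. The Haldane–Anscombe
  +0.5 correction is applied to all four cells only when a zero cell occurs,
  and the result is flagged (`zero_cell_corrected`). No confidence intervals
  are reported.
- **Exact test.** Two-sided Fisher via the point-probability
  (minimum-likelihood) rule — the sum of hypergeometric probabilities of
  all margin-fixed tables no more likely than the observed one — delegated
  to `scipy.stats.fisher_exact` and cross-checked in the test suite against
  an independent brute-force enumeration oracle for all tables with N ≤ 60.
- **Multiplicity.** Raw per-alert p-values are the primary output, matching
  screening practice for alert panels; a Benjamini–Hochberg column can be
  requested (`results_to_frame(fdr_column=True)`).
- **Rounding.** Printed tables round percentages to the nearest integer and
  odds ratios to 2 decimals, half away from zero.

## Classifier

LightGBM is the boosting backend, run single-threaded with
`deterministic=True` so a fixed seed reproduces the pipeline bit-for-bit.
Defaults: stratified 80/20 split (407 drugs split 325/82); grid
depth {2,4,6} × learning rate {0.03,0.1,0.3} × iterations {100,300};
`class_weight="balanced"`; `min_child_samples=5` (the features are a handful
of sparse binary columns, so the library default of 20 would starve splits);
stratified 5-fold CV scored by mean balanced accuracy; ties in the grid
break to the first point in grid order. AUC uses the predicted positive
probability with average-rank tie handling and is reported missing for a
single-class test set.

The permutation null reshuffles labels once per permutation and runs a full
CV with the already-tuned hyperparameters; re-tuning inside every
permutation would multiply cost ×grid-size, and freezing the configuration
is the conservative, conventional choice (it can only make the null easier
to beat if tuning itself overfits, which the near-0.5 null means we do not
observe). The CV arm repeats k-fold CV with fresh fold sampling on intact
labels. The two score distributions are compared with a two-sided Welch
t-test (no equal-variance assumption). Defaults are 1000 permutations and
1000 repetitions; tests and the acceptance script run 50–100 of each, which
is ample to locate the null mean and reject at p < 0.01 — the statistics of
interest (a mean near 0.5 and a many-sigma separation) stabilize long before
1000 draws.

Feature attributions are exact TreeSHAP values from the backend
(`pred_contrib`), satisfying local accuracy: base value + row sum equals the
raw-margin output within 1e-6. Global importance is the mean absolute
attribution.

## Synthetic generator

The generator emulates the statistical structure of a curated oral/injected
drug dataset: fixed class sizes (default 50 AD-positive / 357 AD-negative),
per-alert indicators drawn class-conditionally with prevalences
(p₁, p₀), which plants a population odds ratio p₁(1−p₀)/((1−p₁)p₀); a
class-conditional high-dose indicator (defaults 0.72 / 0.395, matching a
72% / 39.5% high-dose split); and doses drawn log-uniform on [1, 1000] mg
within the side of the 100 mg cutoff selected by the indicator. Default
alert prevalences mirror a headline screen in which the aromatic-amine
alert appears in 28% of positives and 11.8% of negatives (planted OR ≈ 2.9),
with companion motifs at milder effect sizes.

Each drug's SMILES is assembled from an inert alkane/cyclohexane scaffold
with one branch per planted alert (e.g. an aminophenyl group for the
aromatic-amine alert), so the alert is present if and only if its indicator
was drawn true; generation verifies that every fragment realizes its own
SMARTS and reports any cross-reactivity between panel patterns (the default
panel has none). This makes re-screening the emitted SMILES reproduce the
indicator matrix exactly — the round-trip invariant the tests rely on.
Alerts are independent within a drug by default; an exchangeable
Gaussian-copula correlation knob exists but is off. Dose and alerts are
independent given the class.

What the generator does **not** emulate: realistic medicinal-chemistry
property distributions, correlated alert co-occurrence from shared
scaffolds, dose–structure dependence, or label noise. Passing tests
therefore demonstrate the pipeline's statistical correctness and
calibration, not predictive performance on real pharmaceuticals.

## Reactivity descriptors

η = (E_LUMO − E_HOMO)/2, μ = (E_LUMO + E_HOMO)/2, ω = μ²/2η, computed on
whatever energies are supplied (default hartree; eV supported with an
explicit conversion, ×27.211386; mixed units are an error). ω is *not*
invariant under a uniform shift of both energies — algebraically
ω = (E_LUMO + E_HOMO)²/(4(E_LUMO − E_HOMO)) — which the tests assert
directly. Ranking is by descending ω with ascending E_LUMO as tie-break,
then compound id for stability. Electronic-structure calculations
themselves are out of scope; the bundled example energies are synthetic
illustrative values.

## Problem sizes used in tests and the acceptance script

Association statistics are evaluated directly on published per-flag counts
(n = 407), which is instantaneous. The exact-test oracle comparison uses
1000 random tables with N ≤ 60. The permutation-null check runs 100
permutations vs 100 CV repetitions on an n = 400 set with a planted OR-6
alert; the acceptance script uses 50/50. Planted-OR recovery uses 100
generator seeds at 10× the default study size (500/3570); this is a
stochastic check whose success rate is ~92% per seed, so individual
seeds occasionally dip just below the 90/100 mark — the reported rate is
the honest draw.

## Known limitations

- The builtin SMARTS are descriptive reconstructions of named motifs, not a
  published machine-readable alert set; users with a curated library should
  load it from CSV.
- The cross-product OR is reported even where other estimators (e.g.
  conditional MLE) would differ slightly; published screening tables mix
  estimators inconsistently, and the cross-product form is documented and
  reproducible.
- Fisher's exact p is conservative (super-uniform) on discrete tables; the
  null-calibration test checks super-uniformity, not exact uniformity.
- Balanced accuracy of a constant classifier is 0.5 by convention here
  (undefined ratios in model metrics fall back to 0 for sensitivity and
  specificity when a class is absent from predictions, not from the data).
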