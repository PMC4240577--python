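# Methods

## The study being emulated

A two-arm dietary intervention in obese type 2 diabetes patients: 27
patients (13 randomized to VLCD + exercise, 14 to VLCD only) sampled at
baseline and after 16 weeks, plus 27 obese and 27 lean control subjects
sampled once.  Patient plasma was profiled by discovery iTRAQ (8-plex, nine
experiments) and the full cohort by targeted MRM (13-protein panel, three
acquisition batches).  The patient-level measurements of such a study are
not publicly available, so the package ships a synthetic-data generator that
reproduces the design and the noise structure the analysis has to cope with;
every analysis stage is written against the generic data contracts, not the
generator.

The MRM cohort is scheduled as 108 injections (54 patient samples + 54
control samples).  Some reports of this design mention 114 MRM specimens;
the stated cohort sizes sum to 108 and the extra six are unexplained
(plausibly replicate injections), so the generator uses 108.

## Synthetic-data model

For protein *g*, subject *i*, sample *s* and measurement channel/injection
*c*, the generated log2 intensity is

```
log2 I = mu_g + d_g·[T2DM] + o_g·[obese] + (v_g + x_g·[exercise])·[week16]
         + u_i + pep_offset + plex/batch effect + channel effect + eps
```

with `u_i ~ N(0, sigma_b²)` and `eps ~ N(0, sigma_e²)`.  The QC reference
pool carries, per protein, the geometric mean of all scheduled primary
samples' abundances (the pool is mixed from equal fractions of the primary
samples; proportions are otherwise unknowable, so equal contribution is
assumed).  Dropout removes all spectra of a (protein, plex) pair with a
fixed probability, emulating the stochastic peptide sampling of
data-dependent acquisition.

Defaults (log2 units unless noted), chosen once as study-shaped conditions:

| parameter | default | rationale |
|---|---|---|
| `sigma_e` (residual) | 0.20 | ~15% CV, typical isobaric reporter noise |
| `sigma_b` (between-subject) | 0.25 | plasma-protein biological variation; matches ratio-scale SEMs ~0.03–0.08 at n = 27 |
| `sigma_peptide` / fragment offset | 0.30 | ionization-efficiency spread between peptides |
| `sigma_plex`, `sigma_batch` | 0.10 | run-to-run multiplicative shifts the QC bridge must remove |
| `sigma_channel` | 0.05 | residual label/channel bias |
| dropout per (protein, plex) | 0.105 | solves (1−p)⁹ ≈ 234/635, the observed complete-case fraction of a nine-plex study |
| baseline `mu_g` | N(16, 2²) | arbitrary intensity scale; cancels in all ratios |

What the generator does **not** emulate: co-isolation interference and
isotope impurity of reporter channels, chromatographic peak shape and
integration error, shared tryptic peptides between homologous proteins
(available via `shared_fraction`, off by default), missingness that depends
on abundance, and any age/gender structure (the study's final model dropped
those covariates as non-significant).  Passing tests therefore demonstrate
correctness of the pipeline's arithmetic and its statistical calibration
under the stated noise model — not robustness to interference-driven ratio
compression or informative missingness in real spectra.

## Quantification

**iTRAQ.** Each spectrum's primary-channel intensity is converted to
`½·(I_c/I_113 + I_c/I_117)`, the arithmetic mean of the ratios to the two QC
reporters (dividing by the mean QC intensity instead is available by
config; the two agree when the QC replicates are equal).  Spectra of a
peptide within a plex collapse to the median; protein groups take the
median over their peptides' ratios, with peptide counts kept as metadata.
Zero or negative intensities are treated as missing (a ratio is undefined);
rows missing either QC channel are dropped and counted, and a plex whose
every row is dropped raises an error rather than silently vanishing.

**MRM.** Fragment intensities of primary injections are divided by the
median intensity of the same fragment over the batch's QC injections.
Normalization is batch-local: the batches are separate acquisition runs and
a global median would let drift leak across them.  A batch-global median
only bounds slow-drift bias when the batch spans about one QC period, so a
second mode (`qc_scope="bracket"`) log-interpolates the two QC injections
bracketing each primary injection; under a geometric drift it cancels the
drift exactly, and in general it keeps the residual bias within the drift
accrued over one period.  Rollup is a hierarchical mean — fragments to
peptide, peptides to protein — giving each of the two panel peptides equal
weight regardless of surviving fragment counts.

**Reference-stability normalization.** On the complete-case proteins the
stability of protein *j* is `M_j`, the mean over partners *k* of the SD over
samples of `log2(a_ij/a_ik)`.  Proteins are ranked by ascending `M`; the
reference set is the smallest `n` in [3, 10] whose inclusion-step variation
`V(n, n+1)` (SD over samples of the log-ratio of consecutive normalization
factors) falls below 0.15, else 10 — the conventional constants of the
stepwise-reference-selection literature, configurable.  The per-sample
normalization factor `NF_i` is the geometric mean of the selected references
in sample *i*, and the default output is `a_ij / NF_i`.  This form is
*exactly* invariant to any sample-wide multiplicative perturbation, which is
the property the pipeline's QC-bridge design exists to provide; a
scale-preserving variant that re-multiplies by the geometric mean of the
`NF_i` is available (`scale="preserve"`) but lets a single-sample factor *c*
leak `c^(1/S)` into the global scale, so it is not the default.
Normalization runs after protein rollup (stability is a protein-level
notion) and on the ratio scale, with logs used only inside the stability
computation.

**Complete-case filter.** Modelling keeps proteins quantified in every
patient sample at both timepoints, then removes flagged internal-control
proteins; the three counts (total, complete, analyzed) are reported.

## Protein inference

Peptide–protein incidence is deduplicated, proteins with identical peptide
sets merge into one group, and proteins whose evidence is a strict subset of
another's are subsumed (reported inside the covering group rather than as
members of every group — the alternative reading would duplicate
quantitative evidence).  Groups holding at least one unique peptide are
fixed first and can never be absorbed; remaining peptides are covered
greedily, largest number of unexplained peptides first, ties broken by
lexicographic accession so the grouping is a pure function of the incidence.
The greedy step inherits the classical `ln(n)+1` approximation guarantee,
and because forced groups belong to every cover, the overall output stays
within that factor of the exact minimum (verified against exhaustive
enumeration on small instances).

## Repeated-measures model

Per protein, patient samples follow a linear mixed model with a subject
random intercept, fitted by maximum likelihood.  Time is coded 0/1 and
treatment ±½, so `β₁` is the arm-averaged diet effect and `β₃` the extra
time effect of exercise.  Because every subject contributes at most two
observations, the marginal covariance is block 1×1/2×2 and, writing
`λ = σ_b²/σ_e²`, the GLS pieces reduce to closed forms
(`V⁻¹ = I − λ/(1+nλ)·J` per block); the profile likelihood in `λ` is
maximized by an 82-point log-grid followed by 80 golden-section refinements
(bracket shrinks by ~10⁻¹⁸; the relative log-likelihood change at
termination is far below 1e-10), with the boundary `σ_b² = 0` admitted as a
valid constrained ML solution.  All proteins of a study share the design
matrix, so the fitter is vectorized across proteins; correctness is checked
against a dense-covariance brute-force maximizer and against an established
mixed-model implementation.

Fixed effects are tested by likelihood-ratio tests between nested ML fits
(the natural companion of ML estimation): the diet effect by dropping the
time term (df 1; with the ±½ coding this tests the arm-averaged time
effect), the exercise effect by dropping the interaction (df 1), each
referred to χ².  On balanced single-group data the time estimate equals the
mean paired difference exactly and the LRT p agrees with the paired-t p up
to the χ²-vs-t approximation gap (< 0.005 at n = 200, tested).  BH
adjustment runs per contrast family across proteins.  Analysis is on the
ratio scale by default (`log2_scale` available): the abundances are already
dimensionless ratios near 1, and the study's reported tables are on that
scale.  Significance rules: VLCD — raw p(time) < 0.05 **and** BH-adjusted
p(time) < 0.10; exercise — raw p(interaction) < 0.05 with adjusted values
also reported.  Zero-variance t-tests are flagged rather than given a
p-value; in comparison families they enter BH as p = 1.

## Marker classification

Each protein gets six comparisons among T2DM0, T2DM16, OBESE and LEAN
(paired for the within-subject pair, Welch otherwise), BH-adjusted within
each comparison family.  Categories are assigned from the adjusted
significance pattern at α = 0.05, evaluated in order: **DIET** if the
within-subject contrast is significant; **DIABETES** if both patient
timepoints differ from both control groups while the controls do not differ
from each other; **OBESITY** if lean controls differ from obese controls
and from baseline patients while obese controls do not differ from baseline
patients; **NON_ASSOCIATED** if nothing is significant; **AMBIGUOUS**
otherwise.  The precedence (DIET → DIABETES → OBESITY) resolves patterns
that satisfy several templates, e.g. a strong diet responder whose post-diet
level also separates from the controls.  The comparison graph is emitted in
DOT with edge width `clip(5 − (−log10 p), 0.5, 5)` — indistinguishable
groups are joined by thick edges; the p-values are always also written
numerically.

## Verification problem sizes

The test suite and `scripts/acceptance.py` exercise the pipeline at the
study's own scale wherever the quantity refers to the study (27 + 54
subjects, nine plexes, three batches, 232-protein null panels) and at
reduced scale for pure-numerics cross-checks (4–8-protein geNorm instances,
≤10-protein exhaustive covers, 8–16-subject likelihood comparisons).
Monte-Carlo sizes: 100 replicates for effect recovery, 2 000 for LRT null
calibration, 50 replicate studies for the dual-threshold null rate, and a
400-protein cohort (20 planted markers per class, 340 null) for
classification recovery — the mostly-null panel keeps BH leakage onto null
proteins well below the 5% per-class error allowance while 20 per class
lets the ≥95% requirement tolerate a single misclassification.  Planted
classification effects are 1.08 log2 units, i.e. 4× the per-value noise SD
`sqrt(sigma_b² + sigma_e²/4)` after the 2×2 fragment rollup.

## Known limitations

- The parsimony grouping is greedy, not provably minimal on adversarial
  incidences (the exact cover is NP-hard); the brute-force oracle bounds the
  gap on random instances only.
- LRT p-values rely on the asymptotic χ² reference; at very small n the
  paired-t reference is more accurate for the single-group time contrast.
- The generator's dropout is protein×plex-uniform; abundance-dependent
  missingness would bias the complete-case filter toward abundant proteins
  in ways these tests do not measure.
- `scale="preserve"` normalization is provided for comparability with
  reported ratio tables but sacrifices exact single-sample invariance (see
  above).
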