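# Methods

## Scope and model

The package implements a multi-dataset screening-and-validation procedure
for p53-repressed gene modules.  Its statistical core is deliberately
simple — ratio thresholds, unpaired t-tests, the comparative-Ct (ΔΔCt)
transform, Fisher's exact test, and median-split Kaplan–Meier/log-rank
analysis — because each stage mirrors how such screens are actually run:
the power of the design comes from intersecting independent datasets and
from orthogonal perturbation validation, not from any single test.

### Screen criteria

* **Microarray (probe level).** For each probe, `A` is the median intensity
  over the ADR-treated wild-type timepoints (12/24/48 h) and `B` the
  minimum over the untreated wild-type baseline and all p53-null samples.
  A probe is a hit iff `A/B < 0.5`, strictly; a ratio of exactly 0.5 is
  not a hit.  Probes with `B = 0` have an undefined ratio and are excluded
  with a logged count rather than raising — a deliberate choice, since a
  zero minimum is a platform artifact rather than biology.  A gene is a
  candidate if **any** of its probes passes (`any_probe`); the alternative
  `median_probe` collapse (threshold on the median probe ratio) is exposed
  as a parameter because the probe-to-gene collapse rule in such designs is
  a genuine free choice.
* **RNA-seq (gene level, FPKM).** A pseudocount of 1 is added to every
  FPKM value *before* averaging (so an all-zero gene gives A = B = 1,
  ratio 1).  `A = mean(WX)`; `B = min(mean W, mean KX, mean K)`; candidate
  iff `A/B < 0.5`.  The candidate screen uses the mammary gland only; other
  tissues enter through the per-tissue log2 irradiated/control profile.
* **Cohort.** Per gene, an unpaired two-tailed t-test between wild-type-
  and mutant-p53 tumors.  A two-sided F-test at α = 0.05 on the variance
  ratio gates the pooled vs Welch variant (`welch_always` is available for
  users who distrust the gate).  Candidate iff `p < 0.05` **and** the
  wild-type mean is lower.  No multiple-testing correction is applied at
  this stage; the intersection with two independent datasets is the
  false-positive control.  If both groups are exactly constant, p is
  defined as 1 when the constants agree and 0 otherwise; note that the
  degeneracy check must compare elements, not `np.var == 0` (the float
  variance of a constant vector is ~1e-27, not 0).

### ΔΔCt quantification and module membership

`ΔCt = Ct_gene − Ct_ref` per replicate; `ΔΔCt` is the difference of
*group means* of ΔCt (replicates are independent experiments, not paired);
`log2FC = −ΔΔCt`, fold change `2^−ΔΔCt`.  Reported SD is the SD of
per-case-replicate log2FC against the control mean; the per-gene t-test on
ΔCt is reported for parity with figure significance marks but never enters
the membership criteria, which are threshold-based.

Module membership requires, at the `log2FC ≤ −2` cutoff (inclusive):
repression in ≥ 2 of 4 wild-type lines and 0 of 3 mutant lines; abrogation
of the repression under p53 siRNA (control-siRNA arm must itself be
repressed — genes never suppressed are failed and flagged as vacuous); and
repression by exogenous p53 in a mutant line with a clean transduction
control (the control-virus arm must stay above the cutoff; this guard is a
toggle, since a control-driven drop would confound attribution).  The
audit trail records the first stage that excluded each non-member.

### Fisher's exact test

The two-sided p is the probability-at-most-observed sum over all tables
with the observed margins (the convention of R's `fisher.test` and scipy),
computed in log space from `lgamma` with a 1e-7 relative guard against
floating-point ties at the observed probability.  A zero margin gives
p = 1.  An exact integer-arithmetic enumeration oracle
(`fisher_exact_oracle`, numerators compared as integers over the common
denominator `C(n, c1)`) backs the implementation in tests: agreement is
within 1e-12 over every table with total ≤ 60, and spot-checked against
scipy on random tables.

On the published promoter-occupancy counts, one bookkeeping subtlety is
surfaced rather than hidden: the five-dataset promoter test's printed
p-value (0.0000154) arises from the full 28-gene module denominator
([[78,105],[1,27]]), whereas the printed percentage (1 gene, 3.7%) implies
the 27 annotated module genes ([[78,105],[1,26]], p = 2.67e-5).  The
report therefore always states how many genes were dropped for missing TSS
annotation, and the tests pin both variants.

### TSS windows

Peaks and windows are 0-based half-open; the TSS is a single base chosen
strand-aware upstream of this module, and a half-width `w` yields the
window `[tss − w, tss + w + 1)`, which covers the TSS base plus `w` bases
on each side.  Overlap is ≥ 1 bp intersection.  Multiple ChIP-seq sources
combine by "peak in ≥ 1 source" by default, with an all-sources consensus
option; the per-source tables are always emitted alongside the pooled one.

### Survival

Kaplan–Meier estimation and the two-group log-rank test (hypergeometric
variance, simultaneous-event tie convention, χ² with 1 df) are computed
with lifelines.  The median split sends values strictly greater than the
per-gene median to High; the tie rule is fixed and documented because it
is a genuine free choice that changes group sizes at ties.  The direction
of effect is oriented by restricted mean survival time up to the last
observed time.  The per-gene prognosis screen reports nominal p-values at
α = 0.05 by default, with an optional Benjamini–Hochberg toggle (off, to
match how such screens report single-gene survival associations).

## Synthetic data

The generators plant one ground truth across all modalities and emulate
the study designs they stand in for: one array per condition code in the
time course with 1–3 probes per gene; tissues with 3 animals per arm (2
for mammary gland and ovary); a 795 wild-type / 298 mutant cohort; a 4+3
cell-line panel with triplicate qPCR.  Key defaults: repression fold 4
(screen ratio 0.25 vs the 0.5 cutoff), lognormal expression noise with
σ = 0.2 on the natural-log scale, qPCR effect −3 log2 units (vs the −2
cutoff) with 0.15-cycle Ct noise, promoter-peak probabilities
(0.426, 0.037) for induced vs module genes, hazard ratio 3 for the
high-risk group.  Within-condition variances are not published for the
emulated designs, so the noise defaults are calibration choices — set once
to values typical of the respective platforms, not fitted to any output.

Choices worth noting:

* Expression noise is multiplicative lognormal because abundances are
  positive and every screen criterion is scale-based.  qPCR is simulated
  at the Ct level (reference gene fixed at a nominal 20 cycles) so that
  the ΔΔCt arithmetic, including reference normalization, is genuinely
  exercised rather than short-circuited at the fold-change level.
* One wild-type panel line is non-responsive by default (mirroring
  SV40-transformed lines in which p53-mediated repression fails), which
  exercises the ≥ 2-of-4 rule; a configurable fraction (0.6) of planted
  genes is p21-dependent, which the p21-siRNA arm of the knockdown table
  reflects.
* Survival uses exponential event times (baseline median 5 years) with
  independent uniform censoring over 10 years — the simplest model with a
  controllable hazard ratio.  The hazard is driven by a latent standard-
  normal risk factor `u`, independent of p53 status, loaded
  multiplicatively (loading 0.8) onto the planted prognostic genes; a
  patient with `u > 0` has their hazard multiplied by the configured
  ratio.  High expression of a prognostic gene therefore tracks worse
  survival, while non-prognostic genes are exactly null for the log-rank
  screen even though they still separate by p53 status.
* Every generator draws from its own RNG stream derived from the master
  seed via a stable CRC-32 label, so adding a generator cannot perturb the
  others, and identical configs give byte-identical outputs.
* Planted RNA-seq baselines are floored at 8 FPKM so that the fold-4
  effect stays unambiguous against the +1 pseudocount; 5% of null genes
  are unexpressed (FPKM 0 everywhere) to exercise the pseudocount path.

What passing tests on these data do and do not show: the generators
reproduce the *designs* and effect structure, not the full covariance of
real platforms — no probe cross-hybridization, no library-size or batch
effects, no copy-number-driven expression, no correlated gene programs
beyond the single risk factor.  Recovery of the planted module therefore
demonstrates correctness of the criteria and their composition, not
expected sensitivity on real data, where the dataset-dependent candidate
counts cannot be reproduced at this scale.

## Problem sizes and determinism

Default end-to-end runs use 1,000 genes with 50 planted (the calibration
checks use 28-gene modules over 40 replicate cohorts, 200 log-rank
replicates at 200 patients/arm, and 500 null replicates for the
uniformity check) — sizes chosen so the whole suite and the acceptance
script each run in a couple of minutes on one CPU while keeping the
binomial bands on estimated rates tight.  All stochastic tests are seeded;
the pipeline report is byte-identical across runs at a fixed seed
(timings excluded).

## Known limitations

* The ortholog map is symbol-identity by default; paralog splits and
  one-to-many orthology must be supplied explicitly as pairs.
* Amplification-efficiency correction (e.g. Pfaffl) is out of scope; the
  ΔΔCt transform assumes ~100% efficiency for both target and reference.
* No Cox modelling or hazard-ratio confidence intervals; the survival
  module reports direction and log-rank significance only.
* The cohort screen's F-test gate is applied per gene; whether a published
  analysis pooled or Welch-tested per gene is typically ambiguous, so both
  routes are exposed (`f_test_gate`, `welch_always`).
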