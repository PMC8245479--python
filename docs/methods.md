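# Methods

## Scope

`harvestgs` implements a genomic-selection analysis for a perennial
breeding population phenotyped over repeated harvests: marker QC,
RR-BLUP prediction, tenfold cross-validation, selection-efficiency
statistics, and cross-harvest transfer validation.  Because no raw
genotype or field data are available for the motivating study, the
package ships a first-class synthetic-population generator; all
statistical claims in the test suite are made against that generator's
known ground truth, and the desk-scale worked examples are checked
against published numbers whose inputs are themselves published.

## Synthetic population generator

The generator emulates a single large cross-pollinated family group:
parents drawn at Hardy–Weinberg equilibrium per marker (allele
frequencies uniform on `[maf_floor, 1−maf_floor]`), progeny from
Mendelian gamete sampling under a round-robin crossing plan (parent *c*
× parent *c+1*, progeny counts equal up to integer division).  Loci are
unlinked; linkage disequilibrium arises solely from family structure,
which is the component of LD that drives within-population genomic
prediction.  There is no mutation, recombination map, dominance or
epistasis.

Phenotypes: `n_qtl_sim` markers are causal.  Each causal marker's
effects across harvests are one draw from a multivariate normal whose
correlation matrix is the configured genotype-by-harvest genetic
correlation, so cross-harvest transferability is a dial with known
truth.  True breeding values (centered dosages × effects) are rescaled
so every harvest's genetic SD equals `genetic_sd` exactly; this makes
the heritability calibration exact in expectation, since the residual
SD is then `genetic_sd·√((1−h²)/h²)` with `h²` defined on the scale of
single plot records, σ²_g/(σ²_g+σ²ₑ).  Block effects (one per
harvest × block, SD `block_sd`) are treated as nuisance fixed effects
downstream and excluded from the heritability denominator.  One record
is emitted per individual × harvest × block; aggregation to entry means
is left to the analysis.  Everything derives from `numpy`'s seeded
generator; two seed streams (genotypes, phenotypes) keep the two stages
independently reproducible.

Defaults mirror the motivating study's design constants: 42 parents,
386 progeny, 811 markers, 3 harvests with plot h² = 0.18/0.19/0.20, six
blocks, harvest means 173.76/760.85/1075.52 g·plant⁻¹.  Values the
study does not state were fixed once at realistic levels: 400 causal
loci (a polygenic yield trait), genetic SD 60 g·plant⁻¹, block SD 30,
missing-call rate 2%, and a genetic-correlation matrix (0.40/0.30/0.70
for harvests 1–2/1–3/2–3) in which adjacent mature harvests resemble
each other more than either resembles the juvenile first harvest.

What passing tests do **not** show about real data: the generator's
markers include every causal locus, so predictive abilities run higher
(≈0.5–0.6 at h²≈0.2) than field studies typically report (≈0.2–0.55);
there is no genotype-by-environment noise beyond the programmed
correlation structure, no population structure beyond one generation of
crossing, and missingness is completely at random.

## Marker QC

Call rate is the fraction of non-missing calls per marker, filtered
with ≥ (default 0.95).  MAF is computed over observed calls and
filtered strictly (>).  The default threshold is the population-size
critical level `1/√(2N)` — the frequency below which the minor allele
is expected in fewer than √(2N) of the 2N sampled chromosomes — which
at N = 386 gives 0.036 (≈ the conventional 4% cutoff); a fixed
threshold can be supplied to reproduce published filters exactly.  A
marker failing both rules increments both counters, so exclusion counts
can exceed the number of markers removed.  Imputation is by marker mean
(consistent with subsequent centering); standardization divides by the
population SD (ddof = 0) — the RR-BLUP/GBLUP equivalence test pins this
convention, since `K = ZZ′/n` only has average diagonal ≈ 1 under it.
Standardization parameters are frozen objects so held-out individuals
are always projected with training-set means and scales.

## REML and the mixed-model equations

Variance components are estimated on the equivalent individual-level
model `Var(y) = σ²_g·K + σ²ₑ·I`, `K = ZZ′/n`.  After projecting out the
fixed effects with a QR basis, a thin SVD of the projected `Z`
diagonalizes `K` on the residual space; the REML log-likelihood then
depends on one scalar δ = σ²ₑ/σ²_g through sums over eigenvalues, with
the zero-eigenvalue mass handled in closed form.  The profile is
evaluated on a 41-point log grid over δ ∈ [10⁻⁶, 10⁶] and refined with
bounded scalar minimization; the grid doubles as a diagnostic trace
stored on the result.  Cost is O(n·m²), so the study-scale problem
(≈2,100 records × 811 markers) fits in well under a second per fit.
Degenerate inputs: a phenotype fully explained by fixed effects returns
both components zero (infinite ridge ⇒ all marker effects zero); the
boundary cases h² → 0 and h² → 1 land on the grid ends rather than
erroring.

Marker effects solve the block system by Cholesky factorization (the
coefficient matrix is symmetric positive definite for λ > 0 and
full-rank `X`); the solution is verified against the right-hand side to
1e-8 relative as a hard postcondition.  Rank-deficient fixed designs
are rejected with the aliased columns named via pivoted QR.

Fixed effects are intercept + drop-first block dummies within one
harvest, plus drop-first harvest dummies when records are pooled
(mean-yield scope); entry-mean analyses use an intercept only.  Both
record-level (default) and entry-mean phenotype paths are provided,
since the appropriate choice depends on how the trial was balanced.

## Cross-validation

Individuals are permuted once per seed and split into k folds whose
sizes differ by at most one (386/10 → six folds of 39, four of 38).
Within each fold, QC thresholds (when enabled), the monomorphic-marker
guard, standardization, REML and the effect solve are all re-derived
from training individuals only — the leakage test asserts that
training-only and all-data standardizations genuinely differ.
Predictive ability r_yg is the Pearson correlation between assembled
out-of-fold GEBV and entry-mean phenotypes; constant vectors make it
undefined and it is reported as such (NaN plus a flag), never silently
zero.  One repetition of tenfold CV is the default.

## Selection statistics

The accuracy, QTL-count, required-population-size, PEV and efficiency
formulas are implemented as pure functions (see README for the
algebra).  Two choices were genuinely open:

* **Scale flag.**  The accuracy-to-population-size formulas can read
  the observed/desired value as a correlation (entering squared,
  `scale="accuracy"`) or as a reliability (entering directly,
  `scale="reliability"`).  Published required-population-size tables
  for this study system have internal ratios — e.g. 2788/207 ≈ 13.5 =
  (0.9/0.1)/(0.4/0.6) — that only the reliability reading reproduces,
  so it is the default; both are exposed and the report records which
  was used.  At either scale the QTL-count and population-size formulas
  are exact algebraic inverses, asserted over a parameter grid.
* **PEV source.**  Phenotypic-selection accuracy needs a
  prediction-error variance.  It is taken from the replicated-block
  phenotypic mixed model `y = Xβ + Wu + ε` with an independent genetic
  effect per individual (identifiable because each individual has six
  block records): PEV is σ²ₑ times the per-individual diagonal of the
  inverse mixed-model coefficient matrix, and r_yŷ = √(1 − PEV/σ²_u),
  averaged over individuals.

In the pipeline, the accuracy denominator h²ₐ·h²_g uses heritability on
the **entry-mean** scale, σ²_g/(σ²_g + σ²ₑ/n_blocks), because r_yg is a
correlation with entry means; mixing a plot-scale h² with a mean-scale
r_yg systematically overstates accuracy.  Both scales are written to
the summary.  Accuracies above 1 — which arise when markers capture
more of the entry-mean variance than the heritability product implies —
are clamped to 1 with a recorded warning; the implied QTL count then
degenerates toward 0, which is the internally consistent limit (near-
saturated accuracy implies few effective loci).  Cycle times default to
a phenotypic cycle twice the genomic one; only their ratio matters.

## Cross-harvest transfer

Marker effects are trained on harvest *i* inside the usual CV folds;
each individual's out-of-fold GEBV is correlated with its EBV at
harvest *j*.  EBV are genomic-relationship BLUPs (`Z·â` from a full-data
RR-BLUP fit on harvest *j*) rather than pedigree BLUPs — only parent
counts, not a pedigree, are available — with adjusted phenotypic means
available as an alternative target.  Note one subtlety the test suite
respects: the self pair (i = j) against EBV is optimistically biased,
because the EBV share residual noise with the training records; unbiased
comparisons therefore target held-out phenotypes, which never enter the
training folds.  Transfers are computed for all ordered pairs i ≤ j.

## Numerical and testing choices

Property tests are derandomized (fixed seeds or hypothesis
derandomization).  Sampling-noise-sensitive invariants (cross-harvest
TBV correlation recovery, transfer monotonicity, REML recovery) are
asserted on seed-averaged means, with generator sizes chosen so the
assertion margin is several standard errors: TBV-correlation recovery
uses 2,000 QTL because family structure shrinks the effective QTL count
(the concentration of a correlation between two random linear
combinations of the same genotype columns scales with the effective
number of independent directions, not the nominal QTL count).  The
study-scale end-to-end run (386 × 850 × 3 harvests, tenfold CV, all
transfer pairs) takes roughly 1–2 minutes on one CPU.

## Known limitations

* No genetic map, dominance, epistasis, or multi-harvest joint
  (repeatability / random-regression) model.
* The genomic heritability h²_g is not separately identifiable from
  h²ₐ without an external (pedigree) additive-variance estimate; the
  API accepts a user-supplied value.
* Published accuracy columns for this study system cannot be reproduced
  from the published inputs under any h²_g ≤ 1 and are deliberately not
  targets; only worked examples with fully published inputs are.
* The VCF support is deliberately minimal (GT-only, one pseudo-
  chromosome); it is an interchange format here, not a variant-calling
  surface.
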