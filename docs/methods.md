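# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Trait statistics

HTI is computed per measurement pair as `(loose − tight)/loose × 100` and
averaged over measurement repeats per line.  AUDDC is the trapezoidal
integral of moisture readings over days after pollination (default
measurement days 34, 40, 46, 52, 58); readings are assumed already
converted to moisture units.  Pearson correlation tests use the
t-distribution with n−2 degrees of freedom.

## Multi-environment BLUP and heritability

The phenotype model is `y_ijk = μ + e_i + r(e)_ij + f_k + (f×e)_ik + ε`
with environment and replicate-within-environment treated as fixed and
line / line×environment as random.  Treating environments as fixed
mirrors the structure of the heritability denominator
`h² = σ²_g/(σ²_g + σ²_ge/e + σ²_e/(re))`, which divides the interaction
and residual components by the known numbers of environments (e) and
replicates (r).

Balanced designs use the closed-form ANOVA expected-mean-squares solution
(identical to REML in the balanced case): `σ̂²_e = MS_err`,
`σ̂²_ge = (MS_GE − MS_err)/r`, `σ̂²_g = (MS_G − MS_GE)/(er)`, each
truncated at zero (the REML boundary convention).  The per-line BLUP is
`μ̂ + h²·(ȳ_k − μ̂)`, i.e. the line mean shrunk by exactly the
heritability ratio, with μ̂ the grand mean — "BLUP = mean + predicted line
effect".  Unbalanced designs fall back to numerical REML (statsmodels
MixedLM with a per-environment variance component for the interaction).

Degenerate designs: with a single environment no interaction component is
identifiable (fit proceeds without it, with a warning); with one
observation per line the genetic and residual variances are confounded on
a flat likelihood ridge, and the fit resolves the tie by attributing all
line-to-line variance to genetics, so BLUPs equal the raw values.  This
convention makes the no-noise limit exact.

## Synthetic panel generator

The generator emulates a maize association panel: 438 inbred lines in
four subgroups (121 NSS, 30 SS, 186 TST, 101 MIXED), phenotyped in 3
environments × 2 replicates, with a husk-tightness-like trait of
broad-sense heritability 0.41.

* **Structure.** Ancestral allele frequencies are Uniform(0.05, 0.95);
  each pure subgroup draws Balding–Nichols Beta frequencies with its own
  divergence parameter (defaults NSS 0.08, SS 0.12, TST 0.15 — temperate
  pools modest, tropical-subtropical most diverged).  MIXED lines use a
  per-line Dirichlet(1,1,1) convex mixture of the three pure frequency
  vectors, giving a genuinely admixed, heterogeneous subgroup.
* **LD.** Markers are grouped into blocks (default 10 per block, nested
  in 10 chromosomes).  Within a block, haplotype alleles follow a
  first-order Markov copying process: allele j equals allele j−1 with
  probability c, else a fresh draw.  Adjacent-marker r² is c² in
  expectation (so `within_block_r2` parameterizes it directly) and decays
  geometrically with distance; blocks are independent.  One frequency is
  drawn per block so that copying preserves marginal frequencies exactly
  and `within_block_r2 = 1` makes blocks literal marker copies.
* **Inbreeding.** The second gamete copies the first with probability
  0.95 (inbred lines with residual heterozygosity); dosages are 0/1/2.
* **Trait.** Oligogenic architectures draw ≤ 20 large effects; polygenic
  architectures draw Gaussian effects on at least half the markers.  TBV
  is the exact linear score of the raw dosages.  GxE deviations are
  independent Gaussians per line×environment with variance
  `gxe_var_frac·σ²_g` (default 0.2 — no mechanism beyond a variance split
  is modeled), and the residual variance is solved from the heritability
  identity so the expected h² equals the target.  `h2_target = 0`
  produces a pure-noise trait: the drawn effects and TBV stay in the
  truth record but do not enter the phenotype (the only way to have a
  well-defined null trait with a nonconstant recorded TBV).
* **Moisture series.** Dry-down curves decline at 1.2 %/day from ~55% at
  day 34; a per-line latent wetness term, correlated with the supplied
  HTI values at a subgroup-specific target, shifts the whole curve, so
  AUDDC inherits approximately the target correlation (negative in
  temperate subgroups, near zero in TST, as configured).

What the generator does **not** emulate: recombination maps and LD decay
over physical distance, allele-frequency spectra of real SNP arrays,
selection or pedigree structure, non-Gaussian GxE, spatial field trends.
Passing tests therefore demonstrate correctness and calibration of the
*methods*, not expected prediction abilities on any real panel.

## Marker QC, imputation, LD pruning

QC keeps markers with MAF ≥ 0.05 and missing rate ≤ 0.2 (both inclusive);
removal reasons are attributed MAF-first except that fully missing
markers (undefined MAF) count against the missing rule.  Imputation is
per-marker mean (fractional dosages allowed) or mode (ties toward the
smaller dosage).  The original multi-tool filter/impute/refilter loop is
collapsed to filter → impute → (optional) refilter, which reaches the
same invariant endpoint: a clean, imputed, QC-passing matrix.

LD r² is the squared Pearson correlation of dosage columns over pairwise-
complete lines; monomorphic columns give an undefined (NaN) value.
Pruning is sliding-window greedy per chromosome (window 50 markers, step
5 — the common indep-pairwise default): while any kept pair in the window
has r² strictly above the threshold, the pair member with the higher mean
r² to the other kept window markers is removed (ties toward the later
position).  Strict inequality makes threshold 1.0 an exact no-op.
Because window/step and tie-breaks are tool-specific, kept-marker counts
are reproducible for this implementation only, not bit-identical to any
external pruner.

## GS models

All models fit an intercept as the only fixed effect and center marker
columns by training means; effects are per-allele (no variance
standardization).  GEBVs are exact linear scores, so prediction on the
training matrix reproduces fitted genetic values.

**rrBLUP.** REML on the variance ratio λ = σ²_e/σ²_u via the spectral
decomposition of the intercept-projected `ZZ'`; 1-D bounded maximization
on log λ ∈ [−10, 10] with tolerance 1e-8.  A fixed λ can be supplied, in
which case the estimator is the exact (dual) ridge solution — verified
against the primal closed form to 1e-8.

**Bayesian alphabet.** Single-site Gibbs sampling, default 5000
iterations / 1000 burn-in / thin 5 (no lengths are canonical; these are
desk-scale defaults, and the experiments use shorter chains sized to
their problem).  Hyperpriors are weakly informative scaled-inv-χ² with 5
degrees of freedom and mode-matched, data-scaled scale parameters
attributing half the phenotypic variance to markers a priori; π (the
point mass at zero for BayesB/C, parameterized as the exclusion
probability) has a Beta(1,1) prior and is sampled unless fixed.  The
Bayesian LASSO uses the exponential scale-mixture representation with
inverse-Gaussian updates for the local scales and a Gamma(1.1, ·)
hyperprior on λ² whose mean matches the same variance heuristic.  Chains
are bit-deterministic given the seed.

## Cross-validation design

Repeated random splits (Monte-Carlo CV) implement the repeated
"take out x% as training" procedure; a fold-based reading of the same
design would change only the dependence between repeats, not the
estimand, and the random-split description is the one implemented.
Test-set sizes round half away from zero.  Per-repeat generators derive
from (master seed, CRC of the cell identifier, repeat index), so the full
factorial table is reproducible and independent of execution order.  The
cell identity excludes the model name: different models of the same
design cell are scored on identical split sequences, making model
comparisons paired (otherwise "best of k models" gains a selection bias
of the order of the split noise).
Subgroup schemes train inside the focal subgroup and test its remainder
(within) or the remainder plus all other lines (across).  Observed values
are multi-environment BLUPs by default; simulations may substitute the
true breeding values.

Duncan's multiple range test uses studentized-range critical values at
protection levels `1 − (1−α)^(p−1)` with the pooled one-way-ANOVA error
variance (harmonic-mean group size when unbalanced), with the protected
step-down rule that ranges inside a non-significant wider range are not
tested; letters mark maximal non-significant intervals.  Duncan is
deliberately liberal for wide ranges: under a 5-group null at α = 0.05
the widest range is declared significant with probability ≈ 0.18, so all
five groups share a letter in only ≈ 81% of draws — an inherent property
of the procedure, not an implementation artifact.  It is included for
fidelity to common breeding-literature practice; pairwise Welch tests are
the robust alternative for two groups.

## Experiment sizing

The end-to-end experiments (`husk_gs.experiments`) run on desk-scale
panels: 438 lines with 300–2400 markers, 30–50 CV repeats, Gibbs chains
of 1000–3000 iterations.  The density experiment emulates a dense
genotyping array with short blocks (length 4) of near-duplicate markers
(adjacent r² 0.95): real arrays are locally highly redundant, which is
exactly why pruning at r² > 0.1 removes most markers without losing
prediction ability, while pruning at r² > 0.01 starts deleting the only
tag of a block and measurably hurts.  The null-trait calibration redraws
the noise trait on each repeat, because a single finite panel retains an
accidental alignment between kinship and any one noise vector that does
not average away over splits.

## Known limitations

* The unbalanced REML path inherits MixedLM's convergence behavior; very
  sparse line×environment tables may need the balanced subset.
* Gibbs samplers are plain NumPy loops: adequate up to a few thousand
  markers, not for array-scale (10⁵⁺) marker sets.
* Hudson Fst on recorded subgroup frequencies measures the generator's
  divergence parameter, not a finite-sample estimate from genotypes.
* Duncan letters for >26 maximal intervals would exhaust single letters;
  practical group counts never approach this.
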