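# Methods

## Setting

The package implements the statistical side of a candidate-gene
case-control study of xenobiotic-metabolism polymorphisms: a panel of
SNPs and whole-gene deletion loci (scored only present vs. homozygous
null) in three enzyme classes — cytochromes P450 (CYP), esterases, and
glutathione S-transferases (GST) — typed in unrelated cases and
controls with age and sex recorded. The packaged default design mirrors
the reference cohort: 527 cases (270 male / 257 female) and 499
controls (270 / 229), 13 loci (5 CYP, 3 esterase, 5 GST, of which GSTM1
and GSTT1 are deletions), and case/control median ages near 66 and 58
years.

## Statistical primitives

**HWE test.** For genotype counts (n_AA, n_AB, n_BB) the B-allele
frequency q is estimated from the same table and the Pearson χ²
against expected (p², 2pq, q²)·n is referred to χ²₁. No continuity
correction is applied anywhere in the package. Deletion loci carry no
heterozygote information in the present/null coding, so HWE is
undefined for them; the screen flags them untestable and keeps them.

**2×2 odds ratio.** OR = ad/bc with Woolf SE √(1/a+1/b+1/c+1/d) and
Wald 95 % limits exp(log OR ± 1.96·SE). Any empty cell triggers the
Haldane-Anscombe +0.5 correction of all four cells, flagged in the
result; a zero margin leaves the OR undefined and raises. This
closed form is also the independent oracle against which the
regression path is property-tested (saturated exposure-only logistic
log-OR must agree to 1e-6).

**Logistic regression.** Maximum likelihood via Newton iterations
(statsmodels), convergence tolerance 1e-8 on the log-likelihood,
at most 100 iterations. Non-convergence or complete/quasi-complete
separation is flagged rather than reported as a number; separation is
declared when the optimizer fails outright or any coefficient exceeds
15 on the logit scale (an OR above 3×10⁶, never meaningful at n ≈
1000). Wald CIs are used throughout, matching common practice in this
literature; profile-likelihood or Firth-penalised fits are out of
scope.

**Demographics.** Sex is compared by Pearson χ² on the 2×2 table, age
by the two-sided Mann-Whitney U (normal approximation with tie
correction) after a one-sample Kolmogorov-Smirnov check against a
normal fitted by moments. Bonferroni thresholds are α/m, displayed to
4 decimals (0.05/13 → 0.0038, 0.05/11 → 0.0045).

## Single-locus analysis

The control-group HWE screen (default α = 0.05) decides the analysis
set; removed loci also shrink the Bonferroni family. For kept loci the
genotypic model uses two genotype indicators and reports a 2-df
likelihood-ratio P (the natural choice for an adjusted "genotype
frequency difference" test); dominant, recessive and log-additive
models report the Wald P of their single coded exposure. Because
alleles are not independent subjects, an "adjusted allelic" analysis
is ill-defined; the package reports the raw allele-count 2×2 OR as the
allelic result and attaches the covariate-adjusted log-additive OR
alongside it, documenting the distinction instead of silently choosing
one. The effect allele is the second allele in the locus metadata; for
deletion loci the effect state is null.

## Dichotomisation and synergy scan

For the combination analyses each SNP is reduced to two genotype
groups:

1. if the pooled (cases + controls) homozygote-for-effect-allele
   frequency is below 0.05, it is merged into the heterozygote group —
   this merge takes precedence over any model comparison;
2. otherwise the dominant or recessive split with the smaller
   age/sex-adjusted P is adopted, dominant on ties.

Deletion loci keep present/null. The pooled-cohort rare-homozygote
frequency (rather than control-only) is used for symmetry; on the
reference summary counts the two choices agree at every locus, and a
`pool` argument switches the behaviour.

Within an enzyme class of k loci, all 2^k fully-constrained patterns
are tested: a subject carries a pattern when its genotype lies in the
named group at every constrained locus (subjects missing any required
genotype are excluded from that pattern's analysis). Each pattern is a
carrier indicator in an age/sex-adjusted logistic fit. The Bonferroni
family size for the scan defaults to the number of panel loci,
mirroring the reference analysis' reuse of the locus-level threshold;
a stricter per-class 2^k family is available via the `m` argument.

**Backward elimination.** Starting from the smallest-P fully
constrained pattern, every pattern obtained by wildcarding exactly one
constrained locus is evaluated; the walk moves to the smallest-P
successor (ties: larger |log OR|, then lower locus index) and stops at
two constrained loci — single-locus effects belong to the single-locus
stage. The full visited path is reported; the "core" is the minimum-P
pattern on it (ties: fewer constrained loci). Because wildcarding only
relaxes the carrier predicate, carrier counts are non-decreasing along
the path; this is asserted in tests. The step-selection rule is a
design choice — greedy minimum-P with deterministic tie-breaks — since
alternative backward-elimination variants exist; reporting the whole
path keeps alternative cores visible.

**Sex strata.** Path patterns are re-tested within each sex with age
as the only covariate (sex is constant within a stratum). Degenerate
strata (e.g. zero carriers) propagate the separation flag instead of
failing.

## Synthetic cohorts

The generator emulates the study conditions the analyses assume. Base-
population subjects receive: genotypes drawn independently per locus —
Binomial(2, q) effect-allele dose under HWE for SNPs, Bernoulli(f_null)
for deletions — with q/f_null taken from the published control
frequencies; age from a normal N(62, 12²) truncated to [30, 95]; sex
Bernoulli at the overall design female fraction. Disease follows

logit P(case) = β₀ + 0.05·age + β_sex·sex + Σ log(OR_e)·carrier_e,

where planted effects e are multi-locus state-set predicates with an
optional sex restriction. β₀ is calibrated by bisection on a 20 000-
subject Monte Carlo sample so the expected case fraction matches
527/1026; subjects are then quota-sampled into the four (status, sex)
cells until the exact published counts are reached. One seeded NumPy
generator drives everything, so a seed fixes the cohort file byte for
byte.

Two deliberate deviations from a literal per-group parameterisation:
ages are drawn from a single base distribution and the case-control
age gap *emerges* from β_age = 0.05/yr (drawing ages per group at the
observed medians while also modelling age in the disease model would
double-count the association); the realised medians are ≈ 65.5 / 58.5
versus the published 66 / 58, and tests allow ±3 years for this
calibration. Sex splits are exact by quota construction, which is
unbiased at the default β_sex = 0.

What the generator does **not** emulate: linkage disequilibrium
between loci (the panel spans different genes and the reference
analysis treats loci as independent), population stratification,
genotyping error, missing data (downstream code handles missingness by
complete-case exclusion per analysis, but simulated cohorts are
complete), and any real age/sex-genotype joint structure. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the assumed model, not robustness to confounding in
real cohorts — which is also why planted-parameter recovery, not the
published covariate-adjusted ORs, is the simulation target: the
deposited individual-level ages and sexes would be needed to reproduce
those exactly. The published summary counts support exact arithmetic
checks (allele counts, carrier frequencies, HWE statistics, unadjusted
cross-product ORs) and those are asserted at printed precision.

## Numerical and edge-case choices

- Genotype tokens are unordered allele pairs normalised against the
  metadata allele order ("CT" ≡ "TC"); normalisation is idempotent and
  write-read round trips are exact. Missing sentinel: `NA`.
- Monomorphic HWE tables have zero expected cells; those cells are
  skipped (χ² = 0, P = 1 for a fully monomorphic locus).
- P-values are clamped into (0, 1]; tiny Wald P values never underflow
  to 0.
- Scan results order flagged (separated) fits last; elimination treats
  their P as +∞.
- Simulated ages are rounded to 0.1 years for stable file round trips.
- Problem sizes in tests and the acceptance script (40-200 simulation
  replicates, 100 null scans) were chosen to keep the full suite in
  the low tens of seconds on one CPU while leaving Monte Carlo
  standard errors well inside the asserted tolerances.

## Known limitations

- No exact (Fisher/mid-P) tests, permutation nulls, or Firth
  correction for separated fits; separation is flagged, not rescued.
- Cross-class genotype combinations are out of scope (the synergy
  hypothesis is within-class functional compensation).
- The backward-elimination variant is one of several in the
  literature; conclusions about "the" core pattern should be read with
  the reported path, not just its endpoint.
- The allelic χ²/OR treats alleles as independent, which inflates
  precision under Hardy-Weinberg deviation; the log-additive model is
  the safer adjusted analogue.
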