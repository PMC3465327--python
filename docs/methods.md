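# Methods

## The problem being modelled

A case-control association test is miscalibrated when cases and controls
are drawn unevenly from subpopulations with different allele frequencies.
The degree of miscalibration is summarized by the genomic-control
coefficient λ_GC, the median of the observed per-variant 1-df chi-square
statistics divided by the χ²₁ median (≈ 0.45494): 1 means calibrated,
above 1 means inflated. The package's central object of study is how λ_GC
depends on the minor-allele-frequency category of the variants tested and
on the correction strategy applied, in cohorts whose structure mimics a
national-scale genotype-chip study: many geographic regions, weak overall
differentiation, and rare variants that cluster geographically far more
than common ones.

## The synthetic cohort generator

The generator emulates the statistical structure of a stringently
QC-filtered chip dataset, not raw genotyping:

* **Ancestral MAF spectrum.** Each variant stratum draws ancestral minor
  allele frequencies from a configurable spectrum; defaults are uniform on
  [0.05, 0.5] (common), [0.01, 0.05] (low-frequency) and [0.001, 0.01]
  (rare). The lower truncation at 0.001 reflects chip ascertainment:
  alleles had to be seen before being printed on an array.
* **Regional frequencies** follow the Balding-Nichols model: each region's
  frequency is Beta-distributed with mean p and variance Fst·p(1−p), so
  Fst is directly the Wright fixation index. Fst = 0 short-circuits to
  exact equality (the no-structure null). The default Fst = 0.005 is a
  within-country magnitude; experiments pass their own values.
* **Region-private rare variants.** A configurable fraction of
  rare-stratum variants has its frequency zeroed outside one uniformly
  chosen region. This is the generator's mechanism for the empirical fact
  that rare alleles are young and geographically clustered; the
  Balding-Nichols Beta alone (with a stratum-independent Fst) produces
  *equal* relative differentiation at all MAF, which would make rare and
  common variants equally confounded — contrary to what real cohorts
  show. The default private fraction is 0.05 for a 12-region panel; the
  confounded scenario (below) uses 0.5.
* **Genotypes** are Binomial(2, f_region) draws; missingness (default
  0.002, matching a 0.998 call rate) and genotype errors are applied
  afterwards. Errors perturb a call to an adjacent dosage (0↔1↔2, ties
  split evenly) at rate 10⁻⁴. The error rate matters more than it looks:
  error-derived heterozygotes are regionally *unstructured*, so once their
  rate approaches the true carrier frequency of rare alleles
  (10⁻³–10⁻²), they simultaneously push rare variants into higher MAF
  bins and dilute the very clustering under study. 10⁻⁴ is the magnitude
  consistent with the multi-step QC the generator emulates (calling
  probability > 0.99, call rate ≥ 0.99, HWE at 10⁻⁸); pushing it to 10⁻³
  visibly destroys rare-variant structure and is a useful sensitivity
  experiment, not a default.
* **Case assignment** is a label-assignment scheme, not a disease model:
  each region has a case fraction, applied as an exact count
  (deterministic mode, the default — so a 146-individual region at
  fraction 59/146 has exactly 59 cases) or as Bernoulli draws.
* **Determinism.** One global seed fans out through independent
  `SeedSequence` substreams per stage (frequencies, private-region choice,
  genotypes, missingness, errors, cohort split), so any stage can be
  reasoned about in isolation and identical configs are bit-for-bit
  reproducible.

What the generator does *not* emulate: linkage disequilibrium beyond what
binomial sampling induces (the LD-pruning stage is still exercised — on
simulated data it mostly removes chance correlations), haplotype
structure, batch effects between the two control cohorts (they are
exchangeable by construction), and chip ascertainment beyond the MAF
truncation. Passing tests on this cohort therefore demonstrate the
correctness and calibration of the statistical machinery, and the
qualitative mechanism of frequency-dependent stratification; they do not
certify quantitative transfer of any λ value to a particular real cohort.

## Quality control

Variants pass QC iff (in order, each variant counted at its first failing
filter): present in every cohort; call rate ≥ 0.99 in every cohort; exact
Hardy-Weinberg p ≥ 10⁻⁸ in the pooled controls. The HWE test is the exact
conditional test (probability-ordering two-sided, enumerating heterozygote
counts given the minor-allele total with log-factorials): at α = 10⁻⁸ the
decision sits so deep in the tail that the chi-square approximation is
unusable for rare alleles. A chi-square variant is available behind a flag
for cross-checking at common frequencies. Missing genotypes are excluded
from both numerator and denominator of all frequency computations; a MAF
of exactly 0.5 is attributed to allele2 deterministically.

## MAF categories and sharing

Categories: common (MAF ≥ 0.05), low-frequency (0.01 ≤ MAF < 0.05), rare
(MAF < 0.01 and minor allele in more than `copy_threshold` = 2 copies),
others (≤ 2 copies; genotyping-artifact-prone and excluded downstream).
Boundary values go to the more common category. Rare splits at MAF 0.005
into very-rare and less-rare.

A variant is "present" in a region iff at least one minor-allele copy
occurs among the region's called genotypes. The expected proportion of
variants present in *all* regions under homogeneity treats a variant's c
minor-allele carriers as allocated without replacement over individuals
(multivariate hypergeometric over region sizes);
P(every region ≥ 1 carrier) is computed by inclusion-exclusion over region
subsets, grouped by subset-size total and cached per c (exact integer
binomials), or by Monte-Carlo as a cross-check. c below the region count
gives probability 0 by pigeonhole.

Per-individual burden is the sum of minor-allele dosages over a category's
variants, with missing genotypes contributing 0 — a burden is a carrier
count and imputation would manufacture rare alleles. Burden differences
across regions use the tie-corrected Kruskal-Wallis test.

λ_r generalizes genomic control to any homogeneity test: under the null
the p-values are uniform, −2·ln p is χ²₂, and
λ_r = median(−2·ln p)/(2·ln 2) is 1. The natural logarithm is the correct
base (it is what makes the quantity χ²₂); p = 0 inputs are clipped to the
smallest positive float with a warning.

## PCA and supervised ancestry

LD pruning is the greedy 50-variant / 5-step / r² > 0.2 sliding-window
protocol; within a window the lower-MAF member of an offending pair is
removed (tie → later position) — the tie rule is a determinism choice.
PCA normalization is: mean-center each variant, mean-impute missing
dosages, and (with frequency weighting on) divide by √(p̂(1−p̂)) with the
posterior-mean estimate p̂ = (1 + Σg)/(2 + 2n), which keeps rare-variant
weights finite. Scores and eigenvalues come from an SVD; the proportion of
variance explained is eigenvalue over the sum of all eigenvalues. Each
component's sign is fixed by making its largest-magnitude loading
positive. No outlier-removal iterations are performed (flag available
in spirit — the iteration count of reference implementations is not part
of the model).

Supervised ancestry fixes per-region allele frequencies from a labelled
reference panel with a pseudocount of 0.5 per allele and maximizes, per
target individual, the binomial log-likelihood of its dosages under a
simplex-constrained mixture q of region frequencies, by EM (the standard
allele-responsibility update; the log-likelihood is asserted
non-decreasing every iteration). This is a deliberate simplification of
block-relaxation implementations; it is validated by parameter recovery,
not output-file equality. Two regimes matter:

* With real differentiation (Fst = 0.2, K = 3, 2,000 variants) argmax
  assignment recovers the true region for ≥ 95% of targets.
* In the unidentifiable limit — reference frequencies exactly equal across
  regions — the likelihood is flat in q and EM provably stays at uniform
  1/K: nobody clears the 0.5 confidence threshold. With *estimated*
  frequencies from finite panels at Fst = 0, the ML solution instead
  chases sampling noise into simplex corners; assignments can look
  confident but are correct no more often than the random-corner baseline
  1/K. Both behaviours are real properties of supervised ancestry methods
  and both are tested; consumers should treat confident assignments in
  weakly differentiated cohorts with suspicion.

## Association tests and the λ grid

* **Trend (raw):** statistic N·r²(g, y), p from χ²₁; missing dosages
  dropped pairwise. Constant input → (0, 1).
* **PC-adjusted:** residualize dosage and phenotype on k PCs plus
  intercept; statistic (N−k−1)·r² of the residuals. At k = 0 this is
  (N−1)/N times the trend statistic — the tests assert that exact
  relation. The vectorized scan mean-imputes missing dosages before
  residualization (the standard treatment); the single-variant function
  drops missing pairs.
* **CMH:** 2×2×K allelic test (case/control × allele counts per stratum),
  no continuity correction; with one stratum it equals the (N−1)-scaled
  allelic chi-square. Permutation p-values shuffle phenotypes within
  strata, 10,000 by default, with the add-one correction
  (b+1)/(n_perm+1). The permutation null conditions on the observed
  genotypes, so it absorbs the HWE-departure overdispersion that the
  allele-count asymptotic ignores — the two p-values agree only up to
  that dispersion factor, which is precisely why permutations are worth
  their cost on real data.
* **Mixed model:** y = μ + u + ε with u ~ N(0, σ²_g K), K the genetic
  relatedness matrix Z·Zᵀ/m over standardized dosages. The variance ratio
  δ = σ²_e/σ²_g is fitted once under the null by REML — a 1-D bounded
  search on log δ over [10⁻⁵, 10⁵] (tolerance 10⁻⁶) after
  eigendecomposition of K restricted to the intercept's complement. Each
  variant is then tested by weighted least squares in the kinship
  eigenbasis with δ fixed, F(1, n−2). With K = I the weights are constant
  and the p-values equal ordinary regression exactly; δ at the upper
  bound flags an effectively zero genetic variance (the no-structure
  null) and reduces to OLS. The binary phenotype is treated as
  quantitative 0/1, as the mixed-model convention goes.
* **λ_GC:** computed from statistics directly for trend/CMH/PC-adjusted
  scans, and from p-values through the inverse upper-tail χ²₁ transform
  for the mixed model (whose native statistic is an F). The grid reports
  one λ per method × category, categories being common, low-frequency,
  rare, and the rare subdivision at MAF 0.005. Variants with no dosage
  variation among called genotypes in the scan cohort carry no test and
  are excluded from the medians (an analysis tool would report them NA);
  this matters when a panel-wide rare category is scanned in a two-region
  subset where region-private variants of other regions are monomorphic.

## The two canonical studies

**Null calibration** (`studies.null_calibration`): Fst = 0, two regions of
250 samples, 50,000 common variants, equal case fractions. Raw, CMH,
PC-adjusted (k = 2, 10) and mixed-model λ_GC and the heterogeneity λ_r
all sit in [0.95, 1.05]; the sizes are chosen so the Monte-Carlo
uncertainty of a median over 50,000 draws (≈ ±0.01) is well inside that
band.

**Confounded scenario** (`studies.stratification_scenario`): a 12-region
panel (sizes 252 × 10, plus 146 and 273 for regions R11/R12) at
Fst = 0.05, private-rare fraction 0.5, 25,000/2,900/1,900 variants per
stratum. MAF categories are computed on the full pooled panel; the scan
then uses only the 419 R11/R12 individuals with exactly 59 (40.4%) and
150 (54.9%) cases. The two design choices that matter, both mirroring how
such an analysis is actually run: categories from the full control panel
(categorizing on the 419-individual subset would re-bin the most
stratified rare variants into the low-frequency category), and
untestable-in-subset variants excluded from the medians. The resulting
grid reproduces the qualitative ordering: raw λ(rare) ≈ 2.2 ≫ raw
λ(common) ≈ 1.3; CMH calibrates common variants (≈ 1.0) but stays
inflated for rare; PC adjustment matches CMH for common variants; the
mixed model does not rescue rare variants.

## Numerical and degenerate-input conventions

Degenerate inputs return defined values rather than raising where a scan
must keep going: constant genotype → statistic 0 / p 1; degenerate
heterogeneity table → p 1 with a warning; no informative CMH stratum →
p 1 with a warning; empty λ category → NaN cell. Monomorphic columns are
dropped (with warnings) from PCA and the GRM. All permutation and
simulation seeds are explicit; the pipeline manifest records the config
hash and a checksum per artifact, and re-running a stage from its
serialized inputs reproduces its outputs exactly.

## Known limitations

Binary phenotypes are tested with linear machinery throughout (trend,
residual correlation, linear mixed model), as the corresponding reference
methods do; no logistic models. No gene-based collapsing tests, no
covariates beyond PCs, no sex chromosomes or multi-allelic variants, no
VCF. The simulator's independence across variants means LD-based
operations are exercised structurally rather than stressed; and every
quantitative λ value is a property of the simulated design, not a
prediction for any particular real cohort.
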