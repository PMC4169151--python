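# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the shipped tests do and do not demonstrate.

## Genotype datasets

Starting from a raw lines × SNPs matrix of 0/1/2 reference-allele counts
with per-line family labels and a physical map (1-based bp), two datasets
are built.

**Trimming** (applied first, shared by both): SNPs with a missing fraction
strictly greater than 5% are removed; then, scanning each chromosome in
position order, a SNP strictly closer than 64 bp downstream of the
previously retained SNP whose genotype column — including its missing
pattern — is bit-identical is removed, keeping the left-most of the pair.
All three thresholds here and below are strict inequalities, taken
literally from their usual statement.

**GWAS dataset.** The trimmed matrix on the shared allele orientation, with
residual missing cells filled by the within-family SNP mean rounded to the
nearest integer (half away from zero), falling back to the overall SNP mean
when a family has no observed call. Rounded within-family mean filling
preserves the within-family allele frequency; it stands in for a haplotype
based imputation of the raw calls, which is out of scope. A SNP fixed at
0 in one family and at 2 in another is retained as such — this fixation
contrast between families is exactly what lets a single-effect model absorb
between-family variance. Mapping statistics are invariant to a global
allele-orientation flip (g → 2 − g), which is covered by a test.

**Linkage dataset.** Per family: progeny alleles matching the SC parent
count 0 per copy, those matching the EP parent count 2 (parents must be
homozygous where polarized); SNPs at which the two parents agree are set
entirely missing; progeny alleles present in neither parent are counted and
set missing. Chromosomes, and maximal monomorphic runs whose flanking
polymorphic markers are more than 10 Mb apart, are treated as
non-segregating for that family: their cells stay missing, are excluded
from that family's scan, and are never bridged by imputation. All other
missing cells are imputed per line as the mean of the nearest flanking
non-missing *original* values weighted by physical distance:

    v = (v_L * d_R + v_R * d_L) / (d_L + d_R)

with single-flank cells taking the nearest value (the degenerate limit of
the formula). Chained imputation (imputed cells serving as flanks) is
deliberately not used; where the two conventions disagree the canonical
worked example is reproduced only by the nearest-original-value rule (its
one cell commonly quoted as 1.34 is exactly 4/3 under the weighting
formula and is asserted as such).
Imputation is idempotent and bounded by the convex hull of the flanking
values; both are property-tested.

## Mapping models

All models are ordinary least squares of the phenotype on expected allele
dosage (Haley–Knott regression on 0–2 codes; heterozygotes enter linearly,
no dominance column). The base design is an intercept plus one indicator
per family beyond the first (family as a fixed covariate — the lm-style
machinery the approach is built on). Candidate term for SNP j:

* *gwas*: one column, the pooled 0–2 code;
* *joint_linkage*: one column per included family in which the SNP
  segregates (the family's linkage code, zero elsewhere);
* *biparental*: the single-family special case of the above (verified to
  give identical selections, effects and adjusted R² to joint linkage on
  one family).

**Selection statistic.** The partial F of the candidate block given the
current model. Nested blocks carry one df per segregating family, so F
puts 1-df GWAS candidates and k-df nested candidates on a common scale; the
permutation threshold is computed on the same statistic, keeping the
comparison internally consistent. A p-value variant (select by smallest p,
threshold on −log₁₀ p) is available via `ModelSpec.select_by` because
multi-df F values are not directly comparable to 1-df ones; the F variant
is the default.

**Permutation threshold.** Phenotype values are shuffled independently
within each family (family labels and genotypes fixed), the genome-wide
maximum statistic recorded per permutation, and the threshold taken as the
⌊nα⌋-th largest of the n permuted maxima (1000 permutations at α = 0.01 →
the 10th largest). A fresh exchangeable draw exceeds that order statistic
with probability ⌊nα⌋/(n+1) ≈ α, so the rule is calibrated to within
discreteness; the shipped calibration experiment measures the realized
genome-wide error over 1000 fresh null replicates across 10 independent
genotype/threshold batches. The null is computed once against the base
model and reused at every forward step (recomputation per step is available
behind `threshold_per_step` but costs a full permutation pass per step);
permutation i draws from a deterministic substream of the model seed so
individual permutations are replayable, and the permutation loop can be
threaded over fixed-size chunks without changing results.

**Forward selection** adds the best candidate while its statistic strictly
exceeds the threshold, refits all effects jointly after each addition, and
stops at the threshold or a configurable maximum of 10 steps. Exactly tied
statistics resolve to the smallest (chromosome, position). Rank-deficient
augmentations are recorded as not-tested; rank deficiency in the final
joint fit is resolved by deterministic left-to-right dropping of dependent
columns. Reported per-term effects are slopes on the 0–2 dosage (trait
units per allele copy, i.e. half the fitted homozygote difference), with
`NS` for families in which a selected SNP does not segregate; adjusted R²
is 1 − (1 − R²)(n − 1)/(n − p − 1).

The scans are vectorized: candidate columns are residualized against an
orthonormal basis of the base design once, so a whole-genome scan (and the
entire permutation null) reduces to matrix products plus, for nested
candidates, batched k × k solves.

## Synthetic data

The generator emulates the conversion-program design rather than
sequence-level reads. Founder pairs are drawn per family: isogenic
families differ only inside specified introgression segments; families from
related/unrelated parents differ at each locus independently with a set
density (defaults 0.35 and 0.8, spanning the observed gradient from ~1% to
~80% of the genome segregating). The elite-donor allele is the global
reference; monomorphic background sites share a Bernoulli(0.3) allele per
family, producing both 0-fixed and 2-fixed SNPs across families. Any QTL
with a non-zero effect in a family is forced polymorphic there (and must
lie inside a segment for isogenic families — a configuration error
otherwise).

Meiosis is Haldane (no interference): Poisson crossover counts with mean
equal to the chromosome's genetic length, breakpoints uniform in genetic
distance, mapped to bp through a piecewise-linear genetic map (linear by
default; the demo compresses 20–45 Mb of chromosome 1 to mimic suppressed
pericentromeric recombination). An F2:3 line is represented by its F2
parent's diplotype — the dosage expectation of the selfed F3 pool — so
codes stay integral.

Phenotypes follow trait = family offset + Σ_QTL [a·(g−1) + d·1(g=1)] +
N(0, σ²), with g counting the late/tall (EP) allele. The photoperiod locus
defaults to full dominance (d = a) in sensitive families; flowering values
above 138 days are truncated to 138 and flagged censored (value truncation,
not survival modelling). Row flowering can be scored as the mean of the
25%- and 75%-anthesis dates. GBS-like missingness is independent per cell,
scalar or per-SNP (the demo plants five SNPs at 30% missingness to exercise
the trim filter). Residual SDs and family offsets are not constrained by
any measured quantity; defaults (σ_FL = 5 d, σ_HT = 12 cm against additive
effects of 5–45 units) were chosen once so that single-family QTL models
explain on the order of 70–85% of phenotypic variance, the regime typical
of major-gene traits in such material.

Everything is bit-reproducible from (specification, seed); seeds spawn
per-family and per-stage substreams.

### The packaged demo (seed 1402)

Five families over three 60-Mb chromosomes with 200-kb marker spacing. A
photoperiod/flowering locus at chr1:40.27 Mb carries a = 5.3 d in the two
nearly isogenic families A/B and a = 19.3 d (dominant) in C, D
(related parents) and E (unrelated parents); the A/B and C introgression
segments overlap only in a 60-kb marker-free window around the causal
position, so no marker segregates in all five families — by construction,
not by chance. A height locus at chr2:58.56 Mb segregates with equal
effects (45 cm) only in C and E (two equivalent knockouts), and a second
height locus at chr1:44.4 Mb (A/B only) sits 4.1 Mb from the photoperiod
locus to allow fusion-type mislocalization. At the shipped seed the
single-effect model splits the allelic series (first SNP 2.13 Mb off,
large effect; second SNP, small effect) while the nested model enters the
region at 0.87 Mb, and the single-effect model tags the equivalent-knockout
locus at least as tightly as the nested model — the package's central
qualitative reproduction. These orderings are asserted for the shipped
seed; across arbitrary seeds the margins vary with the realized
recombination and family-E polymorphism pattern. A stripped single-locus
variant (`allelic_series_scenario`, asserted at seed 21) shows the pure
form: one nested step versus two-or-more single-effect steps.

## What the tests show — and what they do not

The simulator omits genotyping error, segregation distortion, residual
heterozygosity in parents, multi-generation selfing structure within F3
rows, linkage-map error and real LD between founder genomes. Passing tests
therefore demonstrate correctness of the encoding, scanning, thresholding
and selection machinery and the qualitative model-comparison phenomena
under a faithful but idealized genetic model; they do not certify
positional accuracy or effect calibration on real GBS data, and no numeric
result from the motivating field study is asserted anywhere (that study's
raw data are not deposited). Scaled problem sizes — 1000 SNPs, 5 × 120
lines for calibration; 100 replicates for parameter recovery — were chosen
as desk-scale defaults; all scale linearly if enlarged.

## Numerical choices and edge cases

* Strict thresholds: >5% missing, <64 bp, >10 Mb, statistic strictly
  greater than threshold.
* Collapse tie-break: left-most SNP retained; selection tie-break: smallest
  (chromosome, position).
* Columns with residual norm below 1e-9·n are treated as degenerate
  (monomorphic or collinear) and excluded from the candidate df.
* Edge missing cells with a single flank take that flank's value.
* `n_perm < 20/α` triggers an instability warning (which fires at
  1000 permutations and α = 0.01 — retained as specified, since the
  quantile's discreteness is then non-negligible).
* Adjusted R² is undefined for n ≤ p + 1 and raises.
* BED-like interval outputs are 0-based half-open; SNP positions 1-based.

## Known limitations

Censored flowering values enter OLS as truncated observations, slightly
attenuating photoperiod effect estimates (the accepted practical
approximation). The GWAS-dataset mean-fill is a crude stand-in for
haplotype imputation and can only shrink within-family variance. The
permutation null conditions on the observed genotypes and base model only;
with `threshold_per_step` off, later steps reuse a slightly conservative
threshold. Mixed-model kinship correction, epistasis, composite interval
mapping and multi-trait models are out of scope.
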