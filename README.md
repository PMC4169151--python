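# isoqtl

Multiparental QTL mapping in partially isogenic F2:3 families: forward
Haley–Knott regression under joint-linkage (family-nested) and GWAS
(single-effect) models, with family-stratified permutation thresholds, the
two genotype dataset dialects those models require, and a synthetic-data
generator that emulates sorghum-conversion crosses carrying allelic series
at major loci.

## The problem

Sorghum conversion bred short, early, photoperiod-insensitive versions of
tall tropical landraces by introgressing small elite-donor segments into
exotic backgrounds. Crossing a converted line (SC) back to its exotic
progenitor (EP) yields a *partially isogenic* F2:3 family that segregates
only inside the introgressed regions — ideal material for mapping the major
dwarfing (*Dw1–Dw3*) and maturity (*Ma1*) loci. Pooling several such
families raises power, but the same locus often carries functionally
different alleles in different families (an *allelic series*), and no single
SNP may segregate in all families. Two multiparental models handle this
differently:

* **joint linkage** — each marker gets one coefficient per family in which
  it segregates (effects *nested within family*), with family as a fixed
  covariate, fitted on a parent-of-origin coded "linkage" dataset;
* **GWAS** — each marker gets a single coefficient across all families on
  the shared reference-allele coding.

For phenotype $y$, marker dosage $g \in [0,2]$ and families $f$:

$$\text{joint linkage:}\quad y = \mu + \sum_f \beta_f\,\mathbb{1}[f] + \sum_f a_f\, g\,\mathbb{1}[f] + \varepsilon
\qquad\text{GWAS:}\quad y = \mu + \sum_f \beta_f\,\mathbb{1}[f] + a\,g + \varepsilon$$

Haley–Knott regression means ordinary least squares of $y$ on expected
dosage. Forward selection adds, at each step, the marker with the largest
partial-F statistic for its term block (1 df for GWAS, one df per
segregating family for nested terms), while it exceeds a genome-wide
threshold obtained from permutations of phenotypes *within each family
separately* (default 1000 permutations, genome-wide α = 0.01, threshold =
the ⌊nα⌋-th largest permuted maximum).

The nested model can absorb an allelic series at one marker in one step but
tends to fuse linked QTL; the single-effect model splits an allelic series
across several markers (and can produce *synthetic associations* between
linked heterogeneous loci) but tags multi-knockout loci whose alleles are
functionally equivalent very precisely. The package reproduces this
contrast end to end on simulated families.

## Worked example

The packaged demonstration simulates five families (A–E): A/B nearly
isogenic carrying a small-effect early allele at the chromosome-1
photoperiod locus (a = 5.3 d), C/D/E carrying a large-effect dominant
allele (a = 19.3 d), plus a two-knockout height locus on chromosome 2
segregating only in C and E. No marker segregates in all five families.

```python
import isoqtl as q
from isoqtl.evaluate import run_demo, first_entry_distance

run = run_demo(subsets=("ABCDE",), traits=("FL",))
for kind in ("gwas", "joint_linkage"):
    res = run.results[("FL", "ABCDE", kind)]
    print(kind, f"r2_adj={res.r2_adj:.3f}")
    print(q.estimate_effects(res).to_string(index=False))
    print("first-entry distance to locus (Mb):",
          round(first_entry_distance(res, "1", 40_270_000) / 1e6, 2))
```

prints

```
gwas r2_adj=0.847
 step      snp_id chrom   pos_bp       fstat  combined  state_A  state_B  state_C  state_D  state_E
    1 S1_42400000     1 42400000 1044.623703 19.269807        2        0        1        1        1
    2 S1_40000000     1 40000000   45.752312  5.089220        1        1        2        0        0
first-entry distance to locus (Mb): 2.13
joint_linkage r2_adj=0.850
 step      snp_id chrom   pos_bp      fstat         A         B          C         D         E
    1 S1_39400000     1 39400000 249.109359        NS        NS         NS 14.598568 10.742214
    2 S1_41400000     1 41400000  87.958437  5.480747  4.945093  20.096175  4.241560  8.437581
first-entry distance to locus (Mb): 0.87
```

Read this as the allelic series splitting under the single-effect model:
GWAS first selects a SNP 2.13 Mb from the true locus that is fixed for
opposite alleles in A/B vs (segregating in) C/D/E and carries the
large-allele effect (19.3 d), then needs a second SNP for the small
A/B allele (5.1 d). Joint linkage enters the region 0.87 Mb from the locus
and by step 2 fits the full series per family (≈5 d in A/B, ≈20 d in C);
`NS` marks families in which a SNP does not segregate. Both models explain
≈85% of the phenotypic variance, with the nested model using per-family
effects and the combined model using more markers.

The command-line interface exposes the same pipeline
(`isoqtl simulate | encode | map | evaluate | report | demo`); every run
writes plain TSVs plus a manifest (config hash, seed, versions), and
`isoqtl demo --seed 1402 --out demo/` is byte-reproducible.

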