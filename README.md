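# breedscan

Across-breed genome-wide association for cohorts that have genotypes but no
individual phenotypes.

## The problem

Sequencing repositories such as multi-breed dog WGS collections hold hundreds
of genomes but essentially no per-animal disease records. What *is* known is
breed epidemiology: the prevalence of hip dysplasia, elbow dysplasia, or
cruciate-ligament rupture in each breed. Because strong artificial selection
and bottlenecks have driven large-effect risk alleles toward fixation within
breeds, a disease prevalence attached to every member of a breed — a
*categorical* or breed phenotype — still carries mappable signal: variants
whose frequencies track prevalence across breeds.

`breedscan` implements that design end to end: quality control and two-stage
variant/sample filtering with a full accounting ledger, verification of breed
labels by bootstrapped phylogenies, population-structure correction with a
genomic relatedness matrix, four association models, significance machinery
(Bonferroni, Benjamini–Hochberg FDR, genomic inflation λ, QQ/Manhattan data,
region collapsing, gene annotation), and a synthetic multi-breed cohort
simulator so every stage is testable without any external data.

## The four models

With dosages `x_ij ∈ {0,1,2}`, breed prevalence `y` broadcast to individuals,
covariates `W` (intercept, sex), and the centered genomic relationship matrix
`K = (1/p) Σ_s (g_s − ḡ_s)(g_s − ḡ_s)ᵀ`:

1. **Linear mixed model** — `y = Wα + xβ + u + ε`, `u ~ N(0, σ²_g K)`,
   `ε ~ N(0, σ²_e I)`. The ratio `r = σ²_g/σ²_e` is REML-profiled on a log
   grid over [1e−5, 1e5] with golden-section refinement; each SNP gets a Wald
   test `(β̂/se)²` against `F(1, n−c−1)`.
2. **Binary case-control** — breeds dichotomized into low-risk controls
   (prevalence ≤ low cut) and high-risk cases (≥ high cut), intermediate
   breeds excluded; the same mixed-model machinery on the 0/1 trait.
3. **Sliding-window haplotype model** — fixed 4-SNP windows sliding by one;
   haplotype frequencies estimated by EM from unphased genotypes, rare
   haplotypes (< 1%) pooled; an omnibus F-test of expected haplotype dosages
   over eigenvector covariates; per-SNP p is the minimum over covering
   windows.
4. **Weighted least squares on breed averages** — collapse to a breeds × SNPs
   matrix `X` of mean dosages, then per SNP
   `lm(y ~ pc1+…+pc5 + x_j, weights = n_b/N)`: the weights are breed sample
   proportions, so breeds represented by one dog count for little. This is
   the model built for heavily unbalanced repositories.

Breed-label verification: 100 site-bootstrapped identity-by-state distance
matrices → neighbor-joining trees → strict majority-rule consensus; samples
that fall outside the clade holding most of their breed-mates are flagged and
excluded.

## Worked example

```python
import breedscan as bs
from breedscan.kinship import centered_grm
from breedscan.simulate import SimConfig, generate_study

cfg = SimConfig(seed=42)              # 30 breeds, 5000 SNPs, 1 planted causal SNP
gm, panel, truth = generate_study(cfg)

K = centered_grm(gm)
y = bs.broadcast_phenotype(panel, "sim", gm.samples)
res = bs.lmm_scan(gm, y, bs.build_covariates(gm.samples), K, per_snp_r=False)

print(bs.genomic_lambda(res["p"]))                  # 1.02
print(bs.bonferroni_threshold(0.05, len(res)))      # 1.00e-05
print(res.nsmallest(3, "p")[["chrom", "pos", "beta", "se", "p"]])
```

Output on this seed (285 dogs, breed prevalences 2.5–20.7%):

```
chrom     pos      beta       se        p
 chr7  679364  0.009648 0.002151 0.000011
 chr5 1691531 -0.010126 0.002625 0.000142
 chr8 1669651 -0.008253 0.002263 0.000316
```

The top hit, chr7:679364, is exactly the planted causal variant
(`truth.causal_indices[0]`), and it passes genome-wide significance in the
weighted least-squares scan (`bs.wls_scan` → p = 9.4e-07 < 1e-05). λ ≈ 1
says the mixed model has absorbed the breed structure; β is per alt-allele
copy on the prevalence scale.

The same workflow runs from the shell:

```bash
breedscan simulate --seed 42 --out study/
breedscan run --config study.json        # QC → verify → GRM → scans → summaries
```

A built-in example phenotype table, `bs.ofa_panel()`, holds published OFA
registry hip/elbow dysplasia prevalences for the 37 breeds of a 230-dog WGS
cohort, illustrating the unbalanced breed sizes (1–51 dogs) the weighted
model is designed for.

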