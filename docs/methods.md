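# Methods

## Scope and data model

`breedscan` performs genome-wide association when the phenotype is an
attribute of a *breed* — a disease prevalence — rather than of an individual.
The central container is a samples × variants matrix of alternate-allele
dosages (0/1/2, NaN for missing) with per-variant annotations (chromosome,
1-based position, alleles, site quality, allele count) and per-sample
annotations (id, breed, sex). Coordinates are 1-based inclusive everywhere
internally and in VCF; BED input is converted from 0-based half-open at the
boundary. Multi-allelic records are retained on ingestion with their allele
count recorded; dosages count copies of the first ALT allele, and the
site-quality filter removes non-biallelic records before any analysis.

## Filtering protocol

Two stages, each with a conservation-checked ledger (input = retained +
removals at every stage).

**Stage 1 (site quality).** Keep biallelic SNVs with QUAL ≥ 20 (the
threshold is strict on the low side: QUAL 19.99 is removed, QUAL 20.0 kept).
Removal reasons are attributed in a fixed order — multi-allelic, then
indel/non-SNV, then low quality — so counts are reproducible.

**Stage 2 (genotype QC).** Order matters and is fixed:

1. samples with call rate ≤ 0.90 are removed first;
2. sites with call rate ≤ 0.99 (computed on the remaining samples);
3. sites with minor allele frequency ≤ 0.05, MAF computed from non-missing
   calls after sample removal — sites monomorphic at that point have MAF 0
   and leave via this rule;
4. heterozygous-haploid handling: haploid cells are male calls on
   chromosomes declared haploid in a chromosome-config JSON (no
   pseudoautosomal inference). The default policy removes any site with a
   heterozygous haploid call; a `set_missing` policy instead blanks the
   offending cells before the call-rate stage, matching the other common
   tool convention.

All three rate/frequency cutoffs are *inclusive* removals (a site at MAF
exactly 0.05 goes). Hardy–Weinberg equilibrium is computed for every
retained site with the exact conditional test (summing the probabilities of
heterozygote configurations no more probable than observed, given the allele
counts) but is **reported, not filtered**: the ledger counts failures at
1e-7 and 5e-5, and removal is opt-in via an explicit threshold. The exact
test agrees with brute-force enumeration to < 1e-12 for all genotype totals
up to 50 (tested exhaustively).

## Breed-label verification

An across-breed scan is only as good as its breed labels. Verification uses:

1. **IBS distances** — `d(i,j) = Σ|g_i − g_j| / (2 · #compared)` over
   mutually non-missing sites, equal to `1 − (#IBS2 + ½·#IBS1)/#sites`;
   computed with one-hot matrix products so missingness is pairwise. IBS
   distances satisfy symmetry and identity but are not guaranteed metric;
   no triangle inequality is assumed anywhere.
2. **Bootstrap** — sites resampled with replacement to the original count
   (the standard phylogenetic character bootstrap; samples are never
   resampled), 100 replicates by default, reproducible from one seed.
3. **Neighbor joining** — classical Saitou–Nei agglomeration per replicate;
   Q-criterion ties break to the lowest index pair; negative branch lengths
   are clamped to zero and tallied.
4. **Strict majority-rule consensus** — exactly the bipartitions present in
   more than half the trees, each annotated with its support fraction; no
   greedy/extended resolution, so the consensus can be unresolved where the
   data are.
5. **Outlier flagging** — "did not cluster with its breed" is not a
   self-defining criterion, so the operational rule is: for each breed with
   ≥ 2 samples, its *home clade* is the bipartition side containing > 50% of
   the breed's members that is purest — fewest non-breed members, then most
   breed members, then smallest. Breed members outside the home clade are
   flagged with the clade-membership evidence. Singleton breeds are skipped
   (they cannot cluster). This rule is deterministic, never flags members of
   a monophyletic breed regardless of its internal substructure, and flags
   genetic intruders as soon as the rest of the breed resolves.

On simulated two-level cohorts (12 breeds × 8 dogs, 500 sites, pairwise
breed FST 0.1, 20 bootstrap replicates) injected label swaps are detected
with ≥ 95% sensitivity; the acceptance suite measures this.

## Population structure

The relatedness matrix is the **centered** GRM,
`K = (1/p) Σ_s (g_s − ḡ_s)(g_s − ḡ_s)ᵀ` — not the standardized variant —
with missing dosages mean-imputed per site first (count logged) and
monomorphic sites contributing zero while still counting in the divisor.
`K·1 = 0` by construction (checked to 1e-9). Its eigendecomposition supplies
both the mixed-model rotation and eigenvector covariates.

The number of eigenvector covariates comes from a scree rule: the elbow is
the component index maximizing the second difference of the eigenvalue
sequence. Scree inspection is ordinarily a judgment call, so two safeguards
apply: near-constant decay ratios (no elbow, e.g. geometric decay) fall back
to two components with a low-confidence flag, and a manual override always
wins — reproducing analyses where six or eight eigenvectors were fixed after
visual inspection.

## Association models

**Mixed model.** `y = Wα + xβ + u + ε`, `u ~ N(0, σ²_g K)`,
`ε ~ N(0, σ²_e I)`. The breed prevalence is broadcast to every dog of the
breed as a quantitative phenotype — stated explicitly because nothing forces
this choice; it is how a per-individual mixed model can consume a breed
attribute. Sex enters as a covariate (female 0, male 1, unknown
mean-imputed). The variance ratio `r = σ²_g/σ²_e` is REML-estimated: after
rotating by K's eigenvectors the restricted likelihood at fixed `r` costs
O(n), and `r` is profiled on a 41-point log grid spanning [1e−5, 1e5]
followed by golden-section refinement to 1e-6 relative tolerance; a maximum
on the boundary is returned with a non-convergence flag (this happens
legitimately when the phenotype is perfectly breed-structured and σ²_e → 0).
Per-SNP re-optimization of `r` is the default; `per_snp_r=False` reuses the
null-model ratio for every SNP — the standard fast approximation, used by
the large simulation suites here. The Wald statistic `(β̂/se)²` is referred
to `F(1, n−c−1)` with `c` the covariate count including the intercept.
`K = 0` (or absent) degenerates exactly to the OLS scan. SNPs collinear with
covariates yield flagged `p = 1` rows rather than dropped rows, so output
row counts always equal input SNP counts; an exact fit (zero residual)
yields the smallest representable p rather than a division error.

**Binary case-control.** Breeds with prevalence ≤ low cut are controls,
≥ high cut cases, intermediates excluded; both groups must be nonempty
(violations report the nearest feasible cuts). The 0/1 phenotype then runs
through the identical mixed-model machinery — a linear approximation that is
accurate for small SNP effects. The cuts are explicit user parameters, with
stringent and lenient pairs both supported.

**Haplotype windows.** Fixed windows of 4 consecutive SNPs (configurable)
slide by one within each chromosome: `max(0, sites − 3)` windows per
chromosome. Individuals missing any call in a window are excluded from that
window (count kept). Haplotype frequencies over the 2⁴ classes come from EM
on unphased genotypes: E-step weights each compatible phase pair by the
product of current frequencies (×2 for heterozygous pairs), M-step
re-estimates; convergence at max frequency change < 1e-8 or 1000
iterations. The EM log-likelihood is nondecreasing by construction (tested).
Haplotypes below 1% frequency pool into a rare class; the most frequent
class is the reference. The window test is an omnibus F comparing the
regression of `y` on covariates + (H−1) expected haplotype dosages against
covariates alone, with the numerator degrees of freedom taken from the
realized rank increase so collinear dosage columns degrade gracefully to a
flagged `p = 1`. Covariates are the intercept plus the scree-selected (or
overridden) GRM eigenvectors. Each SNP's p-value is the minimum over the
windows containing it — reported alongside window-level results because a
window method has no canonical per-SNP mapping. Under breed structure this
scan is expected to be inflated (λ well above 1); the package reports λ and
makes no correction, matching the behavior of fixed-window haplotype scans
on stratified cohorts.

**Weighted least squares.** The cohort collapses to `X[b,j]` = mean
non-missing dosage of SNP j in breed b; SNPs unobserved in any breed are
dropped (count kept). Principal components come from the centered GRM of
X's rows. Per SNP: weighted regression of prevalence on intercept + top 5
PCs + `X[:,j]` with weights `n_b/N` (breed sample proportions — invariant to
scaling all counts), slope t-tested with `n − n_pcs − 2` df. Doubling every
breed's count changes nothing; equal weights with zero PCs reduce exactly to
OLS on breed means. This model uses all dogs without per-individual
modeling, which is why it tolerates breeds represented by a single dog.

## Significance machinery

Bonferroni threshold `α/m` at full precision (display-rounded only). FDR is
Benjamini–Hochberg step-up — chosen over empirical-null local-FDR fitting,
which is a separate estimation problem the scans do not depend on; q-values
are monotone with p by construction. The genomic inflation factor is the
field-standard median definition: median of the χ²₁-equivalent statistics
divided by 0.4549364. QQ expected quantiles are `−log10((i−½)/m)`.
Significant SNPs collapse into regions while consecutive same-chromosome
gaps stay ≤ 500 kb (configurable; merged-region reporting has no canonical
rule, so the gap is explicit); region bounds are the terminal SNP positions.
Gene annotation lists genes overlapping a region by ≥ 1 bp — strictly no
flanking, strand ignored — from BED or GFF3, via an interval tree and
cross-checked against an all-pairs oracle.

## Synthetic cohorts

The simulator generates exactly the structure the analysis assumes, so test
outcomes are interpretable:

- **Two-level Balding–Nichols divergence.** Ancestral frequency
  `p0 ~ U(0.05, 0.95)` per SNP; clade frequencies
  `~ Beta(p0(1−F₁)/F₁, (1−p0)(1−F₁)/F₁)`; breed frequencies likewise around
  their clade with F₂. Compound divergence `FST = 1 − (1−F₁)(1−F₂)`;
  defaults F₁ = 0.08, F₂ = 0.13 give ≈ 0.2, in the range of real breed
  differentiation. The moment `Var(p_b) ≈ FST·p0(1−p0)` is verified to 10%.
  The clade level exists so the phylogeny stage has genuine hierarchical
  signal.
- **Cohort shape.** 30 breeds; per-breed sizes 6 + a capped geometric
  (most breeds small, a long tail to 60; ~300 dogs in expectation), mimicking
  registry-style imbalance (the bundled real example panel spans 1–51 dogs
  per breed). Sex is male-skewed (73% male, 3% unknown) as in repository
  cohorts. Genotypes are Binomial(2, p_breed); missingness 2% uniform; site
  quality Gamma(4, 10), so a realistic minority of sites falls under QUAL 20
  and exercises the filter; planted causal sites are assigned QUAL ≥ 20 so a
  filtered pipeline retains its target.
- **Phenotype.** Causal effects act through breed frequencies:
  `L_b = Σ β_j (2p_bj − 2p0_j)`, `prevalence_b = logistic(intercept + L_b +
  ε_b)`. Default: one causal SNP, slope β = 1.5 per dosage unit, intercept
  −2.2 (≈ 10% baseline prevalence). The logistic link keeps prevalences in
  (0,1). `prevalence_noise_sd` (default 0) adds logit-scale breed noise;
  it exists because with no causal variants and no noise every breed sits at
  the same prevalence and a null scan is undefined — null-calibration runs
  set it to 0.5.
- **Limitations.** Sites are independent given breed frequencies — there is
  no linkage disequilibrium, so window/region behavior on real data (where
  significant SNPs cluster by LD) is not captured; no selection dynamics, no
  pedigree, no genotyping-error model beyond uniform missingness. Passing
  power tests therefore demonstrate the estimators find frequency-prevalence
  covariance under drift, not that real cohorts of this size suffice.

Everything is reproducible from a single seed, including file outputs
(byte-identical regeneration is tested).

## Verification strategy and problem sizes

Every scan statistic is checked against an independent dense oracle: WLS
against explicit weighted normal equations (50 random instances, 1e-10),
the mixed model at fixed variance ratio against a dense `(XᵀV⁻¹X)⁻¹` solve
(1e-8 on p-values), the REML objective against the dense restricted
likelihood at five ratios, the haplotype omnibus F against a direct
two-model RSS comparison (and statsmodels), HWE against exhaustive
enumeration, BH against the min-over-tail definition, NJ against additive
path-length recovery (1e-9), consensus supports against a brute bipartition
tally, region collapsing against a brute gap partition.

Simulation-based checks use deliberately modest problem sizes chosen for
desk-scale reproducibility: power over 50 replicates of the default cohort
(~300 dogs × 5,000 SNPs), null calibration over 5 such replicates
(25,000 null tests), haplotype inflation on one 160-dog × 1,200-SNP cohort,
mislabel sensitivity over 10 cohorts of 96 dogs × 500 sites with 20
bootstrap replicates each. Expected outcomes at these sizes: ≥ 90% top-10
recovery for both scans, type-I error within 3 binomial SEs of 0.05 and λ in
[0.85, 1.15] per replicate for the mixed model, λ > 1 for the haplotype
scan, ≥ 95% mislabel sensitivity.

## Known limitations

- No leave-one-chromosome-out GRM: the candidate SNP contributes to K,
  slightly shrinking its own signal (proximal contamination).
- The binary model's linear treatment of 0/1 traits is only approximate for
  large effects.
- Haplotype windows do not phase beyond 4-SNP windows, and no LD-aware
  clumping, conditional analysis, or fine-mapping is provided.
- The variance-ratio search is bounded at [1e−5, 1e5]; phenotypes perfectly
  confounded with K legitimately hit the upper bound (flagged, not an
  error).
- X-chromosome dosage compensation is not modeled; haploid handling is
  limited to the heterozygous-haploid filter.
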