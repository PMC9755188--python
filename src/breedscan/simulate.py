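"""Synthetic multi-breed cohorts with the structure across-breed GWAS assumes.

Breeds descend from a handful of clades under a two-level Balding-Nichols
model: each SNP has an ancestral frequency p0 ~ Uniform(0.05, 0.95); each
clade draws its frequency from Beta(p0 (1-F1)/F1, (1-p0)(1-F1)/F1) and each
breed draws likewise around its clade with dispersion F2.  The compound
between-breed divergence is FST = 1 - (1-F1)(1-F2).  Genotypes are
Binomial(2, p_breed) per dog — sites are independent given breed frequencies
(no linkage disequilibrium).

Breed disease prevalence is driven by planted large-effect variants acting
through breed allele frequencies: liability
``L_b = sum_causal beta_j (2 p_bj - 2 p0_j)`` and
``prevalence_b = logistic(intercept + L_b + noise)``.  The phenotype is a
breed attribute, mirroring the premise that across-breed scans detect shared
fixed large-effect variants.  Everything is reproducible from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .association import BreedPanel
from .vcf_io import GenotypeMatrix, SampleMeta, Variant, write_vcf

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_breed_frequencies",
    "simulate_genotypes",
    "simulate_prevalence",
    "generate_study",
]


@dataclass
class SimConfig:
    """Study-condition knobs for the cohort generator.

    Defaults describe a Table-1-like cohort: 30 breeds in 5 clades with
    heavily skewed sizes (most breeds small, a few large — drawn 6 + a capped
    geometric, ~300 dogs in expectation), 5,000 independent SNPs on 10
    chromosomes, compound between-breed FST ~= 0.2, one planted causal SNP
    with liability slope 1.5 per dosage unit, ~10% baseline prevalence,
    2% missing calls, and a male-skewed sex ratio.
    """

    n_breeds: int = 30
    breed_sizes: Sequence[int] | None = None
    size_min: int = 6
    size_max: int = 60
    n_snps: int = 5000
    n_chromosomes: int = 10
    n_clades: int = 5
    fst_between_clade: float = 0.08
    fst_within_clade: float = 0.13
    n_causal: int = 1
    beta: float = 1.5
    prevalence_intercept: float = -2.2
    prevalence_noise_sd: float = 0.0
    missing_rate: float = 0.02
    qual_shape: float = 4.0
    qual_scale: float = 10.0
    male_fraction: float = 0.73
    unknown_sex_fraction: float = 0.03
    n_mislabeled: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_between_clade", "fst_within_clade"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {f}")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal must be <= n_snps")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")

    @property
    def fst_total(self) -> float:
        return 1.0 - (1.0 - self.fst_between_clade) * (1.0 - self.fst_within_clade)


@dataclass
class SimTruth:
    """Everything needed to score recovery: planted variants and frequencies."""

    p0: np.ndarray
    breed_freqs: np.ndarray          # breeds x SNPs
    clade_of_breed: np.ndarray
    causal_indices: np.ndarray
    causal_beta: np.ndarray
    breed_liability: np.ndarray
    breed_prevalence: np.ndarray
    breed_names: list[str]
    sample_breed: list[str]
    mislabeled_samples: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def _conv(x):
            return x.tolist() if isinstance(x, np.ndarray) else x

        with open(path, "w") as fh:
            json.dump({k: _conv(v) for k, v in asdict(self).items()}, fh, indent=1)


def _bn_draw(rng: np.random.Generator, base: np.ndarray, fst: float) -> np.ndarray:
    """One Balding-Nichols draw around ``base`` with dispersion ``fst``."""
    base = np.clip(base, 1e-4, 1.0 - 1e-4)
    ratio = (1.0 - fst) / fst
    return rng.beta(base * ratio, (1.0 - base) * ratio)


def simulate_breed_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Ancestral and per-breed allele frequencies under two-level divergence.

    Returns ``(p0, breed_freqs, clade_of_breed)`` with breed_freqs of shape
    (n_breeds, n_snps).  As the dispersions shrink toward 0 all breeds
    collapse onto p0; across SNPs the variance of breed frequencies matches
    the Balding-Nichols moment ``FST_total * p0 (1 - p0)``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p0 = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    clade_of_breed = np.arange(cfg.n_breeds) % cfg.n_clades
    clade_freqs = np.vstack(
        [_bn_draw(rng, p0, cfg.fst_between_clade) for _ in range(cfg.n_clades)]
    )
    breed_freqs = np.vstack(
        [_bn_draw(rng, clade_freqs[clade_of_breed[b]], cfg.fst_within_clade)
         for b in range(cfg.n_breeds)]
    )
    return p0, breed_freqs, clade_of_breed


def _breed_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.breed_sizes is not None:
        sizes = np.asarray(cfg.breed_sizes, dtype=int)
        if sizes.size != cfg.n_breeds:
            raise ValueError("breed_sizes length must equal n_breeds")
        return sizes
    # skewed like registry cohorts: most breeds near the minimum, a long tail
    extra = rng.geometric(0.2, size=cfg.n_breeds) - 1
    return np.minimum(cfg.size_min + extra, cfg.size_max)


def simulate_genotypes(
    breed_freqs: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    clade_of_breed: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw dogs: Binomial(2, p_breed) dosages, missingness, QUAL, sex.

    Variants are laid out on ``n_chromosomes`` chromosomes with sorted random
    positions.  Site quality is Gamma-distributed so that a realistic minority
    of sites falls below the usual QUAL 20 cutoff and exercises the filters;
    planted causal sites are assigned quality >= 20 so that a filtered scan
    retains its target.  Sample ids encode the breed for readability.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n_breeds, n_snps = breed_freqs.shape
    sizes = _breed_sizes(cfg, rng)
    breed_names = [f"breed{b:02d}" for b in range(n_breeds)]

    per_chrom = np.full(cfg.n_chromosomes, n_snps // cfg.n_chromosomes)
    per_chrom[: n_snps % cfg.n_chromosomes] += 1
    variants: list[Variant] = []
    qual = rng.gamma(cfg.qual_shape, cfg.qual_scale, size=n_snps)
    j = 0
    for c, m in enumerate(per_chrom, start=1):
        pos = np.cumsum(rng.integers(1, 10_000, size=m))  # sorted, unique
        for k in range(m):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            variants.append(
                Variant(chrom=f"chr{c}", pos=int(pos[k]), ref=str(ref), alt=str(alt),
                        qual=float(qual[j]), vid=f"snp{j}")
            )
            j += 1

    rows, samples = [], []
    for b in range(n_breeds):
        dos = rng.binomial(2, breed_freqs[b], size=(int(sizes[b]), n_snps)).astype(float)
        rows.append(dos)
        for i in range(int(sizes[b])):
            u = rng.random()
            sex = ("unknown" if u < cfg.unknown_sex_fraction
                   else "male" if u < cfg.unknown_sex_fraction + cfg.male_fraction
                   else "female")
            samples.append(SampleMeta(f"{breed_names[b]}_d{i:03d}", breed=breed_names[b], sex=sex))
    dosages = np.vstack(rows)
    if cfg.missing_rate > 0:
        dosages[rng.random(dosages.shape) < cfg.missing_rate] = np.nan
    return GenotypeMatrix(dosages, variants, samples)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_prevalence(
    p0: np.ndarray,
    breed_freqs: np.ndarray,
    causal_indices: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Breed liability and prevalence from the planted causal frequencies.

    ``L_b = sum_j beta (2 p_bj - 2 p0_j)`` over causal SNPs j;
    ``prevalence_b = logistic(intercept + L_b + eps_b)`` with optional
    logit-scale breed noise.  With no causal SNPs and no noise every breed
    sits at logistic(intercept).
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n_breeds = breed_freqs.shape[0]
    causal_indices = np.asarray(causal_indices, dtype=int)
    L = np.zeros(n_breeds)
    for j in causal_indices:
        L += cfg.beta * (2.0 * breed_freqs[:, j] - 2.0 * p0[j])
    noise = (rng.normal(0.0, cfg.prevalence_noise_sd, size=n_breeds)
             if cfg.prevalence_noise_sd > 0 else np.zeros(n_breeds))
    prevalence = _logistic(cfg.prevalence_intercept + L + noise)
    return L, prevalence


def _pick_causal(cfg: SimConfig, p0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Causal sites among mid-frequency SNPs so the signal is scannable."""
    candidates = np.flatnonzero((p0 >= 0.2) & (p0 <= 0.8))
    if candidates.size < cfg.n_causal:
        candidates = np.arange(p0.size)
    return np.sort(rng.choice(candidates, size=cfg.n_causal, replace=False))


def generate_study(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[GenotypeMatrix, BreedPanel, SimTruth]:
    """Generate a full synthetic study; optionally write its file bundle.

    Writes (when ``out_dir`` is given) a sorted VCF, a breed phenotype TSV, a
    sample metadata TSV, and a truth JSON — byte-reproducible from the seed.
    ``cfg.n_mislabeled`` swaps the recorded breed label of that many dogs to a
    different breed (genotypes unchanged), for testing breed verification.
    """
    rng = np.random.default_rng(cfg.seed)
    p0, breed_freqs, clade_of_breed = simulate_breed_frequencies(cfg, rng)
    causal = _pick_causal(cfg, p0, rng) if cfg.n_causal else np.array([], dtype=int)
    gm = simulate_genotypes(breed_freqs, cfg, rng, clade_of_breed)
    for j in causal:  # keep planted sites above the usual QUAL cutoff
        v = gm.variants[j]
        if v.qual < 20.0:
            gm.variants[j] = Variant(v.chrom, v.pos, v.ref, v.alt, 20.0 + rng.random() * 40.0,
                                     v.n_alleles, v.vid)
    L, prevalence = simulate_prevalence(p0, breed_freqs, causal, cfg, rng)
    breed_names = [f"breed{b:02d}" for b in range(cfg.n_breeds)]
    true_breeds = list(gm.breeds)  # before any label corruption
    counts = pd.Series(gm.breeds).value_counts()

    mislabeled: list[str] = []
    if cfg.n_mislabeled:
        idx = rng.choice(gm.n_samples, size=cfg.n_mislabeled, replace=False)
        for i in sorted(int(x) for x in idx):
            s = gm.samples[i]
            others = [b for b in breed_names if b != s.breed]
            wrong = others[int(rng.integers(len(others)))]
            gm.samples[i] = SampleMeta(s.sample_id, breed=wrong, sex=s.sex)
            mislabeled.append(s.sample_id)
        counts = pd.Series(gm.breeds).value_counts()

    panel = BreedPanel(
        pd.DataFrame({"sim": prevalence}, index=breed_names).loc[sorted(set(gm.breeds))],
        counts,
    )
    truth = SimTruth(
        p0=p0,
        breed_freqs=breed_freqs,
        clade_of_breed=clade_of_breed,
        causal_indices=causal,
        causal_beta=np.full(causal.size, cfg.beta),
        breed_liability=L,
        breed_prevalence=prevalence,
        breed_names=breed_names,
        sample_breed=true_breeds,
        mislabeled_samples=mislabeled,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_vcf(gm, out_dir / "cohort.vcf")
        panel.to_tsv(out_dir / "phenotypes.tsv")
        pd.DataFrame(
            {
                "sample_id": gm.sample_ids,
                "breed": gm.breeds,
                "sex": [s.sex for s in gm.samples],
            }
        ).to_csv(out_dir / "meta.tsv", sep="\t", index=False)
        truth.to_json(out_dir / "truth.json")
    return gm, panel, truth
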