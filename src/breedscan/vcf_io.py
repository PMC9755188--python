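"""Genotype I/O, QC summaries, and the two-stage variant/sample filtering protocol.

The central container is :class:`GenotypeMatrix`: a samples x variants matrix of
alternate-allele dosages (0, 1, 2, or missing) with per-variant and per-sample
annotations.  Filtering mirrors the two-stage protocol used for across-breed
GWAS of sequencing repositories: a site-quality stage (biallelic SNVs with
QUAL >= a cutoff) followed by a genotype-QC stage (sample call rate, site call
rate, minor allele frequency, heterozygous-haploid handling), with every
removal accounted for in a :class:`FilterLedger`.

Hardy-Weinberg equilibrium is *reported*, not filtered, by default: the ledger
counts sites failing each reporting threshold, and removal is opt-in.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "Variant",
    "SampleMeta",
    "GenotypeMatrix",
    "FilterLedger",
    "VcfParseError",
    "EmptyCohortError",
    "EmptyPanelError",
    "read_vcf",
    "write_vcf",
    "write_plink",
    "read_plink",
    "write_outputs",
    "apply_ploidy",
    "read_chromosome_config",
    "read_sample_metadata",
    "attach_metadata",
    "qc_summaries",
    "filter_site_quality",
    "filter_genotype_qc",
    "hwe_exact",
]

MISSING = np.nan

SEXES = ("female", "male", "unknown")
_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Malformed VCF header or record (message names the offending line)."""


class EmptyCohortError(ValueError):
    """All samples were removed by filtering."""


class EmptyPanelError(ValueError):
    """All variants were removed by filtering (or an empty matrix was written)."""


@dataclass(frozen=True)
class Variant:
    """A single variant site.

    ``alt`` is the first ALT allele; multi-allelic records keep their full
    allele count in ``n_alleles`` and dosages count copies of the first ALT.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    n_alleles: int = 2
    vid: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.n_alleles < 2:
            raise ValueError(f"n_alleles must be >= 2, got {self.n_alleles}")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref.upper() in _BASES
            and self.alt.upper() in _BASES
        )

    @property
    def is_biallelic(self) -> bool:
        return self.n_alleles == 2


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    breed: str = ""
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with annotations.

    ``dosages[i, j]`` is the count of alternate alleles for sample ``i`` at
    variant ``j`` — 0.0, 1.0, 2.0, or NaN for a missing call.  ``haploid`` is
    an optional boolean mask of the same shape marking haploid cells (male
    non-pseudoautosomal X/Y); ``None`` means all-diploid.
    """

    dosages: np.ndarray
    variants: list[Variant]
    samples: list[SampleMeta]
    haploid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, p = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample annotations for {n} rows")
        if len(self.variants) != p:
            raise ValueError(f"{len(self.variants)} variant annotations for {p} columns")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosage entries must be 0/1/2/missing; found {bad[:5]}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique")
        if self.haploid is not None:
            self.haploid = np.asarray(self.haploid, dtype=bool)
            if self.haploid.shape != self.dosages.shape:
                raise ValueError("haploid mask shape must match dosages")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: dict[str, int] = {}
        last_chrom, last_pos = None, -1
        for v in self.variants:
            if v.chrom != last_chrom:
                if v.chrom in seen:
                    raise ValueError(f"variants not sorted: chromosome {v.chrom} revisited")
                seen[v.chrom] = 1
                last_chrom, last_pos = v.chrom, v.pos
            elif v.pos < last_pos:
                raise ValueError(
                    f"variants not sorted within {v.chrom}: {v.pos} after {last_pos}"
                )
            else:
                last_pos = v.pos

    # -- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def breeds(self) -> list[str]:
        return [s.breed for s in self.samples]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.dosages[idx],
            list(self.variants),
            [self.samples[i] for i in idx],
            None if self.haploid is None else self.haploid[idx],
        )

    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, idx],
            [self.variants[j] for j in idx],
            list(self.samples),
            None if self.haploid is None else self.haploid[:, idx],
        )


@dataclass
class FilterLedger:
    """Stage-by-stage accounting of variant (or sample) removals.

    Conservation holds at every stage: the input count equals the retained
    count plus the sum of removals.  Hardy-Weinberg failure counts are carried
    separately because they are reported, not removed, by default.
    """

    n_input: int
    stages: list[tuple[str, int]] = field(default_factory=list)
    hwe_failures: dict[str, int] = field(default_factory=dict)

    def add(self, label: str, n_removed: int) -> None:
        if n_removed < 0:
            raise ValueError("removal counts must be nonnegative")
        self.stages.append((label, int(n_removed)))

    @property
    def n_removed(self) -> int:
        return sum(n for _, n in self.stages)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def check(self) -> None:
        if self.n_retained < 0:
            raise ValueError("ledger inconsistent: more removed than input")

    def merged(self, other: "FilterLedger") -> "FilterLedger":
        """Chain a downstream ledger whose input is this ledger's retained set."""
        if other.n_input != self.n_retained:
            raise ValueError("ledger chain mismatch")
        out = FilterLedger(self.n_input, list(self.stages) + list(other.stages))
        out.hwe_failures = {**self.hwe_failures, **other.hwe_failures}
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input, "")]
        rows += [(label, n, "removed") for label, n in self.stages]
        rows.append(("final retained", self.n_retained, ""))
        rows += [
            (f"fail Hardy-Weinberg threshold {thr}", n, "reported")
            for thr, n in self.hwe_failures.items()
        ]
        return pd.DataFrame(rows, columns=["stage", "n", "kind"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, optionally bgzipped) into a :class:`GenotypeMatrix`.

    One matrix column per record; multi-allelic records are retained with
    ``n_alleles`` recorded, and dosages count copies of the first ALT allele.
    Missing calls (``./.``) map to NaN.  Breed and sex annotations default to
    empty/unknown; attach them with :func:`attach_metadata`.
    """
    import cyvcf2

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    samples = [SampleMeta(sample_id=s) for s in vcf.samples]
    n = len(samples)
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    lineno = 0
    try:
        for rec in vcf:
            lineno += 1
            alts = rec.ALT or ["."]
            gts = np.asarray(rec.genotype.array())[:, :2]
            if gts.shape[0] != n:
                raise VcfParseError(
                    f"{path}: record {lineno} ({rec.CHROM}:{rec.POS}) has "
                    f"{gts.shape[0]} genotypes for {n} samples"
                )
            dos = (gts == 1).sum(axis=1).astype(float)
            dos[(gts < 0).any(axis=1)] = MISSING
            variants.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alts[0],
                    qual=float(rec.QUAL) if rec.QUAL is not None else float("nan"),
                    n_alleles=1 + len(alts),
                    vid=rec.ID or ".",
                )
            )
            cols.append(dos)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed record near line {lineno}: {exc}") from exc
    dosages = np.column_stack(cols) if cols else np.empty((n, 0))
    return GenotypeMatrix(dosages, variants, samples)


_SEX_CODE = {"female": "2", "male": "1", "unknown": "0"}
_SEX_DECODE = {"2": "female", "1": "male", "0": "unknown"}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a sorted VCF v4.2 with GT fields; round-trips dosages exactly."""
    if gm.n_variants == 0:
        raise EmptyPanelError("refusing to write a VCF with zero variants")
    path = Path(path)
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    contigs = list(dict.fromkeys(v.chrom for v in gm.variants))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedscan\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            qual = "." if np.isnan(v.qual) else f"{v.qual:.10g}"
            calls = "\t".join(
                "./." if np.isnan(d) else gt_of[d] for d in gm.dosages[:, j]
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t{qual}\t.\t.\tGT\t{calls}\n"
            )


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK bed/bim/fam triplet (SNP-major bed, A1 = ALT, A2 = REF).

    2-bit codes per the bed format: 00 = hom A1 (dosage 2), 10 = het,
    11 = hom A2 (dosage 0), 01 = missing; little-endian bit packing, one
    byte block per 4 samples per variant.
    """
    if gm.n_variants == 0:
        raise EmptyPanelError("refusing to write PLINK files with zero variants")
    prefix = Path(prefix)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in gm.samples:
            fam = s.breed if s.breed else s.sample_id
            fh.write(f"{fam} {s.sample_id} 0 0 {_SEX_CODE[s.sex]} -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in gm.variants:
            vid = v.vid if v.vid != "." else f"{v.chrom}:{v.pos}"
            fh.write(f"{v.chrom}\t{vid}\t0\t{v.pos}\t{v.alt}\t{v.ref}\n")
    code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    n = gm.n_samples
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(struct.pack("3B", 0x6C, 0x1B, 0x01))
        for j in range(gm.n_variants):
            col = gm.dosages[:, j]
            byts = bytearray((n + 3) // 4)
            for i in range(n):
                c = 0b01 if np.isnan(col[i]) else code[col[i]]
                byts[i // 4] |= c << (2 * (i % 4))
            fh.write(bytes(byts))


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a SNP-major PLINK bed/bim/fam triplet written by :func:`write_plink`."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    samples = [
        SampleMeta(
            sample_id=r.iid,
            breed="" if r.fid == r.iid else r.fid,
            sex=_SEX_DECODE.get(r.sex, "unknown"),
        )
        for r in fam.itertuples()
    ]
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep="\t",
        header=None,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "vid": str},
    )
    variants = [
        Variant(chrom=r.chrom, pos=int(r.pos), ref=r.a2, alt=r.a1, qual=float("nan"), vid=r.vid)
        for r in bim.itertuples()
    ]
    n, p = len(samples), len(variants)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != bytes((0x6C, 0x1B, 0x01)):
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    dose_of = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: MISSING}
    stride = (n + 3) // 4
    dosages = np.empty((n, p))
    body = raw[3:]
    for j in range(p):
        block = body[j * stride : (j + 1) * stride]
        for i in range(n):
            c = (block[i // 4] >> (2 * (i % 4))) & 0b11
            dosages[i, j] = dose_of[c]
    return GenotypeMatrix(dosages, variants, samples)


def write_outputs(gm: GenotypeMatrix, out: str | Path, format: str = "vcf") -> None:
    """Write ``gm`` as VCF v4.2 (``format='vcf'``) or PLINK bed/bim/fam."""
    if format == "vcf":
        write_vcf(gm, out)
    elif format == "plink":
        write_plink(gm, out)
    else:
        raise ValueError(f"unknown output format {format!r}")


def apply_ploidy(gm: GenotypeMatrix, haploid_chroms: Iterable[str]) -> GenotypeMatrix:
    """Mark haploid cells: male samples on the named chromosomes (e.g. X, Y).

    No pseudoautosomal-region inference is attempted; the chromosome set is
    declared by the caller (typically from a chromosome-config JSON mapping
    chromosome names to ploidy rules).
    """
    haploid_chroms = set(haploid_chroms)
    male = np.array([s.sex == "male" for s in gm.samples])
    on_hap_chrom = np.array([v.chrom in haploid_chroms for v in gm.variants])
    mask = male[:, None] & on_hap_chrom[None, :]
    return GenotypeMatrix(gm.dosages.copy(), list(gm.variants), list(gm.samples), mask)


def read_chromosome_config(path: str | Path) -> set[str]:
    """Read a chromosome-config JSON ({chrom: "diploid"|"haploid_male"}) and
    return the chromosomes haploid in males."""
    import json

    rules = json.loads(Path(path).read_text())
    bad = {c: r for c, r in rules.items() if r not in ("diploid", "haploid_male")}
    if bad:
        raise ValueError(f"unknown ploidy rules: {bad}")
    return {c for c, r in rules.items() if r == "haploid_male"}


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns sample_id, breed, sex."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "breed", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    bad = set(df["sex"]) - set(SEXES)
    if bad:
        raise ValueError(f"{path}: unknown sex values {sorted(bad)}")
    return df


def attach_metadata(gm: GenotypeMatrix, meta: pd.DataFrame) -> GenotypeMatrix:
    """Return a copy of ``gm`` with breed/sex filled in from a metadata table."""
    lookup = {r.sample_id: r for r in meta.itertuples()}
    samples = []
    for s in gm.samples:
        if s.sample_id not in lookup:
            raise ValueError(f"sample {s.sample_id} absent from metadata")
        r = lookup[s.sample_id]
        samples.append(SampleMeta(s.sample_id, breed=r.breed, sex=r.sex))
    return GenotypeMatrix(gm.dosages.copy(), list(gm.variants), samples, gm.haploid)


# ---------------------------------------------------------------------------
# QC summaries
# ---------------------------------------------------------------------------

def qc_summaries(
    gm: GenotypeMatrix, depths: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant and per-sample QC summary tables.

    Returns ``(variant_df, sample_df)``.  Variant table: chrom, pos,
    missingness, quality, and mean depth when a per-cell depth matrix is
    supplied; sample table: sample_id, missingness, and mean depth likewise.
    """
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ValueError("qc_summaries requires a nonempty matrix")
    miss = gm.missing_mask()
    variant_df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in gm.variants],
            "pos": [v.pos for v in gm.variants],
            "missingness": miss.mean(axis=0),
            "quality": [v.qual for v in gm.variants],
        }
    )
    sample_df = pd.DataFrame(
        {"sample_id": gm.sample_ids, "missingness": miss.mean(axis=1)}
    )
    if depths is not None:
        depths = np.asarray(depths, dtype=float)
        if depths.shape != gm.dosages.shape:
            raise ValueError("depth matrix shape must match dosages")
        variant_df["mean_depth"] = depths.mean(axis=0)
        sample_df["mean_depth"] = depths.mean(axis=1)
    return variant_df, sample_df


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_site_quality(
    gm: GenotypeMatrix, min_qual: float = 20.0
) -> tuple[GenotypeMatrix, FilterLedger]:
    """Stage 1: retain biallelic SNVs with site quality >= ``min_qual``.

    Removal reasons are attributed in order: multi-allelic first, then
    indel/non-SNV, then low quality (``qual < min_qual``, strict — a site at
    exactly the cutoff is retained).  Missing QUAL counts as low quality.
    """
    if min_qual < 0:
        raise ValueError("min_qual must be >= 0")
    ledger = FilterLedger(gm.n_variants)
    keep, n_multi, n_indel, n_lowq = [], 0, 0, 0
    for j, v in enumerate(gm.variants):
        if not v.is_biallelic:
            n_multi += 1
        elif not v.is_snv:
            n_indel += 1
        elif np.isnan(v.qual) or v.qual < min_qual:
            n_lowq += 1
        else:
            keep.append(j)
    ledger.add("non-biallelic", n_multi)
    ledger.add("indel or non-SNV", n_indel)
    ledger.add(f"quality < {min_qual:g}", n_lowq)
    ledger.check()
    return gm.take_variants(keep), ledger


def filter_genotype_qc(
    gm: GenotypeMatrix,
    min_sample_call_rate: float = 0.90,
    min_site_call_rate: float = 0.99,
    min_maf: float = 0.05,
    hethap_policy: str = "remove_site",
    hwe_report_thresholds: Sequence[float] = (1e-7, 5e-5),
    hwe_filter: float | None = None,
) -> tuple[GenotypeMatrix, FilterLedger]:
    """Stage 2: sample call rate, site call rate, MAF, heterozygous-haploid.

    The order matters and is fixed: samples with call rate <= the cutoff are
    removed first; site call rate and MAF are then computed on the remaining
    samples.  All three rate/frequency cutoffs are *inclusive* removals
    (a site at MAF exactly 0.05 is removed).  Heterozygous calls at haploid
    cells either remove the whole site (``remove_site``, default) or are set
    missing before the call-rate stage (``set_missing``).  Hardy-Weinberg
    exact-test failures at each reporting threshold are counted in the ledger;
    sites are only removed when ``hwe_filter`` is given.
    """
    for name, val in (
        ("min_sample_call_rate", min_sample_call_rate),
        ("min_site_call_rate", min_site_call_rate),
        ("min_maf", min_maf),
    ):
        if not 0.0 < val < 1.0:
            raise ValueError(f"{name} must be in (0,1), got {val}")
    if hethap_policy not in ("remove_site", "set_missing"):
        raise ValueError(f"unknown hethap_policy {hethap_policy!r}")

    dosages = gm.dosages.copy()
    haploid = gm.haploid

    hethap_sites = np.zeros(gm.n_variants, dtype=bool)
    if haploid is not None:
        hethap_cells = haploid & (dosages == 1.0)
        if hethap_policy == "set_missing":
            dosages[hethap_cells] = MISSING
        else:
            hethap_sites = hethap_cells.any(axis=0)

    # -- samples first ---------------------------------------------------------
    call_rate_sample = 1.0 - np.isnan(dosages).mean(axis=1)
    keep_samples = np.flatnonzero(call_rate_sample > min_sample_call_rate)
    n_samples_removed = gm.n_samples - keep_samples.size
    if keep_samples.size == 0:
        raise EmptyCohortError(
            f"all {gm.n_samples} samples fail call rate > {min_sample_call_rate}"
        )
    dosages = dosages[keep_samples]

    # -- then sites ------------------------------------------------------------
    ledger = FilterLedger(gm.n_variants)
    obs = ~np.isnan(dosages)
    call_rate_site = obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(dosages, axis=0) / (2.0 * obs.sum(axis=0))
    alt_freq = np.where(obs.any(axis=0), alt_freq, 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    removed = np.zeros(gm.n_variants, dtype=bool)
    fail_cr = (call_rate_site <= min_site_call_rate) & ~removed
    removed |= fail_cr
    fail_maf = (maf <= min_maf) & ~removed
    removed |= fail_maf
    fail_hh = hethap_sites & ~removed
    removed |= fail_hh

    ledger.add(f"site call rate <= {min_site_call_rate:g}", int(fail_cr.sum()))
    ledger.add(f"minor allele frequency <= {min_maf:g}", int(fail_maf.sum()))
    ledger.add("heterozygous haploid", int(fail_hh.sum()))

    keep_sites = np.flatnonzero(~removed)

    # -- Hardy-Weinberg reporting on the retained set --------------------------
    hwe_p = np.ones(keep_sites.size)
    for k, j in enumerate(keep_sites):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        n_aa = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        if n_aa + n_ab + n_bb:
            hwe_p[k] = hwe_exact(n_aa, n_ab, n_bb)
    for thr in hwe_report_thresholds:
        ledger.hwe_failures[f"{thr:g}"] = int((hwe_p < thr).sum())
    if hwe_filter is not None:
        fail = hwe_p < hwe_filter
        ledger.add(f"Hardy-Weinberg p < {hwe_filter:g}", int(fail.sum()))
        keep_sites = keep_sites[~fail]
    ledger.check()
    if keep_sites.size == 0:
        raise EmptyPanelError("all variants removed by genotype QC")

    out = GenotypeMatrix(
        dosages[:, keep_sites],
        [gm.variants[j] for j in keep_sites],
        [gm.samples[i] for i in keep_samples],
        None
        if haploid is None
        else haploid[np.ix_(keep_samples, keep_sites)],
    )
    out.n_samples_removed = n_samples_removed  # type: ignore[attr-defined]
    return out, ledger


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test conditional on allele counts.

    Sums the probabilities of all heterozygote counts (with the observed
    allele totals fixed) that are no more probable than the observed count.
    Monomorphic sites return 1.  Comparable to the widely used exact HWE
    test of genotype-count data.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("total genotype count must be > 0")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele count
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if hets.size == 0:
        return 1.0
    n_rr = (n_rare - hets) // 2
    n_cc = n - hets - n_rr
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(n_rr + 1)
        - gammaln(hets + 1)
        - gammaln(n_cc + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))
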