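"""Significance machinery and scan summaries.

Bonferroni family-wise thresholds, Benjamini-Hochberg q-values, the genomic
inflation factor, QQ/Manhattan plot data, collapsing of significant SNPs into
regions, and gene-interval annotation of those regions (strict overlap, no
flanking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScanDiagnostics",
    "Region",
    "bonferroni_threshold",
    "bh_fdr",
    "genomic_lambda",
    "qq_points",
    "manhattan_table",
    "collapse_regions",
    "annotate_regions",
    "read_gene_intervals",
    "regions_to_frame",
    "scan_diagnostics",
    "qq_plot",
    "manhattan_plot",
]

CHI2_1_MEDIAN = 0.4549364231195724  # median of the chi-square(1) distribution


@dataclass
class ScanDiagnostics:
    lambda_gc: float
    n_tests: int
    bonferroni_alpha: float
    qq: pd.DataFrame


@dataclass
class Region:
    """A run of significant SNPs collapsed into one locus (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    min_p: float
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.n_snps < 1:
            raise ValueError("a region holds >= 1 SNP")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold ``alpha / n_tests`` at full precision."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0,1]")
    return alpha / n_tests


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, monotone with p."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def genomic_lambda(pvals: Sequence[float] | np.ndarray) -> float:
    """Genomic inflation factor: median chi-square(1)-equivalent statistic
    divided by the null chi-square(1) median (0.4549...)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    chi2 = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def qq_points(pvals: Sequence[float] | np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p quantile pairs (sorted ascending p)."""
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))
    return pd.DataFrame({"expected": expected, "observed": observed})


def manhattan_table(results: pd.DataFrame, gap: int = 1) -> pd.DataFrame:
    """Plot-ready table with a strictly increasing cumulative genome coordinate."""
    if results.empty:
        raise ValueError("empty result table")
    out = results.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    offset, offsets = 0, {}
    for chrom, grp in out.groupby("chrom", sort=False):
        offsets[chrom] = offset
        offset += int(grp["pos"].max()) + gap
    out["cum_pos"] = out["pos"] + out["chrom"].map(offsets)
    out["neg_log10_p"] = -np.log10(np.clip(out["p"].to_numpy(float), np.finfo(float).tiny, 1.0))
    return out


def scan_diagnostics(results: pd.DataFrame, alpha: float = 0.05) -> ScanDiagnostics:
    p = results["p"].to_numpy(dtype=float)
    n = p.size
    return ScanDiagnostics(
        lambda_gc=genomic_lambda(p),
        n_tests=n,
        bonferroni_alpha=bonferroni_threshold(alpha, n),
        qq=qq_points(p),
    )


def collapse_regions(
    results: pd.DataFrame, threshold: float, max_gap: int = 500_000
) -> list[Region]:
    """Merge significant SNPs into regions.

    SNPs with ``p < threshold`` on the same chromosome merge while the gap
    between consecutive significant positions is <= ``max_gap`` bp; region
    bounds are the terminal SNP positions.  Idempotent and insensitive to
    input row order.
    """
    sig = results.loc[results["p"] < threshold, ["chrom", "pos", "p"]]
    sig = sig.sort_values(["chrom", "pos"], kind="stable")
    regions: list[Region] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=int)
        pv = grp["p"].to_numpy(dtype=float)
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > max_gap:
                block = slice(start, i)
                regions.append(
                    Region(
                        chrom=str(chrom),
                        start=int(pos[block][0]),
                        end=int(pos[block][-1]),
                        n_snps=i - start,
                        min_p=float(pv[block].min()),
                    )
                )
                start = i
    return regions


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED or GFF3 into 1-based inclusive coordinates.

    BED (0-based half-open) is converted at the boundary; GFF3 keeps only
    ``gene`` features (all features when none are typed ``gene``) and takes
    the gene name from ``Name=`` or ``ID=``.  Returns columns
    chrom/start/end/name.
    """
    path = Path(path)
    rows = []
    is_gff = path.suffix.lower() in {".gff", ".gff3", ".gtf"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if is_gff:
                    if len(parts) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    chrom, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    name = attrs.get("Name", attrs.get("ID", f"feature{lineno}"))
                    rows.append((chrom, int(start), int(end), name, ftype))
                else:
                    if len(parts) < 3:
                        raise ValueError("BED needs >= 3 columns")
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"feature{lineno}"
                    rows.append((chrom, start + 1, end, name, "gene"))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed annotation line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "ftype"])
    if is_gff and (df["ftype"] == "gene").any():
        df = df[df["ftype"] == "gene"]
    return df.drop(columns="ftype").sort_values(["chrom", "start"]).reset_index(drop=True)


def annotate_regions(
    regions: Sequence[Region], gene_intervals: pd.DataFrame | str | Path
) -> list[Region]:
    """Attach overlapping gene names to each region (>= 1 bp overlap, no
    flanking, strand-agnostic)."""
    if not isinstance(gene_intervals, pd.DataFrame):
        gene_intervals = read_gene_intervals(gene_intervals)
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for r in gene_intervals.itertuples():
        # half-open tree coordinates: [start, end+1) covers 1-based inclusive
        trees.setdefault(str(r.chrom), IntervalTree()).addi(r.start, r.end + 1, r.name)
    out = []
    for reg in regions:
        hits = trees.get(reg.chrom, IntervalTree()).overlap(reg.start, reg.end + 1)
        genes = sorted({h.data for h in hits})
        out.append(Region(reg.chrom, reg.start, reg.end, reg.n_snps, reg.min_p, genes))
    return out


def regions_to_frame(regions: Sequence[Region], model: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "region": [f"{r.start}-{r.end}" for r in regions],
            "n_snps": [r.n_snps for r in regions],
            "min_p": [r.min_p for r in regions],
            "genes": [";".join(r.genes) for r in regions],
            "model": model,
        }
    )


# ---------------------------------------------------------------------------
# Optional PNG rendering
# ---------------------------------------------------------------------------

def qq_plot(pvals, path: str | Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qq = qq_points(pvals)
    lam = genomic_lambda(pvals)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(qq["expected"], qq["observed"], s=4, alpha=0.6)
    lim = max(qq["expected"].max(), qq["observed"].max())
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.set_title(f"{title} (lambda = {lam:.2f})".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def manhattan_plot(results: pd.DataFrame, path: str | Path, threshold: float | None = None,
                   title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = manhattan_table(results)
    fig, ax = plt.subplots(figsize=(8, 3))
    for k, (_, grp) in enumerate(tab.groupby("chrom", sort=False)):
        ax.scatter(grp["cum_pos"], grp["neg_log10_p"], s=4,
                   color="steelblue" if k % 2 == 0 else "darkorange")
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=1, ls="--")
    ax.set_xlabel("cumulative position")
    ax.set_ylabel("-log10 p")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
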