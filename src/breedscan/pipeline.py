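"""End-to-end study orchestration with a run manifest.

Stages run in a fixed order — QC summaries, breed verification, site-quality
and genotype filtering, GRM/PCA, the selected association scans, significance
summaries, optional gene annotation — and every stage's counts, thresholds
and outputs are recorded in a JSON manifest sufficient to re-run the study.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    BreedPanel,
    assign_binary_phenotype,
    binary_casecontrol_scan,
    breed_average_dosage,
    broadcast_phenotype,
    build_covariates,
    haplotype_scan,
    lmm_scan,
    wls_scan,
)
from .breed_verify import bootstrap_distances, flag_breed_outliers, majority_consensus, \
    neighbor_joining, write_newick
from .kinship import centered_grm, scree_select
from .summarize import annotate_regions, collapse_regions, read_gene_intervals, \
    regions_to_frame, scan_diagnostics
from .vcf_io import attach_metadata, filter_genotype_qc, filter_site_quality, \
    qc_summaries, read_sample_metadata, read_vcf

__all__ = ["RunConfig", "validate_config", "run_study", "StageError"]

logger = logging.getLogger("breedscan")

KNOWN_MODELS = ("lmm", "binary", "haplotype", "wls")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    vcf: str = ""
    phenotypes: str = ""
    meta: str = ""
    disease: str = ""
    out_dir: str = "breedscan_out"
    models: list[str] = field(default_factory=lambda: list(KNOWN_MODELS))
    genes: str | None = None
    min_qual: float = 20.0
    min_sample_call_rate: float = 0.90
    min_site_call_rate: float = 0.99
    min_maf: float = 0.05
    verify_breeds: bool = True
    n_boot: int = 100
    low_cut: float = 0.05
    high_cut: float = 0.15
    window: int = 4
    n_eigenvectors: int | None = None
    n_pcs: int = 5
    alpha: float = 0.05
    max_gap: int = 500_000
    per_snp_r: bool = True
    seed: int = 0


_DEFAULTS = asdict(RunConfig())


def validate_config(cfg: dict) -> RunConfig:
    """Fill defaults and collect *all* validation errors before raising."""
    errors = []
    unknown = set(cfg) - set(_DEFAULTS)
    for key in sorted(unknown):
        errors.append(f"unknown configuration key {key!r}")
    merged = {**_DEFAULTS, **{k: v for k, v in cfg.items() if k in _DEFAULTS}}
    models = merged["models"]
    if not models:
        errors.append("at least one model must be selected")
    for m in models:
        if m not in KNOWN_MODELS:
            errors.append(f"unknown model {m!r} (choose from {KNOWN_MODELS})")
    for key in ("vcf", "phenotypes", "meta"):
        val = merged[key]
        if not val:
            errors.append(f"missing required input path {key!r}")
        elif not Path(val).exists():
            errors.append(f"{key} file does not exist: {val}")
    if merged["genes"] and not Path(merged["genes"]).exists():
        errors.append(f"genes file does not exist: {merged['genes']}")
    if not merged["disease"]:
        errors.append("missing 'disease': the phenotype column to scan")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**merged)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(cfg: RunConfig) -> dict:
    """Run the full workflow; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        rec = stage("load")
        gm = read_vcf(cfg.vcf)
        gm = attach_metadata(gm, read_sample_metadata(cfg.meta))
        panel = BreedPanel.from_tsv(cfg.phenotypes)
        rec.update(n_samples=gm.n_samples, n_variants=gm.n_variants)
    except Exception as exc:
        raise StageError(f"load: {exc}") from exc

    try:
        rec = stage("qc_summaries")
        vstats, sstats = qc_summaries(gm)
        vstats.to_csv(out / "variant_qc.tsv", sep="\t", index=False)
        sstats.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
        rec.update(mean_variant_missingness=float(vstats["missingness"].mean()))
    except Exception as exc:
        raise StageError(f"qc_summaries: {exc}") from exc

    try:
        rec = stage("filter_site_quality")
        gm, site_ledger = filter_site_quality(gm, min_qual=cfg.min_qual)
        rec.update(dict(site_ledger.stages), retained=site_ledger.n_retained)
    except Exception as exc:
        raise StageError(f"filter_site_quality: {exc}") from exc

    if cfg.verify_breeds:
        try:
            rec = stage("verify_breeds")
            multi = [b for b, c in pd.Series(gm.breeds).value_counts().items() if c >= 2]
            dmats = bootstrap_distances(gm, n_boot=cfg.n_boot, seed=cfg.seed)
            trees = [neighbor_joining(d) for d in dmats]
            consensus = majority_consensus(trees)
            write_newick(consensus, out / "consensus.nwk")
            flags = flag_breed_outliers(consensus, gm.samples)
            flagged = {f.sample_id for f in flags}
            rec.update(n_flagged=len(flags), flagged=sorted(flagged),
                       n_multi_sample_breeds=len(multi))
            if flagged:
                keep = [i for i, s in enumerate(gm.samples) if s.sample_id not in flagged]
                gm = gm.take_samples(keep)
        except Exception as exc:
            raise StageError(f"verify_breeds: {exc}") from exc

    try:
        rec = stage("filter_genotype_qc")
        gm, qc_ledger = filter_genotype_qc(
            gm,
            min_sample_call_rate=cfg.min_sample_call_rate,
            min_site_call_rate=cfg.min_site_call_rate,
            min_maf=cfg.min_maf,
        )
        full = qc_ledger.to_frame()
        full.to_csv(out / "filter_ledger.tsv", sep="\t", index=False)
        rec.update(dict(qc_ledger.stages), retained=qc_ledger.n_retained,
                   n_samples=gm.n_samples)
    except Exception as exc:
        raise StageError(f"filter_genotype_qc: {exc}") from exc

    try:
        rec = stage("kinship")
        grm = centered_grm(gm)
        basis = grm.eigen()
        k_sel, low_conf = scree_select(basis.eigenvalues, override=cfg.n_eigenvectors)
        rec.update(n_sites_used=grm.n_sites_used, n_eigenvectors=k_sel,
                   scree_low_confidence=low_conf)
    except Exception as exc:
        raise StageError(f"kinship: {exc}") from exc

    results: dict[str, pd.DataFrame] = {}
    try:
        y = broadcast_phenotype(panel, cfg.disease, gm.samples)
        covars = build_covariates(gm.samples)
        for model in cfg.models:
            rec = stage(f"scan_{model}")
            if model == "lmm":
                res = lmm_scan(gm, y, covars, grm, per_snp_r=cfg.per_snp_r)
            elif model == "binary":
                labels, excluded = assign_binary_phenotype(
                    panel, cfg.disease, cfg.low_cut, cfg.high_cut, gm.samples
                )
                rec["excluded_breeds"] = excluded
                res = binary_casecontrol_scan(gm, labels, covars, grm,
                                              per_snp_r=cfg.per_snp_r)
            elif model == "haplotype":
                windows, res = haplotype_scan(
                    gm, y, basis, n_pcs=k_sel, window_size=cfg.window
                )
                windows.to_csv(out / "haplotype_windows.tsv", sep="\t", index=False)
            else:  # wls
                inputs = breed_average_dosage(gm, panel)
                res = wls_scan(inputs, panel.prevalence_of(cfg.disease), n_pcs=cfg.n_pcs)
            results[model] = res
            res.to_csv(out / f"assoc_{model}.tsv", sep="\t", index=False)
            rec["n_tests"] = len(res)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"scan: {exc}") from exc

    try:
        rec = stage("summarize")
        genes = read_gene_intervals(cfg.genes) if cfg.genes else None
        for model, res in results.items():
            diag = scan_diagnostics(res, alpha=cfg.alpha)
            regions = collapse_regions(res, diag.bonferroni_alpha, max_gap=cfg.max_gap)
            if genes is not None:
                regions = annotate_regions(regions, genes)
            regions_to_frame(regions, model=model).to_csv(
                out / f"regions_{model}.tsv", sep="\t", index=False
            )
            diag.qq.to_csv(out / f"qq_{model}.tsv", sep="\t", index=False)
            rec[model] = {
                "lambda_gc": diag.lambda_gc,
                "bonferroni": diag.bonferroni_alpha,
                "n_significant": int((res["p"] < diag.bonferroni_alpha).sum()),
                "n_regions": len(regions),
            }
    except Exception as exc:
        raise StageError(f"summarize: {exc}") from exc

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.nwk")):
        manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.removeHandler(handler)
    handler.close()
    return manifest
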