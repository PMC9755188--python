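"""The four across-breed association engines.

Phenotypes here are *breed* attributes — disease prevalences — used in place
of missing individual phenotypes.  Four scans share a common result-table
contract:

1. ``lmm_scan`` — linear mixed model with a centered GRM random effect; the
   breed prevalence is broadcast to every dog of the breed as a quantitative
   phenotype, and each SNP is Wald-tested.
2. ``binary_casecontrol_scan`` — the same machinery on a 0/1 phenotype built
   by dichotomizing breed prevalence (low-risk controls vs high-risk cases).
3. ``haplotype_scan`` — sliding fixed-width SNP windows, haplotype
   frequencies estimated by EM, and an omnibus F-test of the expected
   haplotype dosages over eigenvector covariates.
4. ``wls_scan`` — weighted least squares on breed-average SNP dosages with
   top principal components as covariates and breed sample proportions as
   weights; the model for cohorts too unbalanced to scan per-individual.

The mixed model is ``y = W a + x b + u + e`` with ``u ~ N(0, s2_g K)`` and
``e ~ N(0, s2_e I)``.  The variance ratio ``r = s2_g / s2_e`` is estimated by
REML, profiled on a log grid over [1e-5, 1e5] with golden-section refinement;
after rotation by K's eigenvectors each evaluation is O(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import RelatednessMatrix, StructureBasis, centered_grm, mean_impute
from .vcf_io import GenotypeMatrix, SampleMeta, Variant

__all__ = [
    "BreedPanel",
    "LmmFit",
    "WlsInputs",
    "HaplotypeWindow",
    "build_covariates",
    "broadcast_phenotype",
    "reml_variance_ratio",
    "lmm_scan",
    "assign_binary_phenotype",
    "binary_casecontrol_scan",
    "haplotype_em",
    "haplotype_scan",
    "breed_average_dosage",
    "wls_scan",
]

RESULT_COLUMNS = ["chrom", "pos", "ref", "alt", "beta", "se", "stat", "p", "model", "flags"]

_R_BOUNDS = (1e-5, 1e5)  # profiled variance-ratio search bounds
_GOLDEN_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Breed phenotype panel
# ---------------------------------------------------------------------------

class BreedPanel:
    """Breed -> (disease prevalences, genotyped sample count).

    Prevalences are stored as fractions in [0, 1]; values supplied above 1
    are taken as percentages and divided by 100.  Weights are the breed
    sample proportions ``n_b / N`` and always sum to 1.
    """

    def __init__(self, prevalence: pd.DataFrame, n_samples: pd.Series) -> None:
        prev = prevalence.astype(float).copy()
        for col in prev.columns:
            vals = prev[col]
            if (vals.dropna() > 1.0).any():
                prev[col] = vals / 100.0
        bad = prev.stack(future_stack=True).dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("prevalences must lie in [0,1] (or [0,100] percent)")
        n = n_samples.reindex(prev.index).astype(float)
        if n.isna().any() or (n <= 0).any():
            raise ValueError("every breed needs a positive sample count")
        self.prevalence = prev
        self.n_samples = n.astype(int)

    @property
    def breeds(self) -> list[str]:
        return list(self.prevalence.index)

    @property
    def diseases(self) -> list[str]:
        return list(self.prevalence.columns)

    @property
    def weights(self) -> pd.Series:
        return self.n_samples / self.n_samples.sum()

    def prevalence_of(self, disease: str) -> pd.Series:
        if disease not in self.prevalence.columns:
            raise KeyError(f"unknown disease {disease!r}")
        return self.prevalence[disease]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BreedPanel":
        """Build from a table with columns ``breed``, ``n``, and one column per disease."""
        df = df.set_index("breed") if "breed" in df.columns else df
        if "n" not in df.columns:
            raise ValueError("panel table needs an 'n' sample-count column")
        return cls(df.drop(columns="n"), df["n"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BreedPanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        out = self.prevalence.copy()
        out.insert(0, "n", self.n_samples)
        out.index.name = "breed"
        out.to_csv(path, sep="\t")


def broadcast_phenotype(
    panel: BreedPanel, disease: str, samples: Sequence[SampleMeta]
) -> np.ndarray:
    """Assign each dog its breed's prevalence as a quantitative phenotype."""
    prev = panel.prevalence_of(disease)
    y = np.empty(len(samples))
    for i, s in enumerate(samples):
        if s.breed not in prev.index or np.isnan(prev[s.breed]):
            raise KeyError(f"sample {s.sample_id}: breed {s.breed!r} has no {disease} prevalence")
        y[i] = prev[s.breed]
    return y


def build_covariates(samples: Sequence[SampleMeta], extra: np.ndarray | None = None) -> np.ndarray:
    """Intercept + sex covariate matrix (female 0, male 1, unknown mean-imputed)."""
    sex = np.array(
        [{"female": 0.0, "male": 1.0}.get(s.sex, np.nan) for s in samples]
    )
    if np.isnan(sex).all():
        sex[:] = 0.0
    elif np.isnan(sex).any():
        sex[np.isnan(sex)] = np.nanmean(sex)
    cols = [np.ones(len(samples)), sex]
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, float))
        if extra.shape[0] != len(samples):
            extra = extra.T
        cols.extend(extra.T)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """Null-model mixed-model fit: variance ratio and covariate effects."""

    variance_ratio: float
    log_restricted_likelihood: float
    alpha: np.ndarray
    sigma_e2: float
    converged: bool = True

    @property
    def sigma_g2(self) -> float:
        return self.variance_ratio * self.sigma_e2


def _reml_loglik(r: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Restricted log-likelihood (up to an additive constant) at variance ratio r.

    Inputs are already rotated into K's eigenbasis; ``s`` are K's eigenvalues.
    Returns (loglik, alpha, sigma_e2).
    """
    n, c = Xt.shape
    v = r * s + 1.0
    d = 1.0 / v
    Xd = Xt * d[:, None]
    A = Xt.T @ Xd
    b = Xd.T @ yt
    alpha = np.linalg.solve(A, b)
    rss = float(yt @ (d * yt) - b @ alpha)
    rss = max(rss, 1e-300)
    sign, logdet_a = np.linalg.slogdet(A)
    ll = -0.5 * (np.log(v).sum() + logdet_a + (n - c) * np.log(rss))
    return ll, alpha, rss / (n - c)


def _optimize_r(s, yt, Xt, n_grid: int = 41):
    lo, hi = np.log(_R_BOUNDS[0]), np.log(_R_BOUNDS[1])
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([_reml_loglik(np.exp(g), s, yt, Xt)[0] for g in grid])
    k = int(np.argmax(lls))
    converged = 0 < k < n_grid - 1
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    # golden-section on log r
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1 = _reml_loglik(np.exp(x1), s, yt, Xt)[0]
    f2 = _reml_loglik(np.exp(x2), s, yt, Xt)[0]
    while (b - a) > _GOLDEN_RTOL:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = _reml_loglik(np.exp(x2), s, yt, Xt)[0]
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = _reml_loglik(np.exp(x1), s, yt, Xt)[0]
    r = float(np.exp((a + b) / 2.0))
    return r, converged


def reml_variance_ratio(
    y: np.ndarray,
    W: np.ndarray,
    K: RelatednessMatrix | None,
) -> LmmFit:
    """REML estimate of the genetic-to-residual variance ratio under the null.

    ``K = None`` (or a zero matrix) degenerates to ordinary least squares:
    the ratio is reported as 0 and ``sigma_e2`` is the OLS residual variance.
    """
    y = np.asarray(y, float)
    W = np.atleast_2d(np.asarray(W, float))
    n, c = W.shape
    if n <= c + 2:
        raise ValueError(f"need n > c + 2 (n={n}, c={c})")
    if K is None or np.allclose(K.K, 0.0):
        zero = np.zeros(n)
        ll, alpha, s2 = _reml_loglik(0.0, zero, y, W)
        return LmmFit(0.0, ll, alpha, s2, converged=True)
    basis = K.eigen()
    s = basis.eigenvalues
    U = basis.eigenvectors
    yt, Wt = U.T @ y, U.T @ W
    r, converged = _optimize_r(s, yt, Wt)
    ll, alpha, s2 = _reml_loglik(r, s, yt, Wt)
    return LmmFit(r, ll, alpha, s2, converged=converged)


# ---------------------------------------------------------------------------
# SNP scans (LMM / binary)
# ---------------------------------------------------------------------------

def _result_table(variants, beta, se, stat, p, model, flags) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "beta": beta,
            "se": se,
            "stat": stat,
            "p": p,
            "model": model,
            "flags": flags,
        },
        columns=RESULT_COLUMNS,
    )


def _gls_scan_fixed_r(r, s, yt, Wt, Gt):
    """Vectorized per-SNP GLS given a shared variance ratio.

    Returns (beta, se, fstat, p, degenerate) with a Wald F(1, n-c-1) p-value.
    All arrays live in K's eigenbasis; V is diagonal there.
    """
    n, c = Wt.shape
    d = 1.0 / (r * s + 1.0)
    Wd = Wt * d[:, None]
    A = Wt.T @ Wd
    Ainv = np.linalg.inv(A)
    wy = Wd.T @ yt
    yPy = float(yt @ (d * yt) - wy @ (Ainv @ wy))
    B = Wd.T @ Gt                      # c x p
    AB = Ainv @ B
    xDx = (d[:, None] * Gt * Gt).sum(axis=0)
    xPx = xDx - (B * AB).sum(axis=0)
    xDy = Gt.T @ (d * yt)
    xPy = xDy - B.T @ (Ainv @ wy)
    df = n - c - 1
    scale = np.maximum(xDx, 1.0)
    degenerate = xPx <= 1e-10 * scale
    xPx_safe = np.where(degenerate, 1.0, xPx)
    beta = xPy / xPx_safe
    rss = np.maximum(yPy - beta * xPy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 / xPx_safe, 0.0))
    perfect = (se == 0.0) & ~degenerate & (beta != 0.0)  # exact fit: RSS ~ 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = np.where(se > 0, (beta / np.where(se > 0, se, 1.0)) ** 2, 0.0)
    p = stats.f.sf(fstat, 1, df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fstat = np.where(perfect, np.inf, fstat)
    p = np.where(perfect, np.finfo(float).tiny, p)
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.nan, se)
    fstat = np.where(degenerate, 0.0, fstat)
    p = np.where(degenerate, 1.0, p)
    return beta, se, fstat, p, degenerate


def lmm_scan(
    gm: GenotypeMatrix,
    y: np.ndarray,
    covars: np.ndarray,
    K: RelatednessMatrix | None,
    per_snp_r: bool = True,
    model_tag: str = "lmm",
) -> pd.DataFrame:
    """Mixed-model Wald scan of every SNP.

    Missing dosages are mean-imputed per site.  With ``per_snp_r`` (default)
    the variance ratio is re-optimized for every candidate SNP; with the fast
    mode the null-model ratio is reused for all SNPs — the standard
    approximation trading a small loss of exactness for an order-of-magnitude
    speedup on large panels.  SNPs collinear with the covariates are returned
    with p = 1 and a ``degenerate`` flag rather than dropped.
    """
    y = np.asarray(y, float)
    n = gm.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype length must match sample count")
    W = np.atleast_2d(np.asarray(covars, float))
    if W.shape[0] != n:
        raise ValueError("covariate rows must match sample count")
    G, _ = mean_impute(gm.dosages)
    if K is None or np.allclose(K.K, 0.0):
        s = np.zeros(n)
        U = None
        yt, Wt, Gt = y, W, G
        r0 = 0.0
    else:
        basis = K.eigen()
        s, U = basis.eigenvalues, basis.eigenvectors
        yt, Wt, Gt = U.T @ y, U.T @ W, U.T @ G
        r0, _ = _optimize_r(s, yt, Wt)

    if per_snp_r and U is not None:
        p_snps = G.shape[1]
        beta = np.empty(p_snps)
        se = np.empty(p_snps)
        fstat = np.empty(p_snps)
        pvals = np.empty(p_snps)
        degen = np.zeros(p_snps, dtype=bool)
        for j in range(p_snps):
            x = Gt[:, j]
            if np.allclose(x - x.mean(), 0.0):
                rj = r0
            else:
                rj, _ = _optimize_r(s, yt, np.column_stack([Wt, x]), n_grid=21)
            b_, s_, f_, p_, d_ = _gls_scan_fixed_r(rj, s, yt, Wt, x[:, None])
            beta[j], se[j], fstat[j], pvals[j], degen[j] = (
                b_[0], s_[0], f_[0], p_[0], d_[0],
            )
    else:
        beta, se, fstat, pvals, degen = _gls_scan_fixed_r(r0, s, yt, Wt, Gt)
    flags = np.where(degen, "degenerate", "")
    return _result_table(gm.variants, beta, se, fstat, pvals, model_tag, flags)


# ---------------------------------------------------------------------------
# Binary case-control
# ---------------------------------------------------------------------------

def assign_binary_phenotype(
    panel: BreedPanel,
    disease: str,
    low_cut: float,
    high_cut: float,
    samples: Sequence[SampleMeta],
) -> tuple[np.ndarray, list[str]]:
    """Dichotomize breed prevalence into low-risk controls and high-risk cases.

    Breeds with prevalence <= ``low_cut`` become controls (0), >= ``high_cut``
    cases (1); intermediate breeds are excluded (their dogs get NaN labels).
    Cuts accept the same percent-or-fraction convention as the panel.
    Returns ``(labels, excluded_breeds)``.
    """
    if low_cut > 1.0:
        low_cut /= 100.0
    if high_cut > 1.0:
        high_cut /= 100.0
    if low_cut >= high_cut:
        raise ValueError(f"low_cut must be < high_cut ({low_cut} >= {high_cut})")
    prev = panel.prevalence_of(disease).dropna()
    controls = set(prev.index[prev <= low_cut])
    cases = set(prev.index[prev >= high_cut])
    if not controls or not cases:
        lo = prev.min()
        hi = prev.max()
        raise ValueError(
            f"empty {'control' if not controls else 'case'} group for cuts "
            f"({low_cut:g}, {high_cut:g}); observed prevalence spans "
            f"[{lo:g}, {hi:g}] — nearest feasible cuts are low >= {lo:g}, high <= {hi:g}"
        )
    excluded = sorted(set(prev.index) - controls - cases)
    labels = np.full(len(samples), np.nan)
    for i, s in enumerate(samples):
        if s.breed in cases:
            labels[i] = 1.0
        elif s.breed in controls:
            labels[i] = 0.0
    return labels, excluded


def binary_casecontrol_scan(
    gm: GenotypeMatrix,
    labels: np.ndarray,
    covars: np.ndarray,
    K: RelatednessMatrix | None,
    per_snp_r: bool = True,
) -> pd.DataFrame:
    """Case-control scan: the LMM machinery applied to a 0/1 phenotype.

    Rows with NaN labels (excluded breeds) are dropped here, along with the
    matching rows/columns of K.  Valid when SNP effects are small, where the
    linear approximation to the binary trait is accurate.
    """
    labels = np.asarray(labels, float)
    keep = np.flatnonzero(~np.isnan(labels))
    lab = labels[keep]
    if np.all(lab == lab[0] if lab.size else True):
        raise ValueError("binary scan needs both cases and controls")
    sub = gm.take_samples(keep)
    W = np.atleast_2d(np.asarray(covars, float))[keep]
    Ksub = None
    if K is not None:
        Ksub = RelatednessMatrix(K.K[np.ix_(keep, keep)], K.n_sites_used)
    return lmm_scan(sub, lab, W, Ksub, per_snp_r=per_snp_r, model_tag="binary")


# ---------------------------------------------------------------------------
# Haplotype windows
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeWindow:
    """EM-phased fixed-width SNP window.

    ``hap_labels`` are allele strings over {'0' ref, '1' alt}; ``dosage_labels``
    name the columns of ``expected_dosages`` after rare haplotypes (frequency
    below the pooling cutoff) are merged into a single ``rare`` class.
    """

    snp_indices: np.ndarray
    hap_labels: list[str]
    frequencies: np.ndarray
    dosage_labels: list[str]
    expected_dosages: np.ndarray   # retained samples x pooled haplotypes
    retained: np.ndarray           # indices into the original sample axis
    n_excluded: int
    loglik: float
    converged: bool
    stat: float = np.nan
    p: float = np.nan
    flags: str = ""


def _phase_pairs(pattern: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All unordered haplotype pairs compatible with one genotype pattern.

    Haplotype index packs alleles little-endian: site k contributes 2**k.
    Returns (h1, h2, mult) with mult 2 for heterozygous-ordered pairs.
    """
    w = pattern.size
    het = np.flatnonzero(pattern == 1.0)
    base1 = sum(2**k for k in range(w) if pattern[k] == 2.0)
    h1s, h2s, mult = [], [], []
    n_het = het.size
    if n_het == 0:
        return np.array([base1]), np.array([base1]), np.array([1.0])
    for mask in range(2 ** (n_het - 1)):  # fix first het site to hap1 -> unordered
        a = base1 + 2 ** het[0]
        b = base1
        for t in range(1, n_het):
            if (mask >> (t - 1)) & 1:
                a += 2 ** het[t]
            else:
                b += 2 ** het[t]
        h1s.append(a)
        h2s.append(b)
        mult.append(2.0)
    return np.array(h1s), np.array(h2s), np.array(mult)


def haplotype_em(
    block: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    rare_freq: float = 0.01,
    snp_indices: np.ndarray | None = None,
) -> HaplotypeWindow | None:
    """EM haplotype-frequency estimation for one window of unphased dosages.

    Individuals with any missing genotype in the window are excluded (their
    count is recorded).  The E-step weights each individual's compatible
    phase pairs in proportion to products of current frequencies; the M-step
    re-estimates frequencies from expected counts.  Convergence: max
    frequency change < ``tol`` or ``max_iter`` iterations.  Returns ``None``
    when no individual is fully genotyped in the window.
    """
    block = np.asarray(block, float)
    n, w = block.shape
    retained = np.flatnonzero(~np.isnan(block).any(axis=1))
    n_excluded = n - retained.size
    if retained.size == 0:
        return None
    obs = block[retained]
    patterns, inverse, counts = np.unique(
        obs, axis=0, return_inverse=True, return_counts=True
    )
    n_pat = patterns.shape[0]
    pairs = [_phase_pairs(patterns[k]) for k in range(n_pat)]
    # flatten all patterns' phase pairs for vectorized EM iterations
    h1_all = np.concatenate([p[0] for p in pairs])
    h2_all = np.concatenate([p[1] for p in pairs])
    mult_all = np.concatenate([p[2] for p in pairs])
    pat_id = np.concatenate(
        [np.full(p[0].size, k) for k, p in enumerate(pairs)]
    )
    H = 2**w
    f = np.full(H, 1.0 / H)
    loglik = -np.inf
    converged = False
    post = mult_all / np.maximum(np.bincount(pat_id, mult_all, minlength=n_pat), 1)[pat_id]
    for _ in range(max_iter):
        wgt = f[h1_all] * f[h2_all] * mult_all
        tot = np.bincount(pat_id, weights=wgt, minlength=n_pat)
        ok = tot > 0.0
        safe_tot = np.where(ok, tot, 1.0)
        post = np.where(ok[pat_id], wgt / safe_tot[pat_id], post)
        loglik = float(counts[ok] @ np.log(tot[ok]))
        cpost = counts[pat_id] * post
        new_counts = np.bincount(h1_all, weights=cpost, minlength=H)
        new_counts += np.bincount(h2_all, weights=cpost, minlength=H)
        f_new = new_counts / (2.0 * counts.sum())
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            converged = True
            break

    # expected per-sample haplotype dosages from the final posteriors
    wgt = f[h1_all] * f[h2_all] * mult_all
    tot = np.bincount(pat_id, weights=wgt, minlength=n_pat)
    ok = tot > 0.0
    post = np.where(ok[pat_id], wgt / np.where(ok, tot, 1.0)[pat_id], post)
    dose_pattern = np.zeros((n_pat, H))
    np.add.at(dose_pattern, (pat_id, h1_all), post)
    np.add.at(dose_pattern, (pat_id, h2_all), post)
    dosages_full = dose_pattern[inverse]

    labels = [format(h, f"0{w}b")[::-1] for h in range(H)]  # site order, '0'=ref
    common = np.flatnonzero(f >= rare_freq)
    rare = np.flatnonzero((f < rare_freq) & (f > 0))
    cols, col_labels = [], []
    for h in common:
        cols.append(dosages_full[:, h])
        col_labels.append(labels[h])
    if rare.size:
        cols.append(dosages_full[:, rare].sum(axis=1))
        col_labels.append("rare")
    return HaplotypeWindow(
        snp_indices=np.arange(w) if snp_indices is None else np.asarray(snp_indices),
        hap_labels=labels,
        frequencies=f,
        dosage_labels=col_labels,
        expected_dosages=np.column_stack(cols) if cols else np.empty((retained.size, 0)),
        retained=retained,
        n_excluded=n_excluded,
        loglik=float(loglik),
        converged=converged,
    )


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of an OLS fit."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def haplotype_scan(
    gm: GenotypeMatrix,
    y: np.ndarray,
    pcs: np.ndarray | StructureBasis,
    n_pcs: int | None = None,
    window_size: int = 4,
    rare_freq: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sliding-window haplotype omnibus scan.

    Windows of ``window_size`` consecutive SNPs slide by one within each
    chromosome (``max(0, sites - window_size + 1)`` windows per chromosome).
    Per window: EM haplotype dosages, drop the most frequent haplotype as
    reference, and an omnibus F-test of the remaining dosage columns over the
    covariates (intercept + eigenvectors).  Windows whose added columns carry
    no rank — a single non-rare haplotype, or collinearity with the
    covariates — are flagged degenerate with p = 1.

    Returns ``(window_table, snp_table)``; each SNP's p-value is the minimum
    over the windows containing it.
    """
    y = np.asarray(y, float)
    if isinstance(pcs, StructureBasis):
        k = n_pcs if n_pcs is not None else (pcs.k_selected or 2)
        E = pcs.top(k)
    else:
        E = np.atleast_2d(np.asarray(pcs, float))
        if E.shape[0] != gm.n_samples:
            E = E.T
    covars = np.column_stack([np.ones(gm.n_samples), E])

    chrom_of = np.array([v.chrom for v in gm.variants])
    rows = []
    snp_p = np.full(gm.n_variants, np.nan)
    for chrom in dict.fromkeys(chrom_of):
        idx = np.flatnonzero(chrom_of == chrom)
        for start in range(0, len(idx) - window_size + 1):
            jj = idx[start : start + window_size]
            win = haplotype_em(
                gm.dosages[:, jj], rare_freq=rare_freq, snp_indices=jj
            )
            pos_lo = gm.variants[jj[0]].pos
            pos_hi = gm.variants[jj[-1]].pos
            if win is None:
                rows.append((chrom, pos_lo, pos_hi, 0, np.nan, np.nan, "skipped"))
                continue
            ridx = win.retained
            # drop the most frequent pooled column as the reference class
            D = win.expected_dosages
            if D.shape[1] >= 2:
                ref_col = int(np.argmax([D[:, c].sum() for c in range(D.shape[1])]))
                D = np.delete(D, ref_col, axis=1)
            else:
                D = D[:, :0]
            yv = y[ridx]
            X0 = covars[ridx]
            stat, p, flag = np.nan, 1.0, ""
            if D.shape[1] == 0:
                flag = "degenerate"
            else:
                rss0, rank0 = _rss(yv, X0)
                rss1, rank1 = _rss(yv, np.column_stack([X0, D]))
                q = rank1 - rank0
                df2 = len(yv) - rank1
                if q <= 0 or df2 <= 0:
                    flag = "degenerate"
                elif rss1 <= 1e-300:
                    stat, p = np.inf, np.finfo(float).tiny
                else:
                    stat = ((rss0 - rss1) / q) / (rss1 / df2)
                    stat = max(stat, 0.0)
                    p = float(stats.f.sf(stat, q, df2))
                    p = min(max(p, np.finfo(float).tiny), 1.0)
            rows.append((chrom, pos_lo, pos_hi, D.shape[1], stat, p, flag))
            if flag == "":
                cur = snp_p[jj]
                snp_p[jj] = np.fmin(np.where(np.isnan(cur), p, cur), p)
    window_table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_hap_dof", "stat", "p", "flags"]
    )
    snp_table = _result_table(
        gm.variants,
        np.nan,
        np.nan,
        np.nan,
        np.where(np.isnan(snp_p), 1.0, snp_p),
        "haplotype",
        np.where(np.isnan(snp_p), "no_window", ""),
    )
    return window_table, snp_table


# ---------------------------------------------------------------------------
# Weighted least squares on breed averages
# ---------------------------------------------------------------------------

@dataclass
class WlsInputs:
    """Breed-level design for the weighted least-squares scan."""

    breeds: list[str]
    X: np.ndarray                   # breeds x SNPs average dosages, entries in [0,2]
    weights: np.ndarray             # breed sample proportions, sum to 1
    pcs: StructureBasis
    variants: list[Variant]
    n_dropped_snps: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if self.X.shape != (len(self.breeds), len(self.variants)):
            raise ValueError("X shape must be breeds x variants")


def breed_average_dosage(gm: GenotypeMatrix, panel: BreedPanel) -> WlsInputs:
    """Collapse the cohort to a breeds x SNPs matrix of average dosages.

    ``X[b, j]`` is the mean non-missing dosage of SNP j over breed b's
    samples; the weight of each breed is its share of the genotyped cohort.
    SNPs unobserved in any breed are dropped (count recorded).  Principal
    components are taken from the centered genomic relationship matrix of
    the rows of X.
    """
    breeds_here = [b for b in panel.breeds if b in set(gm.breeds)]
    unknown = set(gm.breeds) - set(panel.breeds)
    if unknown:
        raise ValueError(f"samples from breeds absent from the panel: {sorted(unknown)[:5]}")
    if len(breeds_here) < 3:
        raise ValueError("need >= 3 breeds with genotyped samples")
    sample_breed = np.array(gm.breeds)
    X = np.empty((len(breeds_here), gm.n_variants))
    counts = np.empty(len(breeds_here))
    with np.errstate(invalid="ignore"):
        for i, b in enumerate(breeds_here):
            rows = gm.dosages[sample_breed == b]
            counts[i] = rows.shape[0]
            X[i] = np.nanmean(rows, axis=0)
    keep = np.flatnonzero(~np.isnan(X).any(axis=0))
    n_dropped = gm.n_variants - keep.size
    if keep.size == 0:
        raise ValueError("no SNP observed in every breed")
    X = X[:, keep]
    grm = centered_grm(X)
    return WlsInputs(
        breeds=breeds_here,
        X=X,
        weights=counts / counts.sum(),
        pcs=grm.eigen(),
        variants=[gm.variants[j] for j in keep],
        n_dropped_snps=int(n_dropped),
    )


def wls_scan(inputs: WlsInputs, y: np.ndarray | pd.Series, n_pcs: int = 5) -> pd.DataFrame:
    """Weighted least squares of breed prevalence on breed-average SNP dosage.

    Per SNP j: ``y ~ 1 + pc1..pc_{n_pcs} + X[:, j]`` with breed-proportion
    weights; the slope is t-tested with ``n_breeds - n_pcs - 2`` degrees of
    freedom.  Equivalent to the weighted normal-equations solve
    ``(X' W X)^-1 X' W y`` for every SNP, vectorized across SNPs.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(inputs.breeds).to_numpy(dtype=float)
    y = np.asarray(y, float)
    B = len(inputs.breeds)
    if y.shape != (B,):
        raise ValueError("prevalence vector must align with breeds")
    if np.isnan(y).any():
        raise ValueError("prevalence contains missing breeds")
    if B <= n_pcs + 2:
        raise ValueError(f"need more breeds ({B}) than parameters ({n_pcs + 2})")
    W = np.column_stack([np.ones(B), inputs.pcs.top(n_pcs)]) if n_pcs else np.ones((B, 1))
    wts = inputs.weights
    # identical algebra to the GLS scan with diagonal weight matrix
    d = wts
    Wd = W * d[:, None]
    A = W.T @ Wd
    Ainv = np.linalg.inv(A)
    wy = Wd.T @ y
    yPy = float(y @ (d * y) - wy @ (Ainv @ wy))
    G = inputs.X
    Bm = Wd.T @ G
    xDx = (d[:, None] * G * G).sum(axis=0)
    xPx = xDx - (Bm * (Ainv @ Bm)).sum(axis=0)
    xPy = G.T @ (d * y) - Bm.T @ (Ainv @ wy)
    df = B - W.shape[1] - 1
    degenerate = xPx <= 1e-12 * np.maximum(xDx, 1.0)
    xPx_safe = np.where(degenerate, 1.0, xPx)
    beta = xPy / xPx_safe
    rss = np.maximum(yPy - beta * xPy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 / xPx_safe, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.nan, se)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    flags = np.where(degenerate, "degenerate", "")
    return _result_table(inputs.variants, beta, se, t, p, "wls", flags)
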