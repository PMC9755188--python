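"""Centered genomic relatedness matrix (GRM), eigendecomposition, scree selection.

The GRM is the centered (not standardized) form,
``K = (1/p) * sum_s (g_s - mean(g_s)) (g_s - mean(g_s))^T`` over the p retained
sites, the construction used by mixed-model association tools for
population-structure correction.  Missing dosages are mean-imputed per site
before the sum (with a logged count); monomorphic sites contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vcf_io import GenotypeMatrix

__all__ = [
    "RelatednessMatrix",
    "StructureBasis",
    "centered_grm",
    "grm_eigen",
    "scree_select",
    "mean_impute",
]

_EIG_CLAMP = -1e-10


def mean_impute(dosages: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace missing dosages with the per-site mean; returns (matrix, n imputed)."""
    out = np.array(dosages, dtype=float)
    miss = np.isnan(out)
    n_imputed = int(miss.sum())
    if n_imputed:
        col_mean = np.nanmean(np.where(miss.all(axis=0), 0.0, out), axis=0)
        col_mean = np.nan_to_num(col_mean)
        idx = np.nonzero(miss)
        out[idx] = col_mean[idx[1]]
    return out, n_imputed


@dataclass
class RelatednessMatrix:
    """Symmetric samples x samples relatedness matrix with row sums zero."""

    K: np.ndarray
    n_sites_used: int
    n_monomorphic: int = 0
    n_imputed: int = 0
    _eigen: "StructureBasis | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("K must be symmetric")

    @property
    def n_samples(self) -> int:
        return self.K.shape[0]

    def eigen(self) -> "StructureBasis":
        """Eigendecomposition, computed once and cached."""
        if self._eigen is None:
            self._eigen = grm_eigen(self)
        return self._eigen


@dataclass
class StructureBasis:
    """Eigenvalues (nonincreasing) and orthonormal eigenvectors of a GRM."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    k_selected: int | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be nonincreasing")

    def top(self, k: int) -> np.ndarray:
        """The leading k eigenvectors as covariate columns."""
        return self.eigenvectors[:, :k]


def centered_grm(gm: GenotypeMatrix | np.ndarray) -> RelatednessMatrix:
    """Centered GRM from a genotype matrix (samples x sites dosages).

    Equivalent to the naive per-site outer-product sum
    ``(1/p) * sum_s z_s z_s^T`` with ``z_s = g_s - mean(g_s)``, computed as a
    single matrix product.  The divisor p counts every retained site,
    including monomorphic ones (which contribute zero and are tallied).
    """
    dosages = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm, float)
    if dosages.size == 0:
        raise ValueError("empty genotype matrix")
    Z, n_imputed = mean_impute(dosages)
    p = Z.shape[1]
    col_mean = Z.mean(axis=0)
    Z = Z - col_mean
    mono = (np.abs(Z).max(axis=0) == 0.0)
    n_mono = int(mono.sum())
    if n_mono == p:
        raise ValueError("zero polymorphic sites: GRM undefined")
    K = (Z @ Z.T) / p
    K = (K + K.T) / 2.0
    return RelatednessMatrix(K, n_sites_used=p, n_monomorphic=n_mono, n_imputed=n_imputed)


def grm_eigen(K: RelatednessMatrix | np.ndarray) -> StructureBasis:
    """Full symmetric eigendecomposition, eigenvalues sorted nonincreasing.

    Small numerical negatives are clamped at 0 (tolerance 1e-10); a genuinely
    negative spectrum raises, since a GRM is positive semidefinite by
    construction.
    """
    mat = K.K if isinstance(K, RelatednessMatrix) else np.asarray(K, dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("relatedness matrix contains non-finite entries")
    vals, vecs = np.linalg.eigh(mat)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(1.0, float(np.abs(vals).max()))
    if vals.min() < _EIG_CLAMP * scale * 1e4:
        raise ValueError("matrix is not positive semidefinite")
    vals = np.maximum(vals, 0.0)
    return StructureBasis(vals, vecs)


def scree_select(
    eigenvalues: np.ndarray, k_max: int = 20, override: int | None = None
) -> tuple[int, bool]:
    """Choose the number of eigenvector covariates by the scree-elbow rule.

    The elbow is the index (1-based component count) maximizing the second
    difference of the eigenvalue sequence over positions 2..k_max — the point
    where the curve bends hardest.  Smooth (e.g. geometric) decay has no
    meaningful elbow; the smallest admissible count is returned with a
    low-confidence flag.  ``override`` always wins (returned as-is), matching
    practice where the component count is fixed after visual scree inspection.

    Returns ``(k_selected, low_confidence)``.
    """
    if override is not None:
        if override < 1:
            raise ValueError("override must be >= 1")
        return int(override), False
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("scree selection needs >= 3 eigenvalues")
    k_max = min(k_max, lam.size - 1)
    # second difference at interior component k (1-based): lam[k-2] - 2 lam[k-1] + lam[k]
    ks = np.arange(2, k_max + 1)
    d2 = lam[ks - 2] - 2.0 * lam[ks - 1] + lam[ks]
    best = int(ks[np.argmax(d2)])
    # no-elbow detection: near-constant decay ratios mean the curve bends
    # nowhere in particular (e.g. strictly geometric eigenvalue decay)
    head = lam[: k_max + 1]
    pos = head[head > 0]
    low_conf = False
    if pos.size >= 3:
        ratios = pos[1:] / pos[:-1]
        low_conf = bool(ratios.max() - ratios.min() < 0.05)
    elif lam[0] <= 0:
        low_conf = True
    if low_conf:
        best = 2
    return best, low_conf
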