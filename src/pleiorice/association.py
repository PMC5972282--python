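"""Kinship, principal components, and the per-SNP mixed-linear-model scan.

The scan fits, per SNP,

    y = mu + PC gamma + x beta + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with variance components by REML on the spectral decomposition of K.  The
default mode is P3D ("population parameters previously determined"): the
ratio lambda = sg^2/se^2 is estimated once under the null model and reused
for every SNP, which reduces each SNP test to a weighted regression in the
rotated basis.  ``mode='exact'`` re-estimates lambda per SNP.  The per-SNP
test is a Wald t-test on beta with the residual variance re-estimated from
the SNP model, so in the K = I limit it coincides with the OLS F-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix

_RIDGE = 1e-6


@dataclass
class KinshipMatrix:
    """VanRaden genomic relationship matrix (accessions x accessions)."""

    accessions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.values, dtype=float)
        n = len(self.accessions)
        if k.shape != (n, n):
            raise ValueError("kinship shape does not match accession count")
        if not np.allclose(k, k.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        self.values = (k + k.T) / 2.0


@dataclass
class PCScores:
    """Principal-component scores of the genotype matrix."""

    accessions: list[str]
    scores: np.ndarray  # n x k
    explained_variance_ratio: np.ndarray


@dataclass
class SpectralK:
    """Eigendecomposition of K (+ ridge), reusable across scans."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns

    @classmethod
    def from_kinship(cls, K: KinshipMatrix) -> "SpectralK":
        k = K.values + _RIDGE * np.eye(len(K.accessions))
        w, u = np.linalg.eigh(k)
        if w.min() < -1e-8:
            raise ValueError("kinship not positive semi-definite after ridge")
        return cls(np.clip(w, 0.0, None), u)


def _imputed_centered(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed dosages and alt frequencies (for K and PCA only)."""
    d = geno.dosage
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mean, d)
    p = mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    return d[:, poly], p[poly]


def compute_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden kinship: Z Z' / (2 sum p(1-p)) on centered dosages."""
    if geno.n_accessions < 2 or geno.n_snps < 1:
        raise ValueError("kinship needs >= 2 accessions and >= 1 SNP")
    d, p = _imputed_centered(geno)
    z = d - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    k = (z @ z.T) / denom
    return KinshipMatrix(list(geno.accessions), k)


def compute_pcs(geno: GenotypeMatrix, k: int) -> PCScores:
    """Top-k PCs of the centered, scaled genotype matrix.

    Columns are scaled by sqrt(2 p (1-p)); the sign of each component is
    fixed by making its largest-magnitude accession score positive.
    """
    if k <= 0:
        raise ValueError("number of PCs must be positive")
    if k >= geno.n_accessions:
        raise ValueError("k must be smaller than the number of accessions")
    d, p = _imputed_centered(geno)
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    total = float(np.sum(s**2))
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return PCScores(list(geno.accessions), scores, evr)


# ---------------------------------------------------------------------------
# REML in the rotated basis


def _reml_neg_loglik(
    log_lambda: float, s: np.ndarray, yr: np.ndarray, xr: np.ndarray
) -> float:
    """Negative restricted log-likelihood profiled over se^2.

    ``s`` are eigenvalues of K, ``yr``/``xr`` the rotated response and
    fixed-effect design; lambda = sg^2/se^2.
    """
    lam = math.exp(log_lambda)
    w = 1.0 / (lam * s + 1.0)  # proportional to inverse variances
    xtwx = (xr * w[:, None]).T @ xr
    xtwy = (xr * w[:, None]).T @ yr
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - xr @ beta
    n, p = xr.shape
    rss = float(np.sum(w * r * r))
    if rss <= 0:
        return np.inf
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    _, logdet_xtx = np.linalg.slogdet(xr.T @ xr)
    ll = -0.5 * (
        (n - p) * math.log(2.0 * math.pi * rss / (n - p))
        + (n - p)
        + float(np.sum(np.log(lam * s + 1.0)))
        + logdet_xtwx
        - logdet_xtx
    )
    return -ll


def estimate_lambda(
    s: np.ndarray,
    yr: np.ndarray,
    xr: np.ndarray,
    grid: tuple[float, float, int] = (-10.0, 10.0, 41),
    tol: float = 1e-6,
) -> float:
    """REML estimate of lambda = sg^2/se^2 by grid search + Brent refinement."""
    lo, hi, m = grid
    pts = np.linspace(lo, hi, m)
    vals = [_reml_neg_loglik(x, s, yr, xr) for x in pts]
    i = int(np.argmin(vals))
    a = pts[max(i - 1, 0)]
    b = pts[min(i + 1, m - 1)]
    if a == b:
        best = pts[i]
    else:
        best = optimize.minimize_scalar(
            _reml_neg_loglik,
            bounds=(a, b),
            args=(s, yr, xr),
            method="bounded",
            options={"xatol": tol},
        ).x
    return math.exp(float(best))


def _wald_scan(
    w: np.ndarray, yr: np.ndarray, x0r: np.ndarray, gr: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP weighted regression given weights ``w``.

    Returns (beta, se, p) with residual variance per SNP from the full
    model, t-distributed with n - p0 - 1 df.
    """
    sw = np.sqrt(w)
    yt = yr * sw
    x0t = x0r * sw[:, None]
    gt = gr * sw[:, None]
    q, _ = np.linalg.qr(x0t)
    ey = yt - q @ (q.T @ yt)
    ex = gt - q @ (q.T @ gt)
    sxx = np.einsum("ij,ij->j", ex, ex)
    sxy = ex.T @ ey
    syy = float(ey @ ey)
    n, p0 = x0t.shape
    df = n - p0 - 1
    beta = np.full(gr.shape[1], np.nan)
    se = np.full(gr.shape[1], np.nan)
    pvals = np.full(gr.shape[1], np.nan)
    ok = sxx > 1e-12
    beta[ok] = sxy[ok] / sxx[ok]
    rss = np.clip(syy - beta[ok] ** 2 * sxx[ok], 0.0, None)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, se, pvals


def pvc(geno_column: np.ndarray, pheno_vector: np.ndarray) -> float:
    """Phenotypic variance contribution: marginal one-SNP R^2.

    The squared Pearson correlation between dosage and phenotype over
    pairwise-complete accessions; equals the OLS R^2 of the single-SNP
    regression.
    """
    x = np.asarray(geno_column, dtype=float)
    y = np.asarray(pheno_vector, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        raise ValueError("PVC needs non-constant dosage and phenotype")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pvc_vector(dosage: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Marginal R^2 of every SNP column against y (vectorized, NaN-safe)."""
    out = np.full(dosage.shape[1], np.nan)
    miss = np.isnan(dosage)
    yv = y - y.mean()
    if not miss.any():
        xc = dosage - dosage.mean(axis=0)
        sxx = np.einsum("ij,ij->j", xc, xc)
        sxy = xc.T @ yv
        syy = float(yv @ yv)
        ok = (sxx > 0) & (syy > 0)
        out[ok] = (sxy[ok] ** 2) / (sxx[ok] * syy)
        return out
    for j in range(dosage.shape[1]):
        x = dosage[:, j]
        ok = ~np.isnan(x)
        xs, ys = x[ok], y[ok]
        if xs.size >= 3 and xs.std() > 0 and ys.std() > 0:
            r = np.corrcoef(xs, ys)[0, 1]
            out[j] = r * r
    return out


def mlm_scan(
    geno: GenotypeMatrix,
    pheno_vector: np.ndarray | pd.Series,
    K: KinshipMatrix,
    PCs: PCScores | None,
    mode: str = "p3d",
    trait: str = "",
    population: str = "full",
    environment: str = "",
    spectral: SpectralK | None = None,
) -> pd.DataFrame:
    """Mixed-linear-model association scan.

    Returns a DataFrame with one row per SNP: chrom, pos, id, beta, se,
    p, neg_log10_p, pvc, plus scan metadata columns.  Monomorphic SNPs
    get missing statistics.  Accessions with a missing phenotype are
    dropped; missing dosages are mean-imputed for the regression (PVC is
    computed pairwise-complete).
    """
    if mode not in ("p3d", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(pheno_vector, dtype=float)
    n = geno.n_accessions
    if y.shape != (n,):
        raise ValueError("phenotype length does not match accessions")
    if K.values.shape[0] != n:
        raise ValueError("kinship does not match accessions")
    keep = ~np.isnan(y)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 phenotyped accessions")
    if np.nanstd(y) == 0:
        raise ValueError("phenotype is constant")

    dosage = geno.dosage[keep]
    y = y[keep]
    x0 = np.ones((y.size, 1))
    if PCs is not None and PCs.scores.shape[1] > 0:
        x0 = np.hstack([x0, PCs.scores[keep]])

    if spectral is not None and keep.all():
        spec = spectral
    else:
        sub = KinshipMatrix(
            [a for a, m in zip(K.accessions, keep) if m],
            K.values[np.ix_(keep, keep)],
        )
        spec = SpectralK.from_kinship(sub)
    s, u = spec.eigenvalues, spec.eigenvectors

    yr = u.T @ y
    x0r = u.T @ x0
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(dosage, axis=0)
    g = np.where(np.isnan(dosage), col_mean, dosage)
    gr = u.T @ g

    pvc_vals = _pvc_vector(dosage, y)

    if mode == "p3d":
        lam = estimate_lambda(s, yr, x0r)
        w = 1.0 / (lam * s + 1.0)
        beta, se, pvals = _wald_scan(w, yr, x0r, gr)
    else:
        beta = np.full(geno.n_snps, np.nan)
        se = np.full(geno.n_snps, np.nan)
        pvals = np.full(geno.n_snps, np.nan)
        for j in range(geno.n_snps):
            if np.nanstd(dosage[:, j]) == 0:
                continue
            xj = np.hstack([x0r, gr[:, [j]]])
            lam = estimate_lambda(s, yr, xj)
            w = 1.0 / (lam * s + 1.0)
            bj, sj, pj = _wald_scan(w, yr, x0r, gr[:, [j]])
            beta[j], se[j], pvals[j] = bj[0], sj[0], pj[0]

    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(pvals)
    frame = geno.snp_frame()
    frame["beta"] = beta
    frame["se"] = se
    frame["p"] = pvals
    frame["neg_log10_p"] = neg_log10
    frame["pvc"] = pvc_vals
    frame["trait"] = trait
    frame["population"] = population
    frame["environment"] = environment
    return frame
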