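"""Structure-preserving permutation threshold for genome-wide significance.

The observed phenotype Y is split into a population-structure component Ps
(the least-squares fit of Y on the principal components) and a residual
genotypic component G = Y - Ps.  Each permutation reshuffles G across
accessions while keeping Ps fixed, rescans the candidate SNPs with the same
mixed-model settings, and the threshold is the most extreme p-value seen in
any permutation (P_perm).  A SNP in the original scan is declared
significant when its -log10(p) exceeds -log10(P_perm).

Only candidate SNPs — by default those with -log10(p) > 2 in the original
scan — are rescanned, in both the original comparison and the permutations,
which keeps the null and observed scans comparable while saving compute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import KinshipMatrix, PCScores, SpectralK, mlm_scan
from .genotype_io import GenotypeMatrix


@dataclass
class PhenotypeDecomposition:
    """Y = Ps + G: structure fit plus residual genotypic effect."""

    y: np.ndarray
    ps: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.ps + self.g, self.y, atol=1e-8):
            raise ValueError("Ps + G must reconstruct Y")


@dataclass
class PermutationThreshold:
    """Result of the permutation scan.

    ``p_perm`` is NaN when the candidate set was empty (no SNP can be
    declared significant); ``threshold_neg_log10`` is +inf in that case.
    """

    p_perm: float
    threshold_neg_log10: float
    n_perm: int
    seed: int
    candidate_rule: str
    n_candidates: int
    per_perm_min_p: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def defined(self) -> bool:
        return not math.isnan(self.p_perm)

    def significant_mask(self, assoc: pd.DataFrame) -> np.ndarray:
        """Boolean mask over ``assoc`` rows: -log10(p) > threshold."""
        if not self.defined:
            return np.zeros(len(assoc), dtype=bool)
        with np.errstate(invalid="ignore"):
            return assoc["neg_log10_p"].to_numpy() > self.threshold_neg_log10


def decompose_phenotype(
    pheno_vector: np.ndarray, pcs: PCScores | np.ndarray
) -> PhenotypeDecomposition:
    """Split Y into the PC regression fit (Ps) and its residual (G)."""
    y = np.asarray(pheno_vector, dtype=float)
    scores = pcs.scores if isinstance(pcs, PCScores) else np.asarray(pcs)
    if scores.ndim != 2 or scores.shape[0] != y.size:
        raise ValueError("PC score matrix does not match phenotype length")
    x = np.hstack([np.ones((y.size, 1)), scores])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("PC design is rank deficient")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    ps = x @ beta
    return PhenotypeDecomposition(y=y, ps=ps, g=y - ps)


def permutation_scan(
    geno: GenotypeMatrix,
    decomposition: PhenotypeDecomposition,
    K: KinshipMatrix,
    PCs: PCScores | None,
    n_perm: int = 1000,
    seed: int = 0,
    candidate_mask: np.ndarray | None = None,
    threshold_rule: str = "min",
    quantile: float = 0.05,
    mode: str = "p3d",
    spectral: SpectralK | None = None,
) -> PermutationThreshold:
    """Run the Ps + Gr permutation scan and return the threshold.

    ``candidate_mask`` restricts the scanned SNPs (typically the original
    scan's -log10(p) > 2 set).  ``threshold_rule='min'`` takes P_perm as
    the global minimum p over all permutations (the literal rule);
    ``'quantile'`` instead takes the ``quantile`` level of the
    per-permutation minima, which does not grow stricter without bound as
    n_perm increases.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if threshold_rule not in ("min", "quantile"):
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    if candidate_mask is None:
        candidate_mask = np.ones(geno.n_snps, dtype=bool)
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    n_candidates = int(candidate_mask.sum())
    rule = f"mask[{n_candidates}]"
    if n_candidates == 0:
        return PermutationThreshold(
            p_perm=float("nan"),
            threshold_neg_log10=float("inf"),
            n_perm=n_perm,
            seed=seed,
            candidate_rule=rule,
            n_candidates=0,
        )

    if spectral is None:
        spectral = SpectralK.from_kinship(K)
    rng = np.random.default_rng(seed)
    minima = np.empty(n_perm)
    if mode == "p3d":
        # fast path: the rotated genotypes are permutation-invariant, so
        # rotate them once; each permutation only re-rotates the phenotype,
        # re-estimates lambda by REML, and reruns the weighted regressions
        # (numerically identical to calling mlm_scan per permutation)
        from .association import _wald_scan, estimate_lambda

        dosage = geno.dosage[:, candidate_mask]
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(dosage, axis=0)
        g = np.where(np.isnan(dosage), col_mean, dosage)
        u, s = spectral.eigenvectors, spectral.eigenvalues
        gr_rot = u.T @ g
        n = g.shape[0]
        x0 = np.ones((n, 1))
        if PCs is not None and PCs.scores.shape[1] > 0:
            x0 = np.hstack([x0, PCs.scores])
        x0r = u.T @ x0
        for b in range(n_perm):
            y_star = decomposition.ps + rng.permutation(decomposition.g)
            yr = u.T @ y_star
            lam = estimate_lambda(s, yr, x0r)
            w = 1.0 / (lam * s + 1.0)
            _, _, p = _wald_scan(w, yr, x0r, gr_rot)
            minima[b] = np.nanmin(p) if np.isfinite(p).any() else 1.0
    else:
        sub = geno.subset_snps(candidate_mask)
        for b in range(n_perm):
            y_star = decomposition.ps + rng.permutation(decomposition.g)
            res = mlm_scan(sub, y_star, K, PCs, mode=mode, spectral=spectral)
            p = res["p"].to_numpy()
            minima[b] = np.nanmin(p) if np.isfinite(p).any() else 1.0
    if threshold_rule == "min":
        p_perm = float(np.min(minima))
    else:
        p_perm = float(np.quantile(minima, quantile))
    return PermutationThreshold(
        p_perm=p_perm,
        threshold_neg_log10=-math.log10(p_perm),
        n_perm=n_perm,
        seed=seed,
        candidate_rule=rule,
        n_candidates=n_candidates,
        per_perm_min_p=minima,
    )


def candidate_mask_from_scan(
    assoc: pd.DataFrame, min_neg_log10_p: float = 2.0
) -> np.ndarray:
    """Candidate filter: SNPs with -log10(p) above ``min_neg_log10_p``."""
    with np.errstate(invalid="ignore"):
        vals = assoc["neg_log10_p"].to_numpy()
    return np.nan_to_num(vals, nan=-np.inf) > min_neg_log10_p
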