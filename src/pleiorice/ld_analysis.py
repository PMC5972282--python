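"""Pairwise r^2, between-set mean LD for pleiotropic QTLs, LD tiers, and
the hitch-hiking correlation statistic.

Accessions are treated as inbred: each contributes one haplotype (its
homozygous allele at each SNP), so haplotype frequencies are counted
directly and no phasing is needed.  Heterozygous or missing calls are
excluded pairwise.  Undefined quantities propagate as NaN sentinels,
never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .qtl_calling import PleiotropicQTL

LD_TIERS = (0.2, 0.4, 0.6, 0.8)

UNDEFINED = float("nan")


def r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared LD correlation between two SNPs from inbred haplotypes.

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)) with haplotype
    frequencies counted over accessions homozygous and non-missing at
    both sites.  Returns NaN when fewer than two informative accessions
    remain or either site is monomorphic after exclusion.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = np.isin(a, (0.0, 2.0)) & np.isin(b, (0.0, 2.0))
    if ok.sum() < 2:
        return UNDEFINED
    ha = a[ok] / 2.0
    hb = b[ok] / 2.0
    pa = ha.mean()
    pb = hb.mean()
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return UNDEFINED
    pab = (ha * hb).mean()
    return float((pab - pa * pb) ** 2 / denom)


def mean_r2_between_sets(
    set_a_snps: list[str],
    set_b_snps: list[str],
    geno: GenotypeMatrix,
) -> tuple[float, int, int]:
    """Mean r^2 over the Cartesian product of two significant-SNP sets.

    Returns (mean, n_pairs_used, n_pairs_skipped); mean is NaN when every
    pair is undefined.  Shared SNP ids appearing in both sets contribute
    their self-pair (r^2 = 1) like any other pair.
    """
    if not set_a_snps or not set_b_snps:
        raise ValueError("both SNP sets must be non-empty")
    index = {s.id: j for j, s in enumerate(geno.snps)}
    cols_a = [index[i] for i in set_a_snps]
    cols_b = [index[i] for i in set_b_snps]
    vals = []
    n_skipped = 0
    for ja in cols_a:
        for jb in cols_b:
            v = r2(geno.dosage[:, ja], geno.dosage[:, jb])
            if math.isnan(v):
                n_skipped += 1
            else:
                vals.append(v)
    if not vals:
        return UNDEFINED, 0, n_skipped
    return float(np.mean(vals)), len(vals), n_skipped


def fill_pqtl_ld(pqtls: list[PleiotropicQTL], geno: GenotypeMatrix) -> None:
    """Compute and store mean cross-trait r^2 on each pQTL in place."""
    for q in pqtls:
        q.mean_r2, _, _ = mean_r2_between_sets(
            q.bin_a.snp_ids, q.bin_b.snp_ids, geno
        )


def ld_tiers(pqtls: list[PleiotropicQTL]) -> pd.DataFrame:
    """Strict-inequality tier counts (> 0.2 / 0.4 / 0.6 / 0.8) per trait
    pair; tiers are nested by construction."""
    rows = []
    pairs = sorted({(q.trait_a, q.trait_b) for q in pqtls})
    for ta, tb in pairs:
        sel = [
            q
            for q in pqtls
            if (q.trait_a, q.trait_b) == (ta, tb) and not math.isnan(q.mean_r2)
        ]
        row = {"trait_a": ta, "trait_b": tb, "n_pqtl": len(sel)}
        for tier in LD_TIERS:
            row[f"gt_{tier:g}"] = sum(q.mean_r2 > tier for q in sel)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["trait_a", "trait_b", "n_pqtl"]
        + [f"gt_{t:g}" for t in LD_TIERS],
    )


@dataclass
class HitchhikingResult:
    """Correlation between per-pQTL mean LD and the PVC deficit of the
    "foreign" bin, quantifying how much of one trait's signal at another
    trait's QTL is carried by linkage."""

    trait_x: str  # the hitch-hiking QTL's trait
    trait_y: str  # the trait whose variance is evaluated
    r: float
    n: int

    @property
    def label(self) -> str:
        return f"r_{self.trait_x}2{self.trait_y}"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def _bin_pvc(
    snp_ids: list[str], assoc_y: pd.DataFrame, aggregate: str
) -> float:
    """Aggregate PVC (toward trait Y) of a bin's member SNPs."""
    sub = assoc_y.set_index("id").reindex(snp_ids)["pvc"].dropna()
    if sub.empty:
        return UNDEFINED
    if aggregate == "mean":
        return float(sub.mean())
    if aggregate == "peak":
        return float(sub.max())
    raise ValueError(f"unknown PVC aggregate {aggregate!r}")


def hitchhiking_points(
    pqtls: list[PleiotropicQTL],
    assoc_by_trait: dict[str, pd.DataFrame],
    trait_x: str,
    trait_y: str,
    aggregate: str = "mean",
) -> tuple[list[float], list[float]]:
    """Per-pQTL (mean r^2, Delta-PVC) points for direction X -> Y.

    Delta-PVC = mean PVC to Y of the Y-bin's significant SNPs minus mean
    PVC to Y of the X-bin's significant SNPs, both read from the Y-trait
    scan.  pQTLs with undefined LD or PVC are dropped.
    """
    assoc_y = assoc_by_trait[trait_y]
    lds, dpvcs = [], []
    for q in pqtls:
        if {q.trait_a, q.trait_b} != {trait_x, trait_y}:
            continue
        if math.isnan(q.mean_r2):
            continue
        bin_x = q.bin_a if q.bin_a.trait == trait_x else q.bin_b
        bin_y = q.bin_a if q.bin_a.trait == trait_y else q.bin_b
        pvc_y = _bin_pvc(bin_y.snp_ids, assoc_y, aggregate)
        pvc_x = _bin_pvc(bin_x.snp_ids, assoc_y, aggregate)
        if math.isnan(pvc_y) or math.isnan(pvc_x):
            continue
        lds.append(q.mean_r2)
        dpvcs.append(pvc_y - pvc_x)
    return lds, dpvcs


def hitchhiking_correlation(
    pqtls: list[PleiotropicQTL],
    assoc_by_trait: dict[str, pd.DataFrame],
    trait_x: str,
    trait_y: str,
    aggregate: str = "mean",
) -> HitchhikingResult:
    """Pearson r between per-pQTL mean r^2 and Delta-PVC for direction
    X -> Y.

    Needs at least three usable pQTLs and non-constant vectors;
    otherwise the result carries the NaN sentinel.
    """
    lds, dpvcs = hitchhiking_points(
        pqtls, assoc_by_trait, trait_x, trait_y, aggregate
    )
    return hitchhiking_from_points(lds, dpvcs, trait_x, trait_y)


def hitchhiking_from_points(
    lds: list[float], dpvcs: list[float], trait_x: str, trait_y: str
) -> HitchhikingResult:
    """Correlate collected (LD, Delta-PVC) points; NaN below n=3 or with
    zero variance in either coordinate."""
    n = len(lds)
    if n < 3:
        return HitchhikingResult(trait_x, trait_y, UNDEFINED, n)
    lds_arr = np.asarray(lds)
    d_arr = np.asarray(dpvcs)
    if np.allclose(lds_arr, lds_arr[0]) or np.allclose(d_arr, d_arr[0]):
        return HitchhikingResult(trait_x, trait_y, UNDEFINED, n)
    r = float(np.corrcoef(lds_arr, d_arr)[0, 1])
    return HitchhikingResult(trait_x, trait_y, r, n)


def ld_report(pqtls: list[PleiotropicQTL], geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-pQTL LD report: mean r^2, pair counts, tier flags."""
    rows = []
    for q in pqtls:
        mean, n_pairs, n_skipped = mean_r2_between_sets(
            q.bin_a.snp_ids, q.bin_b.snp_ids, geno
        )
        q.mean_r2 = mean
        row = {
            "chrom": q.chrom,
            "start": q.start,
            "end": q.end,
            "trait_a": q.trait_a,
            "trait_b": q.trait_b,
            "population": q.population,
            "environment": q.environment,
            "mean_r2": mean,
            "n_pairs": n_pairs,
            "n_skipped": n_skipped,
        }
        for tier in LD_TIERS:
            row[f"gt_{tier:g}"] = bool(not math.isnan(mean) and mean > tier)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "trait_a", "trait_b", "population",
            "environment", "mean_r2", "n_pairs", "n_skipped",
        ]
        + [f"gt_{t:g}" for t in LD_TIERS],
    )
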