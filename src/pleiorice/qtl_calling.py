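"""QTL bin calling, pleiotropic-QTL intersection, pSNP/pGene annotation,
and percentage summaries.

A QTL bin is a chain of at least ``min_snps`` significant SNPs on one
chromosome in which adjacent significant SNPs are fewer than ``max_gap``
base pairs apart (default < 70 kb, the panel's LD scale).  A pleiotropic
QTL (pQTL) is a pair of bins from two traits in the same population and
environment whose intervals overlap by at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotype_io import GeneModel


@dataclass
class QTLBin:
    """A called QTL: span of its member significant SNPs (1-based incl.)."""

    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    snp_positions: list[int]
    peak_snp: str
    peak_neg_log10_p: float
    trait: str
    population: str
    environment: str

    def __post_init__(self) -> None:
        if len(self.snp_ids) < 1 or self.start > self.end:
            raise ValueError("malformed QTL bin")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class PleiotropicQTL:
    """Two overlapping QTL bins from different traits, same scan context."""

    trait_a: str
    trait_b: str
    bin_a: QTLBin
    bin_b: QTLBin
    chrom: str
    start: int  # merged interval
    end: int
    psnp_ids: list[str] = field(default_factory=list)
    pgene_ids: list[str] = field(default_factory=list)
    pgene_with_psnp_ids: list[str] = field(default_factory=list)
    mean_r2: float = float("nan")

    @property
    def population(self) -> str:
        return self.bin_a.population

    @property
    def environment(self) -> str:
        return self.bin_a.environment


def call_qtls(
    assoc: pd.DataFrame,
    significant_mask: np.ndarray,
    max_gap: int = 70_000,
    min_snps: int = 3,
) -> list[QTLBin]:
    """Chain significant SNPs into QTL bins.

    ``assoc`` must be coordinate-sorted with columns chrom/pos/id/
    neg_log10_p/trait/population/environment; ``significant_mask`` flags
    the SNPs above the permutation threshold.  Adjacent significant SNPs
    on one chromosome closer than ``max_gap`` (strict) join the same
    chain; chains with at least ``min_snps`` members become bins.
    """
    sig = assoc.loc[np.asarray(significant_mask, dtype=bool)]
    if sig.empty:
        return []
    sig = sig.sort_values(["chrom", "pos"], kind="mergesort")
    bins: list[QTLBin] = []
    for chrom, group in sig.groupby("chrom", sort=True):
        pos = group["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            chain = group.iloc[a : b + 1]
            if len(chain) < min_snps:
                continue
            peak = chain.iloc[int(chain["neg_log10_p"].to_numpy().argmax())]
            bins.append(
                QTLBin(
                    chrom=str(chrom),
                    start=int(chain["pos"].iloc[0]),
                    end=int(chain["pos"].iloc[-1]),
                    snp_ids=list(chain["id"]),
                    snp_positions=[int(p) for p in chain["pos"]],
                    peak_snp=str(peak["id"]),
                    peak_neg_log10_p=float(peak["neg_log10_p"]),
                    trait=str(chain["trait"].iloc[0]),
                    population=str(chain["population"].iloc[0]),
                    environment=str(chain["environment"].iloc[0]),
                )
            )
    bins.sort(key=lambda x: (x.chrom, x.start, x.end))
    return bins


def _overlap(a: QTLBin, b: QTLBin) -> bool:
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def intersect_qtls(
    bins_a: list[QTLBin],
    bins_b: list[QTLBin],
    genes: list[GeneModel] | None = None,
) -> list[PleiotropicQTL]:
    """Pair up overlapping bins of two traits into pleiotropic QTLs.

    pSNPs are the SNPs significant for both traits (member-id
    intersection).  With ``genes`` given, pGenes are genes whose span
    holds at least one significant SNP of *each* trait; the stricter
    pGene-with-pSNP class requires a shared significant SNP inside the
    gene.  Touching-but-not-overlapping intervals do not pair.
    """
    pqtls: list[PleiotropicQTL] = []
    for a in bins_a:
        for b in bins_b:
            if a.trait == b.trait:
                raise ValueError("intersect_qtls needs bins from two traits")
            if a.population != b.population or a.environment != b.environment:
                raise ValueError(
                    "bins must come from the same population and environment"
                )
            if not _overlap(a, b):
                continue
            shared = sorted(set(a.snp_ids) & set(b.snp_ids))
            pq = PleiotropicQTL(
                trait_a=a.trait,
                trait_b=b.trait,
                bin_a=a,
                bin_b=b,
                chrom=a.chrom,
                start=min(a.start, b.start),
                end=max(a.end, b.end),
                psnp_ids=shared,
            )
            if genes is not None:
                _annotate_pgenes(pq, genes)
            pqtls.append(pq)
    pqtls.sort(key=lambda q: (q.chrom, q.start, q.end))
    return pqtls


def _annotate_pgenes(pq: PleiotropicQTL, genes: list[GeneModel]) -> None:
    pos_a = dict(zip(pq.bin_a.snp_ids, pq.bin_a.snp_positions))
    pos_b = dict(zip(pq.bin_b.snp_ids, pq.bin_b.snp_positions))
    psnp = set(pq.psnp_ids)
    pgenes, with_psnp = [], []
    for gene in genes:
        if gene.chrom != pq.chrom or gene.end < pq.start or gene.start > pq.end:
            continue
        in_a = [i for i, p in pos_a.items() if gene.start <= p <= gene.end]
        in_b = [i for i, p in pos_b.items() if gene.start <= p <= gene.end]
        if in_a and in_b:
            pgenes.append(gene.gene_id)
            if psnp & (set(in_a) | set(in_b)):
                with_psnp.append(gene.gene_id)
    pq.pgene_ids = pgenes
    pq.pgene_with_psnp_ids = with_psnp


def round_percent(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_pleiotropy(
    pqtls: list[PleiotropicQTL],
    qtl_totals: dict[str, int],
    ld_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Per-trait-pair counts and percentages relative to each trait's
    total QTL number.

    Classes mirror the four summary tiers: all pQTLs, pQTLs with mean
    r^2 above ``ld_cutoff``, pQTLs containing pGenes, and pQTLs
    containing pGenes with pSNPs.  Percentages are computed for both
    traits of the pair.
    """
    rows = []
    pairs = sorted({(q.trait_a, q.trait_b) for q in pqtls})
    for ta, tb in pairs:
        if qtl_totals.get(ta, 0) <= 0 or qtl_totals.get(tb, 0) <= 0:
            raise ValueError(f"zero QTL total for trait pair ({ta}, {tb})")
        sel = [q for q in pqtls if (q.trait_a, q.trait_b) == (ta, tb)]
        classes = {
            "all": sel,
            f"ld_gt_{ld_cutoff:g}": [
                q for q in sel if not np.isnan(q.mean_r2) and q.mean_r2 > ld_cutoff
            ],
            "with_pgene": [q for q in sel if q.pgene_ids],
            "with_psnp_pgene": [q for q in sel if q.pgene_with_psnp_ids],
        }
        for cls, members in classes.items():
            n = len(members)
            rows.append(
                {
                    "trait_a": ta,
                    "trait_b": tb,
                    "class": cls,
                    "count": n,
                    "total_a": qtl_totals[ta],
                    "total_b": qtl_totals[tb],
                    "pct_of_a": round_percent(n, qtl_totals[ta]),
                    "pct_of_b": round_percent(n, qtl_totals[tb]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trait_a", "trait_b", "class", "count",
            "total_a", "total_b", "pct_of_a", "pct_of_b",
        ],
    )


def distinct_pqtl_intervals(pqtls: list[PleiotropicQTL]) -> int:
    """Number of distinct genomic loci among pQTLs, merging overlapping
    merged-intervals per population/environment (a locus shared by three
    traits counts once here but three times in the pairwise list)."""
    by_ctx: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for q in pqtls:
        by_ctx.setdefault((q.population, q.environment, q.chrom), []).append(
            (q.start, q.end)
        )
    n = 0
    for spans in by_ctx.values():
        spans.sort()
        cur_end = -1
        for s, e in spans:
            if s > cur_end:
                n += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
    return n


def bins_to_frame(bins: list[QTLBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "n_snps": b.n_snps,
                "peak_snp": b.peak_snp,
                "peak_neg_log10_p": b.peak_neg_log10_p,
                "trait": b.trait,
                "population": b.population,
                "environment": b.environment,
            }
            for b in bins
        ],
        columns=[
            "chrom", "start", "end", "n_snps", "peak_snp",
            "peak_neg_log10_p", "trait", "population", "environment",
        ],
    )


def pqtls_to_frame(pqtls: list[PleiotropicQTL]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "trait_a": q.trait_a,
                "trait_b": q.trait_b,
                "population": q.population,
                "environment": q.environment,
                "n_psnps": len(q.psnp_ids),
                "n_pgenes": len(q.pgene_ids),
                "n_pgenes_with_psnp": len(q.pgene_with_psnp_ids),
                "mean_r2": q.mean_r2,
            }
            for q in pqtls
        ],
        columns=[
            "chrom", "start", "end", "trait_a", "trait_b", "population",
            "environment", "n_psnps", "n_pgenes", "n_pgenes_with_psnp", "mean_r2",
        ],
    )
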