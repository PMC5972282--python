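"""Shared-pathway detection and the two-locus interaction (iGene) scan.

A pathway is "shared" when at least two distinct member genes carry
significant SNPs for at least two distinct traits.  Within each shared
pathway, every cross-trait gene pair is tested for statistical
interaction with a two-locus linear model at the genes' peak significant
SNPs:

    trait = mu + b1 * dosage(g1) + b2 * dosage(g2) + b12 * dosage(g1) * dosage(g2)

The Wald p-value of the product term is recorded for each trait of the
pair and Benjamini-Hochberg adjusted across all pairs tested for that
trait pair; pairs with q < alpha on at least one trait are reported as
iGene pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .genotype_io import GeneModel, GenotypeMatrix
from .ld_analysis import r2

logger = logging.getLogger(__name__)


@dataclass
class SharedPathway:
    """A pathway whose member genes hit >= 2 traits with >= 2 genes."""

    pathway_id: str
    genes_by_trait: dict[str, list[str]]  # trait -> gene ids
    contains_cloned: bool

    @property
    def genes(self) -> set[str]:
        return {g for gs in self.genes_by_trait.values() for g in gs}


@dataclass(frozen=True)
class IGenePair:
    """A significant cross-trait gene-gene interaction within a pathway."""

    gene_a: str
    gene_b: str
    pathway_id: str
    trait_a: str
    trait_b: str
    tested_trait: str
    snp_a: str
    snp_b: str
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("iGene pair needs two distinct genes")
        if self.q < self.p - 1e-12:
            raise ValueError("adjusted q must be >= p")


def find_shared_pathways(
    assoc_genes: dict[str, set[str]],
    genes: list[GeneModel],
    cloned: set[str] | None = None,
) -> list[SharedPathway]:
    """Pathways where >= 2 distinct genes are associated with >= 2
    distinct traits.

    ``assoc_genes`` maps trait -> gene ids carrying significant SNPs for
    that trait; pathway membership comes from the gene models; ``cloned``
    flags pathways containing a known cloned gene (membership test only).
    """
    cloned = cloned or set()
    pathway_members: dict[str, set[str]] = {}
    for g in genes:
        for pw in g.pathways:
            pathway_members.setdefault(pw, set()).add(g.gene_id)
    out: list[SharedPathway] = []
    for pw, members in sorted(pathway_members.items()):
        by_trait: dict[str, list[str]] = {}
        for trait, hit_genes in assoc_genes.items():
            inside = sorted(hit_genes & members)
            if inside:
                by_trait[trait] = inside
        involved = {g for gs in by_trait.values() for g in gs}
        if len(by_trait) >= 2 and len(involved) >= 2:
            out.append(
                SharedPathway(
                    pathway_id=pw,
                    genes_by_trait=by_trait,
                    contains_cloned=bool(involved & cloned),
                )
            )
    return out


def peak_snp_per_gene(
    assoc: pd.DataFrame,
    genes: list[GeneModel],
    significant_mask: np.ndarray,
) -> dict[str, str]:
    """Representative SNP per gene: its minimum-p significant SNP,
    ties broken by smaller position."""
    sig = assoc.loc[np.asarray(significant_mask, dtype=bool)]
    out: dict[str, str] = {}
    for gene in genes:
        inside = sig[
            (sig["chrom"] == gene.chrom)
            & (sig["pos"] >= gene.start)
            & (sig["pos"] <= gene.end)
        ]
        if inside.empty:
            continue
        best = inside.sort_values(["p", "pos"], kind="mergesort").iloc[0]
        out[gene.gene_id] = str(best["id"])
    return out


def _interaction_p(
    y: np.ndarray, xa: np.ndarray, xb: np.ndarray
) -> float:
    """Wald p of the product term in the two-locus model."""
    ok = ~(np.isnan(y) | np.isnan(xa) | np.isnan(xb))
    y, xa, xb = y[ok], xa[ok], xb[ok]
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    design = sm.add_constant(np.column_stack([xa, xb, xa * xb]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return float("nan")
    fit = sm.OLS(y, design).fit()
    return float(fit.pvalues[-1])


def igene_scan(
    shared: list[SharedPathway],
    geno: GenotypeMatrix,
    pheno_by_trait: dict[str, np.ndarray],
    representative_snp: dict[str, str],
    alpha: float = 0.05,
    collinearity_r2: float = 0.95,
) -> list[IGenePair]:
    """Scan cross-trait gene pairs inside shared pathways for interaction.

    For every pathway and unordered cross-trait gene pair, the product
    term is tested on both traits of the pair; BH adjustment is applied
    per trait pair over all tested pairs; a pair qualifies when q <
    ``alpha`` on at least one trait.  Pairs whose representative SNPs
    are nearly collinear (r^2 > ``collinearity_r2``) are skipped.
    """
    index = {s.id: j for j, s in enumerate(geno.snps)}
    tests: list[dict] = []
    seen: set[tuple] = set()
    for pw in shared:
        traits = sorted(pw.genes_by_trait)
        for ta, tb in itertools.combinations(traits, 2):
            for ga in pw.genes_by_trait[ta]:
                for gb in pw.genes_by_trait[tb]:
                    if ga == gb:
                        continue
                    g1, g2 = sorted((ga, gb))
                    key = (pw.pathway_id, ta, tb, g1, g2)
                    if key in seen:
                        continue
                    seen.add(key)
                    sa = representative_snp.get(ga)
                    sb = representative_snp.get(gb)
                    if sa is None or sb is None:
                        continue
                    xa = geno.dosage[:, index[sa]]
                    xb = geno.dosage[:, index[sb]]
                    pair_r2 = r2(xa, xb)
                    if not np.isnan(pair_r2) and pair_r2 > collinearity_r2:
                        logger.warning(
                            "skipping %s x %s in %s: representative SNPs "
                            "nearly collinear (r2=%.3f)",
                            ga, gb, pw.pathway_id, pair_r2,
                        )
                        continue
                    for tested in (ta, tb):
                        p = _interaction_p(pheno_by_trait[tested], xa, xb)
                        if np.isnan(p):
                            continue
                        tests.append(
                            {
                                "pathway_id": pw.pathway_id,
                                "trait_a": ta,
                                "trait_b": tb,
                                "tested_trait": tested,
                                "gene_a": ga,
                                "gene_b": gb,
                                "snp_a": sa,
                                "snp_b": sb,
                                "p": p,
                            }
                        )
    if not tests:
        return []
    df = pd.DataFrame(tests)
    df["q"] = np.nan
    for _, idx in df.groupby(["trait_a", "trait_b"]).groups.items():
        pvals = df.loc[idx, "p"].to_numpy()
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        df.loc[idx, "q"] = np.maximum(qvals, pvals)  # guard fp rounding
    hits = df[df["q"] < alpha]
    pairs: list[IGenePair] = []
    for _, row in hits.iterrows():
        pairs.append(
            IGenePair(
                gene_a=row["gene_a"],
                gene_b=row["gene_b"],
                pathway_id=row["pathway_id"],
                trait_a=row["trait_a"],
                trait_b=row["trait_b"],
                tested_trait=row["tested_trait"],
                snp_a=row["snp_a"],
                snp_b=row["snp_b"],
                p=float(row["p"]),
                q=float(row["q"]),
            )
        )
    return pairs


def igene_pairs_frame(pairs: list[IGenePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "pathway_id": p.pathway_id,
                "trait_a": p.trait_a,
                "trait_b": p.trait_b,
                "tested_trait": p.tested_trait,
                "snp_a": p.snp_a,
                "snp_b": p.snp_b,
                "p": p.p,
                "q": p.q,
            }
            for p in pairs
        ],
        columns=[
            "gene_a", "gene_b", "pathway_id", "trait_a", "trait_b",
            "tested_trait", "snp_a", "snp_b", "p", "q",
        ],
    )


def distinct_igene_pairs(pairs: list[IGenePair]) -> int:
    """Number of distinct (gene, gene) pairs among reported interactions."""
    return len({tuple(sorted((p.gene_a, p.gene_b))) for p in pairs})
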