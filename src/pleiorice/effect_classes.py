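"""Allele/haplotype effect-direction calls and same-/opposite-direction
classification, plus their distribution over variety classes.

A unit (a pSNP's allele groups, a pQTL or gene haplotype grouping) is
tested with a one-way fixed-effects model; group directions come from
all-pairs Tukey HSD comparisons at the configured alpha.  A group is
"increased" (I) when it sits significantly above at least one other group
and below none, "decreased" (D) in the mirror case, otherwise NS.  A unit
significant on two traits is SD when both directions agree (I,I or D,D),
OD when they oppose, and UNCLASSIFIED when either call is NS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genotype_io import AccessionMeta, GeneModel, GenotypeMatrix

logger = logging.getLogger(__name__)

SD = "SD"
OD = "OD"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class EffectCall:
    """Direction call of one group of one unit on one trait."""

    unit_id: str
    group: str
    trait: str
    direction: str  # 'I', 'D' or 'NS'
    group_mean: float
    n: int
    min_p_vs_others: float


@dataclass(frozen=True)
class SDODClass:
    """SD/OD class of one unit over a trait pair."""

    unit_id: str
    group: str
    trait_a: str
    trait_b: str
    direction_a: str
    direction_b: str
    sd_od: str


def call_effect(
    unit_partition: Mapping[str, Sequence[str]],
    pheno: pd.Series,
    unit_id: str,
    trait: str,
    alpha: float = 0.05,
    min_group_size: int = 2,
) -> list[EffectCall]:
    """Tukey-HSD direction calls for each group of one unit.

    ``unit_partition`` maps group label (allele or haplotype) to carrier
    accession ids; ``pheno`` is indexed by accession.  Groups below
    ``min_group_size`` are reported NS with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    small: set[str] = set()
    for label, members in unit_partition.items():
        vals = pheno.reindex(members).dropna().to_numpy()
        if vals.size < min_group_size:
            small.add(label)
            logger.warning(
                "unit %s group %s has %d phenotyped carriers; called NS",
                unit_id, label, vals.size,
            )
        groups[label] = vals
    usable = {k: v for k, v in groups.items() if k not in small}

    directions = {label: "NS" for label in groups}
    min_p = {label: float("nan") for label in groups}
    if len(usable) >= 2:
        values = np.concatenate(list(usable.values()))
        labels = np.concatenate(
            [np.full(v.size, k) for k, v in usable.items()]
        )
        if np.std(values) > 0:
            tuk = pairwise_tukeyhsd(values, labels, alpha=alpha)
            above: dict[str, int] = {k: 0 for k in usable}
            below: dict[str, int] = {k: 0 for k in usable}
            res = pd.DataFrame(
                tuk.summary().data[1:], columns=tuk.summary().data[0]
            )
            for _, row in res.iterrows():
                g1, g2 = str(row["group1"]), str(row["group2"])
                p = float(row["p-adj"])
                for g in (g1, g2):
                    min_p[g] = np.nanmin([min_p[g], p])
                if not bool(row["reject"]):
                    continue
                hi, lo = (g1, g2) if usable[g1].mean() > usable[g2].mean() else (g2, g1)
                above[hi] += 1
                below[lo] += 1
            for k in usable:
                if above[k] and not below[k]:
                    directions[k] = "I"
                elif below[k] and not above[k]:
                    directions[k] = "D"
    return [
        EffectCall(
            unit_id=unit_id,
            group=label,
            trait=trait,
            direction=directions[label],
            group_mean=float(np.mean(v)) if v.size else float("nan"),
            n=int(v.size),
            min_p_vs_others=float(min_p[label]),
        )
        for label, v in groups.items()
    ]


def classify_sd_od(call_a: EffectCall, call_b: EffectCall) -> SDODClass:
    """Map a pair of direction calls on two traits to SD/OD/UNCLASSIFIED."""
    if call_a.unit_id != call_b.unit_id or call_a.group != call_b.group:
        raise ValueError("calls must describe the same unit and group")
    da, db = call_a.direction, call_b.direction
    if "NS" in (da, db):
        cls = UNCLASSIFIED
    elif da == db:
        cls = SD
    else:
        cls = OD
    return SDODClass(
        unit_id=call_a.unit_id,
        group=call_a.group,
        trait_a=call_a.trait,
        trait_b=call_b.trait,
        direction_a=da,
        direction_b=db,
        sd_od=cls,
    )


@dataclass
class Haplotype:
    """One haplotype of a gene: allele string, carriers, frequency."""

    gene_id: str
    alleles: str  # e.g. 'ACA', or 'rare' for the pooled class
    carriers: list[str]
    frequency: float


def snp_allele_partition(
    geno: GenotypeMatrix, snp_id: str
) -> dict[str, list[str]]:
    """Homozygous carriers per allele of one SNP (het/missing excluded)."""
    index = {s.id: j for j, s in enumerate(geno.snps)}
    j = index[snp_id]
    snp = geno.snps[j]
    col = geno.dosage[:, j]
    out: dict[str, list[str]] = {snp.ref_allele: [], snp.alt_allele: []}
    for acc, d in zip(geno.accessions, col):
        if d == 0.0:
            out[snp.ref_allele].append(acc)
        elif d == 2.0:
            out[snp.alt_allele].append(acc)
    return out


def gene_haplotypes(
    geno: GenotypeMatrix, gene: GeneModel, min_freq: float = 0.05
) -> list[Haplotype]:
    """Enumerate homozygous haplotypes over the SNPs inside a gene span.

    Accessions with any heterozygous or missing call among the member
    SNPs are excluded; haplotypes rarer than ``min_freq`` are pooled
    into a 'rare' class.  Frequencies are over included accessions.
    """
    cols = [
        j
        for j, s in enumerate(geno.snps)
        if s.chrom == gene.chrom and gene.start <= s.pos <= gene.end
    ]
    if not cols:
        logger.warning("gene %s spans no SNPs", gene.gene_id)
        return []
    sub = geno.dosage[:, cols]
    homozygous = np.isin(sub, (0.0, 2.0)).all(axis=1)
    snps = [geno.snps[j] for j in cols]
    by_string: dict[str, list[str]] = {}
    for i in np.flatnonzero(homozygous):
        alleles = "".join(
            s.ref_allele if d == 0.0 else s.alt_allele
            for s, d in zip(snps, sub[i])
        )
        by_string.setdefault(alleles, []).append(geno.accessions[i])
    n_inc = int(homozygous.sum())
    if n_inc == 0:
        return []
    haps: list[Haplotype] = []
    rare_carriers: list[str] = []
    for alleles, carriers in sorted(
        by_string.items(), key=lambda kv: (-len(kv[1]), kv[0])
    ):
        freq = len(carriers) / n_inc
        if freq < min_freq:
            rare_carriers.extend(carriers)
        else:
            haps.append(Haplotype(gene.gene_id, alleles, carriers, freq))
    if rare_carriers:
        haps.append(
            Haplotype(gene.gene_id, "rare", rare_carriers, len(rare_carriers) / n_inc)
        )
    return haps


def haplotype_partition(haps: list[Haplotype]) -> dict[str, list[str]]:
    """Haplotype -> carriers mapping, excluding the pooled rare class."""
    return {h.alleles: h.carriers for h in haps if h.alleles != "rare"}


def distribution_by_variety(
    classes: list[tuple[SDODClass, Sequence[str]]],
    meta: AccessionMeta,
) -> pd.DataFrame:
    """Cross-tabulate SD/OD classes over the four variety classes.

    ``classes`` pairs each SD/OD classification with its carrier
    accessions.  Returns counts and within-variety-class fractions
    (fractions over all classified units, including UNCLASSIFIED).
    """
    variety = meta.variety_class()
    rows = []
    for cls, carriers in classes:
        for acc in carriers:
            if acc not in variety.index:
                raise KeyError(f"accession {acc!r} missing from metadata")
            rows.append(
                {
                    "unit_id": cls.unit_id,
                    "group": cls.group,
                    "sd_od": cls.sd_od,
                    "variety_class": variety[acc],
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["variety_class", "sd_od", "count", "fraction"]
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["variety_class", "sd_od"]).size().rename("count").reset_index()
    )
    totals = counts.groupby("variety_class")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts
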