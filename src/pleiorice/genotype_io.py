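"""Readers/writers for the formats the pipeline touches, plus the shared
coordinate and genotype-coding conventions.

Conventions
-----------
* All genomic coordinates are **1-based inclusive** inside the package.
  BED output is 0-based half-open; :func:`to_bed_interval` /
  :func:`from_bed_interval` are the only places the offset is applied.
* Genotypes are stored as alt-allele dosages in ``{0, 1, 2}`` with ``NaN``
  for missing calls.  Heterozygous calls (dosage 1) are tolerated in the
  matrix but excluded from LD and haplotype analyses, reflecting a largely
  homozygous inbred panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAITS = ("HD", "GNP", "PN", "KGW")
ENVIRONMENTS = ("SY", "CS")
SUBSPECIES = ("indica", "japonica")
STATUSES = ("landrace", "improved")

_VALID_ALLELES = frozenset("ACGT")


class VCFParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class EmptyResultError(ValueError):
    """Raised when filtering leaves nothing to analyse."""


# ---------------------------------------------------------------------------
# coordinate conversion — the single place BED offsets are applied


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive span -> 0-based half-open BED interval."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based span [{start}, {end}]")
    return start - 1, end


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive span."""
    if bed_start < 0 or bed_end <= bed_start:
        raise ValueError(f"invalid BED interval [{bed_start}, {bed_end})")
    return bed_start + 1, bed_end


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP: identity and alleles."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")
        for a in (self.ref_allele, self.alt_allele):
            if a not in _VALID_ALLELES:
                raise ValueError(f"allele {a!r} is not a single base")


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix with SNP coordinates.

    ``dosage[i, j]`` counts alt alleles of accession ``i`` at SNP ``j``
    (0/1/2, NaN = missing).  SNPs are kept sorted by (chrom, pos) with no
    duplicate site.
    """

    snps: list[SNPRecord]
    accessions: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.accessions), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.snps)} SNPs"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        keys = [(s.chrom, s.pos) for s in self.snps]
        if keys != sorted(keys):
            raise ValueError("SNPs must be sorted by (chrom, pos)")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) among SNPs")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.snps],
                "pos": [s.pos for s in self.snps],
                "id": [s.id for s in self.snps],
                "ref": [s.ref_allele for s in self.snps],
                "alt": [s.alt_allele for s in self.snps],
            }
        )

    def alt_freq(self) -> np.ndarray:
        """Per-SNP alt-allele frequency among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.accessions)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise KeyError(f"unknown accessions: {missing[:5]}")
        rows = [index[a] for a in ids]
        return GenotypeMatrix(list(self.snps), list(ids), self.dosage[rows])

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        snps = [s for s, m in zip(self.snps, mask) if m]
        return GenotypeMatrix(snps, list(self.accessions), self.dosage[:, mask])


@dataclass
class AccessionMeta:
    """Subspecies and breeding-status labels per accession."""

    table: pd.DataFrame  # columns: accession, subspecies, status

    def __post_init__(self) -> None:
        required = {"accession", "subspecies", "status"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"metadata needs columns {sorted(required)}")
        if self.table["accession"].duplicated().any():
            raise ValueError("duplicate accession in metadata")
        bad_sub = set(self.table["subspecies"]) - set(SUBSPECIES)
        bad_status = set(self.table["status"]) - set(STATUSES)
        if bad_sub:
            raise ValueError(f"unknown subspecies labels: {sorted(bad_sub)}")
        if bad_status:
            raise ValueError(f"unknown status labels: {sorted(bad_status)}")

    def accessions_in(self, population: str) -> list[str]:
        """Accession ids in 'full', 'indica' or 'japonica'."""
        if population == "full":
            return list(self.table["accession"])
        if population not in SUBSPECIES:
            raise ValueError(f"unknown population {population!r}")
        sel = self.table["subspecies"] == population
        return list(self.table.loc[sel, "accession"])

    def variety_class(self) -> pd.Series:
        """'indica-landrace' style label per accession (indexed by id)."""
        lab = self.table["subspecies"] + "-" + self.table["status"]
        return pd.Series(lab.values, index=self.table["accession"].values)


@dataclass
class PhenotypeTable:
    """Long-format accession x trait x environment phenotype values."""

    table: pd.DataFrame  # columns: accession, trait, environment, value

    def __post_init__(self) -> None:
        required = {"accession", "trait", "environment", "value"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"phenotypes need columns {sorted(required)}")
        bad_traits = set(self.table["trait"]) - set(TRAITS)
        if bad_traits:
            raise ValueError(f"unknown trait labels: {sorted(bad_traits)}")
        bad_envs = set(self.table["environment"]) - set(ENVIRONMENTS)
        if bad_envs:
            raise ValueError(f"unknown environment labels: {sorted(bad_envs)}")
        key = self.table[["accession", "trait", "environment"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate phenotype record for "
                f"({dup['accession']}, {dup['trait']}, {dup['environment']})"
            )
        values = self.table["value"]
        if np.isinf(values.fillna(0.0)).any():
            raise ValueError("phenotype values must be finite or missing")

    def vector(
        self, trait: str, environment: str, accessions: Sequence[str]
    ) -> pd.Series:
        """Phenotype values for one trait/environment, aligned to
        ``accessions`` (NaN where unmeasured)."""
        sel = (self.table["trait"] == trait) & (
            self.table["environment"] == environment
        )
        sub = self.table.loc[sel].set_index("accession")["value"]
        return sub.reindex(accessions)


@dataclass(frozen=True)
class GeneModel:
    """A gene span with optional pathway memberships."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    pathways: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | Path, min_maf: float = 0.05, max_missing: float = 0.5
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    SNPs with minor allele frequency below ``min_maf`` or a missing-call
    fraction above ``max_missing`` are dropped, as are indels and
    multiallelic records (counted in the log).
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        reader = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    accessions = list(reader.samples)
    if not accessions:
        raise VCFParseError(f"VCF {path} declares no samples")

    snps: list[SNPRecord] = []
    columns: list[np.ndarray] = []
    n_dropped_shape = 0
    for lineno, var in enumerate(reader, start=1):
        alts = var.ALT
        if (
            len(alts) != 1
            or len(var.REF) != 1
            or len(alts[0]) != 1
            or var.REF not in _VALID_ALLELES
            or alts[0] not in _VALID_ALLELES
        ):
            n_dropped_shape += 1
            continue
        try:
            rec = SNPRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=alts[0],
                id=var.ID or f"{var.CHROM}:{var.POS}",
            )
        except ValueError as exc:
            raise VCFParseError(f"record {lineno} of {path}: {exc}") from exc
        gts = np.asarray(var.genotype.array())[:, :2]
        dosage = np.where((gts < 0).any(axis=1), np.nan, gts.clip(0).sum(axis=1))
        snps.append(rec)
        columns.append(dosage.astype(float))
    if n_dropped_shape:
        logger.info(
            "read_vcf: dropped %d non-SNP/multiallelic records", n_dropped_shape
        )
    if not snps:
        raise EmptyResultError(f"no biallelic SNPs in {path}")

    dosage = np.column_stack(columns)
    order = np.lexsort(
        ([s.pos for s in snps], [s.chrom for s in snps])
    )
    snps = [snps[i] for i in order]
    dosage = dosage[:, order]
    geno = GenotypeMatrix(snps, accessions, dosage)
    geno = filter_genotypes(geno, min_maf=min_maf, max_missing=max_missing)
    if geno.n_snps == 0:
        raise EmptyResultError(
            f"no SNPs in {path} survive MAF >= {min_maf} and "
            f"missing <= {max_missing}"
        )
    return geno


def filter_genotypes(
    geno: GenotypeMatrix, min_maf: float = 0.05, max_missing: float = 0.5
) -> GenotypeMatrix:
    """Apply MAF/missingness retention filters (order-independent)."""
    keep = (geno.maf() >= min_maf) & (geno.missing_rate() <= max_missing)
    return geno.subset_snps(keep)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal VCF 4.2 file (GT only, unphased).

    Dosage 1 is written as ``0/1``; inbred simulation output contains only
    0/2 and round-trips exactly.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in geno.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accessions)
            + "\n"
        )
        for j, snp in enumerate(geno.snps):
            calls = [
                "./." if math.isnan(d) else gt_map[d] for d in geno.dosage[:, j]
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.ref_allele}\t"
                f"{snp.alt_allele}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# phenotype / metadata TSVs


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a TSV with columns accession/trait/environment/value.

    'NA' or empty values become missing entries; the accession is retained.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str}, na_values=["NA"])
    required = ["accession", "trait", "environment", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    return PhenotypeTable(df[required].copy())


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_accession_meta(path: str | Path) -> AccessionMeta:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AccessionMeta(df[["accession", "subspecies", "status"]].copy())


def write_accession_meta(meta: AccessionMeta, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation


def _read_pathway_map(path: str | Path) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "pathway_id"], dtype=str
    )
    for gene_id, pathway_id in df.itertuples(index=False):
        mapping.setdefault(gene_id, set()).add(pathway_id)
    return mapping


def read_genes(
    path: str | Path, pathway_path: str | Path | None = None
) -> list[GeneModel]:
    """Read gene models from GFF3 or BED, optionally merging a two-column
    (gene id, pathway id) TSV.

    Genes named in the pathway TSV but absent from the annotation are
    skipped with a warning.  Output is sorted by (chrom, start).
    """
    path = Path(path)
    raw: list[tuple[str, str, int, int]] = []  # id, chrom, start, end (1-based)
    if path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", merge_strategy="create_unique"
        )
        for feat in db.features_of_type("gene"):
            gid = feat.attributes.get("ID", [feat.id])[0]
            raw.append((gid, feat.seqid, feat.start, feat.end))
    else:  # BED
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}: BED gene line needs a name: {line}")
                chrom, bed_start, bed_end, name = parts[:4]
                start, end = from_bed_interval(int(bed_start), int(bed_end))
                raw.append((name, chrom, start, end))

    pathway_map = _read_pathway_map(pathway_path) if pathway_path else {}
    known = {gid for gid, *_ in raw}
    for orphan in sorted(set(pathway_map) - known):
        logger.warning(
            "pathway map names gene %s absent from annotation; skipped", orphan
        )
    genes = [
        GeneModel(
            gene_id=gid,
            chrom=chrom,
            start=start,
            end=end,
            pathways=frozenset(pathway_map.get(gid, ())),
        )
        for gid, chrom, start, end in raw
    ]
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def write_qtl_bed(bins: Iterable, path: str | Path) -> None:
    """Write QTL bins as BED (0-based half-open).

    name = trait:population:environment, score = peak -log10(p) capped
    at 1000 per BED convention.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for b in bins:
            bed_start, bed_end = to_bed_interval(b.start, b.end)
            score = min(b.peak_neg_log10_p, 1000.0)
            name = f"{b.trait}:{b.population}:{b.environment}"
            fh.write(f"{b.chrom}\t{bed_start}\t{bed_end}\t{name}\t{score:g}\n")


def read_qtl_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED written by :func:`write_qtl_bed` back to 1-based spans."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, bed_start, bed_end, name, score = line.split("\t")
            start, end = from_bed_interval(int(bed_start), int(bed_end))
            trait, population, environment = name.split(":")
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "trait": trait,
                    "population": population,
                    "environment": environment,
                    "score": float(score),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "trait", "population", "environment", "score",
        ],
    )
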