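"""Synthetic inbred rice-panel generator.

Produces genotype/phenotype fixtures with the statistical structure the
downstream analyses assume: two diverged subpopulations (indica/japonica),
fully homozygous accessions, block-wise linkage disequilibrium, four
correlated traits (HD, GNP, PN, KGW) measured in two environments (SY, CS),
and planted causal architecture of three kinds — pleiotropic SNPs, linked
causal pairs closer than the QTL-binning gap, and gene pairs acting through
a genotype x genotype product term.

Genotypes come from a latent autocorrelated-ancestry model: each inbred
accession carries, per chromosome, a standard-normal latent process with
first-order autocorrelation exp(-gap / block_length_bp) between adjacent
SNPs, and its haplotype allele at a SNP is the indicator that the latent
value falls below the quantile of the SNP's subpopulation allele
frequency.  Marginal allele frequencies are therefore exact, r^2 between
nearby SNPs is high and decays monotonically toward zero over roughly the
block length, and chromosomes are independent.  Subpopulation divergence
follows the Balding-Nichols model on shared ancestral frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import (
    ENVIRONMENTS,
    TRAITS,
    AccessionMeta,
    GeneModel,
    GenotypeMatrix,
    PhenotypeTable,
    SNPRecord,
)

# Trait scale/location used to express phenotypes in field units
# (days, grains, panicles, grams).
TRAIT_MEAN = {"HD": 95.0, "GNP": 150.0, "PN": 10.0, "KGW": 25.0}
TRAIT_SD = {"HD": 12.0, "GNP": 35.0, "PN": 2.5, "KGW": 4.0}


@dataclass(frozen=True)
class PleiotropicSpec:
    """One SNP with additive effects on several traits.

    Effects are in units of the trait's baseline phenotypic SD per
    standardized dosage.  ``env_scale`` multiplies the effect per
    environment (0 switches the QTL off in that environment).
    """

    effects: Mapping[str, float]
    env_scale: Mapping[str, float] = field(
        default_factory=lambda: {"SY": 1.0, "CS": 1.0}
    )
    snp_index: int | None = None


@dataclass(frozen=True)
class LinkedPairSpec:
    """Two distinct causal SNPs < ``max_distance_bp`` apart, each affecting
    a different trait — the substrate for hitch-hiking via LD."""

    trait_a: str
    effect_a: float
    trait_b: str
    effect_b: float
    max_distance_bp: int = 60_000
    min_distance_bp: int = 5_000
    snp_indices: tuple[int, int] | None = None


@dataclass(frozen=True)
class InteractionSpec:
    """Two causal SNPs (notionally two genes in one pathway) whose
    standardized dosage product carries an effect on each listed trait.

    Each SNP also carries an additive ``main_effect`` on its own trait
    (first listed trait for the first SNP, last for the second), so the
    genes are discoverable by association — mirroring how candidate
    pathway genes are found through significant SNPs in the first place.
    """

    effects: Mapping[str, float]
    main_effect: float = 0.5
    snp_indices: tuple[int, int] | None = None


def _default_residual_correlation() -> np.ndarray:
    # order HD, GNP, PN, KGW; mild correlations mirroring the phenotypic
    # pattern (HD-GNP positive, GNP-PN negative)
    r = np.eye(4)
    idx = {t: i for i, t in enumerate(TRAITS)}
    pairs = {("HD", "GNP"): 0.30, ("GNP", "PN"): -0.30, ("PN", "KGW"): -0.10}
    for (a, b), v in pairs.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return r


@dataclass
class SimulationConfig:
    """Study conditions for one simulated panel.

    Defaults emulate a 266-accession panel (157 indica / 109 japonica)
    with rice-like block LD (~150 kb), moderate subpopulation divergence,
    and a causal architecture containing all three pleiotropy mechanisms.
    """

    n_indica: int = 157
    n_japonica: int = 109
    n_snps: int = 20_000
    n_chromosomes: int = 4
    snp_spacing_bp: int = 1_000
    block_length_bp: int = 150_000
    within_block_recomb: float = 0.0  # extra per-adjacent-SNP decorrelation
    divergence: float = 0.20  # Balding-Nichols F
    landrace_fraction: float = 151 / 265  # 151 landraces / 114 improved

    pleiotropic: Sequence[PleiotropicSpec] = field(
        default_factory=lambda: (
            PleiotropicSpec({"HD": 0.6, "GNP": 0.6}),
            PleiotropicSpec({"GNP": 0.5, "PN": -0.5}),
        )
    )
    linked_pairs: Sequence[LinkedPairSpec] = field(
        default_factory=lambda: (
            LinkedPairSpec("HD", 0.5, "GNP", 0.5),
            LinkedPairSpec("PN", 0.5, "KGW", -0.5),
        )
    )
    interactions: Sequence[InteractionSpec] = field(
        default_factory=lambda: (InteractionSpec({"GNP": 0.5, "PN": -0.5}),)
    )
    n_background_qtl: int = 3  # extra single-trait QTLs per trait
    background_effect: float = 0.4
    background_env_specific: bool = True  # alternate SY-/CS-only effects

    heritability: Mapping[str, float] = field(
        default_factory=lambda: {"HD": 0.5, "GNP": 0.4, "PN": 0.35, "KGW": 0.45}
    )
    residual_correlation: np.ndarray = field(
        default_factory=_default_residual_correlation
    )
    env_shift: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "HD": {"SY": 0.0, "CS": 15.0},
            "GNP": {"SY": 0.0, "CS": 10.0},
            "PN": {"SY": 0.0, "CS": 1.0},
            "KGW": {"SY": 0.0, "CS": -1.5},
        }
    )
    min_causal_maf: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for t, h2 in self.heritability.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"heritability[{t}]={h2} outside [0, 1]")
        r = np.asarray(self.residual_correlation, dtype=float)
        if r.shape != (4, 4) or not np.allclose(r, r.T):
            raise ValueError("residual correlation must be symmetric 4x4")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ValueError("residual correlation must be positive semi-definite")
        self.residual_correlation = r
        n_causal = (
            len(self.pleiotropic)
            + 2 * len(self.linked_pairs)
            + 2 * len(self.interactions)
            + self.n_background_qtl * len(TRAITS)
        )
        if self.n_snps < n_causal:
            raise ValueError(
                f"n_snps={self.n_snps} smaller than {n_causal} causal SNPs"
            )

    @property
    def n_accessions(self) -> int:
        return self.n_indica + self.n_japonica


# ---------------------------------------------------------------------------
# population


def _latent_haplotypes(
    rng: np.random.Generator,
    freqs: np.ndarray,
    positions: np.ndarray,
    n_acc: int,
    block_length_bp: float,
    within_block_recomb: float,
) -> np.ndarray:
    """Inbred haplotype alleles (0/1) from the latent AR(1) ancestry model.

    Each accession's latent path has correlation
    ``exp(-gap/block_length) * (1 - within_block_recomb)`` between
    adjacent SNPs; the allele is 1 where the latent value is below the
    normal quantile of the SNP's allele frequency, so marginal
    frequencies equal ``freqs`` exactly.
    """
    from scipy.stats import norm

    n_snps = freqs.shape[0]
    gaps = np.diff(positions).astype(float)
    rho = np.exp(-gaps / block_length_bp) * (1.0 - within_block_recomb)
    z = np.empty((n_acc, n_snps))
    z[:, 0] = rng.standard_normal(n_acc)
    noise = rng.standard_normal((n_acc, n_snps - 1))
    scale = np.sqrt(1.0 - rho**2)
    for s in range(1, n_snps):
        z[:, s] = rho[s - 1] * z[:, s - 1] + scale[s - 1] * noise[:, s - 1]
    thresholds = norm.ppf(np.clip(freqs, 1e-9, 1 - 1e-9))
    return (z < thresholds[None, :]).astype(np.int8)


def simulate_population(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, AccessionMeta]:
    """Simulate the inbred two-subpopulation panel.

    Returns a fully homozygous dosage matrix (values 0/2) and accession
    metadata with subspecies and landrace/improved status.  Deterministic
    under ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1

    acc_ids = [f"IND{i + 1:04d}" for i in range(config.n_indica)] + [
        f"JAP{i + 1:04d}" for i in range(config.n_japonica)
    ]
    subs = ["indica"] * config.n_indica + ["japonica"] * config.n_japonica
    status = np.where(
        rng.random(config.n_accessions) < config.landrace_fraction,
        "landrace",
        "improved",
    )
    meta = AccessionMeta(
        pd.DataFrame(
            {"accession": acc_ids, "subspecies": subs, "status": status}
        )
    )

    snps: list[SNPRecord] = []
    blocks: list[np.ndarray] = []
    bases = np.array(list("ACGT"))
    for c, m in enumerate(per_chrom, start=1):
        chrom = f"chr{c}"
        gaps = rng.uniform(0.5, 1.5, size=m) * config.snp_spacing_bp
        positions = np.cumsum(gaps).astype(np.int64) + 1
        positions = np.maximum.accumulate(positions + np.arange(m))  # strictly increasing
        # ancestral frequencies: probit transform of an AR(1) walk, so the
        # marginal spectrum is uniform on (0.05, 0.95) while nearby SNPs
        # share similar frequencies (frequency coherence within LD blocks)
        w = np.empty(m)
        w[0] = rng.standard_normal()
        rho_f = np.exp(-np.diff(positions) / float(config.block_length_bp))
        eps = rng.standard_normal(m - 1)
        for s in range(1, m):
            w[s] = rho_f[s - 1] * w[s - 1] + math.sqrt(1 - rho_f[s - 1] ** 2) * eps[s - 1]
        anc = 0.05 + 0.90 * stats.norm.cdf(w)
        if config.divergence > 0:
            # Balding-Nichols marginals, but drawn through an AR(1)-correlated
            # probit so divergence is coherent within haplotype blocks rather
            # than independent per SNP
            f = config.divergence
            a = anc * (1 - f) / f
            b = (1 - anc) * (1 - f) / f

            def _coherent_beta() -> np.ndarray:
                v = np.empty(m)
                v[0] = rng.standard_normal()
                e = rng.standard_normal(m - 1)
                for s in range(1, m):
                    v[s] = rho_f[s - 1] * v[s - 1] + math.sqrt(
                        1 - rho_f[s - 1] ** 2
                    ) * e[s - 1]
                return stats.beta.ppf(stats.norm.cdf(v), a, b)

            freq_ind = np.clip(_coherent_beta(), 1e-4, 1 - 1e-4)
            freq_jap = np.clip(_coherent_beta(), 1e-4, 1 - 1e-4)
        else:
            freq_ind = anc.copy()
            freq_jap = anc.copy()

        hap_parts = []
        for freqs, n_acc in (
            (freq_ind, config.n_indica),
            (freq_jap, config.n_japonica),
        ):
            hap_parts.append(
                _latent_haplotypes(
                    rng, freqs, positions, n_acc,
                    config.block_length_bp, config.within_block_recomb,
                )
            )
        blocks.append(np.vstack(hap_parts) * 2.0)  # inbred: dosage 0/2

        ref_idx = rng.integers(4, size=m)
        alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
        for pos, r, a2 in zip(positions, bases[ref_idx], bases[alt_idx]):
            snps.append(
                SNPRecord(
                    chrom=chrom,
                    pos=int(pos),
                    ref_allele=str(r),
                    alt_allele=str(a2),
                    id=f"{chrom}:{pos}",
                )
            )

    dosage = np.hstack(blocks).astype(float)
    return GenotypeMatrix(snps, acc_ids, dosage), meta


# ---------------------------------------------------------------------------
# phenotypes


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant dosage column")
    return (x - x.mean()) / sd


def _pick_causal_indices(
    geno: GenotypeMatrix, config: SimulationConfig, rng: np.random.Generator
) -> dict:
    """Assign SNP indices to every causal element that did not fix them.

    Candidates need MAF >= ``min_causal_maf``; distinct elements are kept
    >= 1 Mb apart so planted QTLs do not collide, and linked pairs are
    chosen at the requested physical distance.
    """
    maf = geno.maf()
    pos = np.array([s.pos for s in geno.snps])
    chrom = np.array([s.chrom for s in geno.snps])
    eligible = np.flatnonzero(maf >= config.min_causal_maf)
    if eligible.size == 0:
        raise ValueError("no SNPs pass min_causal_maf; lower the threshold")
    taken: list[int] = []

    # separations tried in order: keep planted loci as far apart as the
    # genome allows (>= 150 kb keeps distinct causal elements from fusing
    # into one bin); tiny fixture genomes fall back to closer placements
    _SEPARATIONS = (1_000_000, 500_000, 250_000, 150_000, 75_000, 30_000, 10_000, 1)

    def far_enough(j: int, min_bp: int) -> bool:
        return all(
            chrom[j] != chrom[t] or abs(int(pos[j]) - int(pos[t])) >= min_bp
            for t in taken
        )

    def pick_one() -> int:
        for sep in _SEPARATIONS:
            for j in rng.permutation(eligible):
                if far_enough(int(j), sep):
                    taken.append(int(j))
                    return int(j)
        raise ValueError("could not place causal SNPs 150 kb apart; too few SNPs")

    def pick_pair(min_bp: int, max_bp: int) -> tuple[int, int]:
        for sep in _SEPARATIONS:
            for j in rng.permutation(eligible):
                j = int(j)
                if not far_enough(j, sep):
                    continue
                same = np.flatnonzero(
                    (chrom == chrom[j])
                    & (np.abs(pos - pos[j]) >= min_bp)
                    & (np.abs(pos - pos[j]) <= max_bp)
                    & (maf >= config.min_causal_maf)
                )
                if same.size:
                    k = int(rng.choice(same))
                    taken.extend([j, k])
                    return j, k
        raise ValueError("could not place a linked causal pair; too few SNPs")

    assignment = {"pleiotropic": [], "linked": [], "interaction": [], "background": []}
    for spec in config.pleiotropic:
        j = spec.snp_index if spec.snp_index is not None else pick_one()
        assignment["pleiotropic"].append(j)
    for spec in config.linked_pairs:
        if spec.snp_indices is not None:
            assignment["linked"].append(tuple(spec.snp_indices))
        else:
            assignment["linked"].append(
                pick_pair(spec.min_distance_bp, spec.max_distance_bp)
            )
    for spec in config.interactions:
        if spec.snp_indices is not None:
            assignment["interaction"].append(tuple(spec.snp_indices))
        else:
            assignment["interaction"].append((pick_one(), pick_one()))
    for _t in TRAITS:
        assignment["background"].append(
            [pick_one() for _ in range(config.n_background_qtl)]
        )
    return assignment


def simulate_phenotypes(
    geno: GenotypeMatrix,
    meta: AccessionMeta,
    config: SimulationConfig,
    kinship: np.ndarray | None = None,
    polygenic_h2: float | None = None,
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Simulate the four traits in both environments on ``geno``.

    Per environment each trait is built on a unit-variance baseline
    (polygenic background with covariance proportional to kinship plus
    residual noise correlated across traits per the config), and causal
    effects are added on top in baseline-SD units.  ``heritability[t]``
    is the polygenic share of the baseline.  Trait values are then placed
    on field scales (days/grains/panicles/grams) with per-environment
    mean shifts.

    Returns the phenotype table and a truth table with one row per
    planted causal element.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = geno.n_accessions
    dosage = geno.dosage
    if np.isnan(dosage).any():
        dosage = np.where(np.isnan(dosage), np.nanmean(dosage, axis=0), dosage)

    assignment = _pick_causal_indices(geno, config, rng)

    h2 = {t: float(config.heritability.get(t, 0.0)) for t in TRAITS}
    if polygenic_h2 is not None:
        h2 = {t: float(polygenic_h2) for t in TRAITS}
    resid_var = {t: 1.0 - h2[t] for t in TRAITS}
    if any(v < -1e-12 for v in resid_var.values()):
        raise ValueError("negative residual variance; lower heritability")

    # polygenic background, shared across environments
    poly = {t: np.zeros(n) for t in TRAITS}
    if any(h2[t] > 0 for t in TRAITS):
        if kinship is None:
            from .association import compute_kinship

            kinship = compute_kinship(geno).values
        w, u = np.linalg.eigh(kinship + 1e-6 * np.eye(n))
        root = u @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        for t in TRAITS:
            g = root @ rng.standard_normal(n)
            sd = g.std()
            poly[t] = np.sqrt(h2[t]) * (g / sd if sd > 0 else g)

    # residual noise, correlated across traits, independent across envs
    chol = np.linalg.cholesky(
        np.asarray(config.residual_correlation) + 1e-10 * np.eye(4)
    )
    truth_rows: list[dict] = []
    records: list[dict] = []

    def describe(j: int) -> tuple[str, int, str]:
        s = geno.snps[j]
        return s.chrom, s.pos, s.id

    for env in ENVIRONMENTS:
        genetic = {t: np.zeros(n) for t in TRAITS}

        for spec, j in zip(config.pleiotropic, assignment["pleiotropic"]):
            x = _standardize(dosage[:, j])
            scale = float(spec.env_scale.get(env, 1.0))
            for t, beta in spec.effects.items():
                genetic[t] += beta * scale * x
        for spec, (j, k) in zip(config.linked_pairs, assignment["linked"]):
            genetic[spec.trait_a] += spec.effect_a * _standardize(dosage[:, j])
            genetic[spec.trait_b] += spec.effect_b * _standardize(dosage[:, k])
        for spec, (j, k) in zip(config.interactions, assignment["interaction"]):
            xa = dosage[:, j] - dosage[:, j].mean()
            xb = dosage[:, k] - dosage[:, k].mean()
            prod = _standardize(xa * xb)
            for t, gamma in spec.effects.items():
                genetic[t] += gamma * prod
            ts = list(spec.effects)
            if spec.main_effect and ts:
                genetic[ts[0]] += spec.main_effect * _standardize(dosage[:, j])
                genetic[ts[-1]] += spec.main_effect * _standardize(dosage[:, k])
        for t, idx_list in zip(TRAITS, assignment["background"]):
            for q, j in enumerate(idx_list):
                scale = 1.0
                if config.background_env_specific:
                    # alternate QTLs active in only one environment
                    only = ENVIRONMENTS[q % 2]
                    scale = 1.0 if env == only else 0.25
                genetic[t] += config.background_effect * scale * _standardize(
                    dosage[:, j]
                )

        noise = chol @ rng.standard_normal((4, n))
        for i, t in enumerate(TRAITS):
            baseline = poly[t] + np.sqrt(resid_var[t]) * noise[i]
            y = genetic[t] + baseline
            value = (
                TRAIT_MEAN[t]
                + float(config.env_shift.get(t, {}).get(env, 0.0))
                + TRAIT_SD[t] * y
            )
            for acc, v in zip(geno.accessions, value):
                records.append(
                    {"accession": acc, "trait": t, "environment": env, "value": v}
                )

    for spec, j in zip(config.pleiotropic, assignment["pleiotropic"]):
        chrom, pos, sid = describe(j)
        for t, beta in spec.effects.items():
            truth_rows.append(
                {
                    "class": "pleiotropic",
                    "snp_index": j,
                    "snp_id": sid,
                    "chrom": chrom,
                    "pos": pos,
                    "trait": t,
                    "effect": beta,
                    "env_scale_SY": float(spec.env_scale.get("SY", 1.0)),
                    "env_scale_CS": float(spec.env_scale.get("CS", 1.0)),
                    "partner_snp_id": "",
                }
            )
    for spec, (j, k) in zip(config.linked_pairs, assignment["linked"]):
        for (jj, t, beta), partner in (
            ((j, spec.trait_a, spec.effect_a), k),
            ((k, spec.trait_b, spec.effect_b), j),
        ):
            chrom, pos, sid = describe(jj)
            truth_rows.append(
                {
                    "class": "linked",
                    "snp_index": jj,
                    "snp_id": sid,
                    "chrom": chrom,
                    "pos": pos,
                    "trait": t,
                    "effect": beta,
                    "env_scale_SY": 1.0,
                    "env_scale_CS": 1.0,
                    "partner_snp_id": geno.snps[partner].id,
                }
            )
    for spec, (j, k) in zip(config.interactions, assignment["interaction"]):
        for t, gamma in spec.effects.items():
            chrom, pos, sid = describe(j)
            truth_rows.append(
                {
                    "class": "interactive",
                    "snp_index": j,
                    "snp_id": sid,
                    "chrom": chrom,
                    "pos": pos,
                    "trait": t,
                    "effect": gamma,
                    "env_scale_SY": 1.0,
                    "env_scale_CS": 1.0,
                    "partner_snp_id": geno.snps[k].id,
                }
            )
    for t, idx_list in zip(TRAITS, assignment["background"]):
        for q, j in enumerate(idx_list):
            chrom, pos, sid = describe(j)
            only = ENVIRONMENTS[q % 2] if config.background_env_specific else None
            truth_rows.append(
                {
                    "class": "background",
                    "snp_index": j,
                    "snp_id": sid,
                    "chrom": chrom,
                    "pos": pos,
                    "trait": t,
                    "effect": config.background_effect,
                    "env_scale_SY": 1.0 if only in (None, "SY") else 0.25,
                    "env_scale_CS": 1.0 if only in (None, "CS") else 0.25,
                    "partner_snp_id": "",
                }
            )

    pheno = PhenotypeTable(pd.DataFrame.from_records(records))
    truth = pd.DataFrame.from_records(truth_rows)
    return pheno, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, AccessionMeta, PhenotypeTable, pd.DataFrame]:
    """Convenience wrapper: population + phenotypes in one call."""
    geno, meta = simulate_population(config)
    pheno, truth = simulate_phenotypes(geno, meta, config)
    return geno, meta, pheno, truth


def causal_gene_models(
    geno: GenotypeMatrix,
    truth: pd.DataFrame,
    span_bp: int = 10_000,
    pathway_for_interactions: str = "pw_carotenoid",
) -> list[GeneModel]:
    """Gene models wrapping each causal SNP, for annotation-level tests.

    Interactive partners share one pathway so the pathway scan has a true
    positive to find; other causal genes get singleton pathways.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    id_to_index = {s.id: j for j, s in enumerate(geno.snps)}

    def add(sid: str, j: int, interactive: bool) -> None:
        if sid in seen:
            return
        seen.add(sid)
        snp = geno.snps[j]
        pathways = (
            frozenset({pathway_for_interactions})
            if interactive
            else frozenset({f"pw_{sid}"})
        )
        genes.append(
            GeneModel(
                gene_id=f"gene_{sid}",
                chrom=snp.chrom,
                start=max(1, snp.pos - span_bp // 2),
                end=snp.pos + span_bp // 2,
                pathways=pathways,
            )
        )

    for _, row in truth.iterrows():
        interactive = row["class"] == "interactive"
        add(row["snp_id"], int(row["snp_index"]), interactive)
        if interactive and row["partner_snp_id"]:
            pid = row["partner_snp_id"]
            add(pid, id_to_index[pid], True)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes
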