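"""End-to-end orchestration: simulate or load data, scan, threshold, call
bins, intersect pleiotropy, LD/hitch-hiking, effect classes, pathway scan,
and write all stage reports plus a machine-readable run manifest.

Every stochastic stage takes its seed from the config, so rerunning with
the same config reproduces identical outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import (
    association,
    effect_classes,
    genotype_io,
    ld_analysis,
    pathway_igenes,
    perm_threshold,
    qtl_calling,
    synth_data,
    trait_correlation,
)
from .genotype_io import ENVIRONMENTS, TRAITS

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "correlation",
    "scan",
    "threshold",
    "callqtl",
    "pleiotropy",
    "ld",
    "effects",
    "pathways",
)

_DEFAULTS: dict[str, Any] = {
    "populations": ["full", "indica", "japonica"],
    "environments": list(ENVIRONMENTS),
    "traits": list(TRAITS),
    "association": {"n_pcs_full": 3, "n_pcs_subspecies": 2, "mode": "p3d"},
    "permutation": {
        "n_perm": 1000,
        "seed": 0,
        "candidate_neg_log10_p": 2.0,
        "threshold_rule": "min",
        "quantile": 0.05,
    },
    "binning": {"max_gap": 70000, "min_snps": 3},
    "ld": {"tiers": [0.2, 0.4, 0.6, 0.8], "pvc_aggregate": "mean"},
    "effects": {"alpha": 0.05, "min_group_size": 2, "haplotype_min_freq": 0.05},
    "pathways": {"alpha": 0.05, "collinearity_r2": 0.95},
    "io": {"min_maf": 0.05, "max_missing": 0.5},
}


class ConfigError(ValueError):
    """Raised for malformed pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated, normalized pipeline configuration."""

    raw: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    def get(self, *keys: str) -> Any:
        node: Any = self.raw
        for k in keys:
            node = node[k]
        return node


def _merge_defaults(user: dict, defaults: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{where} must be a mapping")
            out[key] = _merge_defaults(value, defaults[key], where)
        else:
            out[key] = value
    return out


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load, default-fill and sanity-check a pipeline config.

    ``source`` is a YAML path or an already-parsed mapping.  Exactly one
    of ``simulate`` (a simulation block with an explicit seed) or
    ``inputs`` (paths to VCF/TSVs) must be present.  Unknown keys are
    rejected with the offending key named.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")

    sim_block = user.pop("simulate", None)
    inputs = user.pop("inputs", None)
    if (sim_block is None) == (inputs is None):
        raise ConfigError(
            "config needs exactly one of 'simulate' or 'inputs'"
        )
    merged = _merge_defaults(user, _DEFAULTS)

    if sim_block is not None:
        if not isinstance(sim_block, dict):
            raise ConfigError("simulate must be a mapping")
        if "seed" not in sim_block:
            raise ConfigError("simulate.seed must be explicit")
        valid = set(synth_data.SimulationConfig.__dataclass_fields__)
        unknown = set(sim_block) - valid
        if unknown:
            raise ConfigError(
                f"unknown simulate key {sorted(unknown)[0]!r}"
            )
        merged["simulate"] = dict(sim_block)
    else:
        if not isinstance(inputs, dict):
            raise ConfigError("inputs must be a mapping")
        required = {"vcf", "phenotypes", "metadata"}
        missing = required - set(inputs)
        if missing:
            raise ConfigError(f"inputs missing {sorted(missing)}")
        unknown = set(inputs) - (required | {"genes", "pathway_map", "cloned_genes"})
        if unknown:
            raise ConfigError(f"unknown inputs key {sorted(unknown)[0]!r}")
        for key, p in inputs.items():
            if not Path(p).exists():
                raise ConfigError(f"inputs.{key} path does not exist: {p}")
        merged["inputs"] = dict(inputs)

    for pop in merged["populations"]:
        if pop not in trait_correlation.POPULATIONS:
            raise ConfigError(f"unknown population {pop!r}")
    if merged["permutation"]["n_perm"] < 1:
        raise ConfigError("permutation.n_perm must be >= 1")
    return PipelineConfig(merged)


def _build_sim_config(block: dict) -> synth_data.SimulationConfig:
    kwargs = dict(block)
    for key in ("pleiotropic", "linked_pairs", "interactions"):
        if key in kwargs:
            cls = {
                "pleiotropic": synth_data.PleiotropicSpec,
                "linked_pairs": synth_data.LinkedPairSpec,
                "interactions": synth_data.InteractionSpec,
            }[key]
            kwargs[key] = tuple(
                item if isinstance(item, cls) else cls(**item)
                for item in kwargs[key]
            )
    if "residual_correlation" in kwargs:
        kwargs["residual_correlation"] = np.asarray(
            kwargs["residual_correlation"], dtype=float
        )
    return synth_data.SimulationConfig(**kwargs)


@dataclass
class PipelineResult:
    """In-memory handle on everything a run produced."""

    config: PipelineConfig
    geno: genotype_io.GenotypeMatrix
    meta: genotype_io.AccessionMeta
    pheno: genotype_io.PhenotypeTable
    truth: pd.DataFrame | None
    genes: list
    correlation: trait_correlation.CorrelationReport | None = None
    assoc: dict = field(default_factory=dict)  # (pop, env, trait) -> DataFrame
    thresholds: dict = field(default_factory=dict)
    sig_masks: dict = field(default_factory=dict)
    bins: dict = field(default_factory=dict)  # (pop, env, trait) -> [QTLBin]
    pqtls: list = field(default_factory=list)
    hitchhiking: list = field(default_factory=list)
    sdod: list = field(default_factory=list)  # (SDODClass, carriers)
    shared_pathways: list = field(default_factory=list)
    igene_pairs: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def qtl_totals(self) -> dict[str, int]:
        """Total QTL bins per trait pooled over populations/environments."""
        totals: dict[str, int] = {t: 0 for t in TRAITS}
        for (pop, env, trait), bins in self.bins.items():
            totals[trait] += len(bins)
        return totals


def run_pipeline(
    config: PipelineConfig | dict | str | Path,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> PipelineResult:
    """Execute the pipeline through ``stages`` (a prefix of STAGES) and
    write stage TSVs plus ``manifest.json`` under ``outdir``."""
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.normalized.yaml", "w") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=True)

    manifest: dict[str, Any] = {"stages": {}, "parameters": config.raw}
    t_all = time.time()

    def stage_done(name: str, **info: Any) -> None:
        manifest["stages"][name] = {
            "wall_time_s": round(time.time() - t_stage, 3),
            **info,
        }
        logger.info("stage %s done (%.2fs)", name, time.time() - t_stage)

    # ---- simulate / load -------------------------------------------------
    t_stage = time.time()
    truth = None
    genes: list = []
    if "simulate" in config.raw:
        sim_cfg = _build_sim_config(config.raw["simulate"])
        geno, meta = synth_data.simulate_population(sim_cfg)
        pheno, truth = synth_data.simulate_phenotypes(geno, meta, sim_cfg)
        genes = synth_data.causal_gene_models(geno, truth)
        genotype_io.write_vcf(geno, outdir / "genotypes.vcf")
        genotype_io.write_phenotypes(pheno, outdir / "phenotypes.tsv")
        genotype_io.write_accession_meta(meta, outdir / "accessions.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    else:
        inputs = config.raw["inputs"]
        geno = genotype_io.read_vcf(
            inputs["vcf"],
            min_maf=config.get("io", "min_maf"),
            max_missing=config.get("io", "max_missing"),
        )
        pheno = genotype_io.read_phenotypes(inputs["phenotypes"])
        meta = genotype_io.read_accession_meta(inputs["metadata"])
        if "genes" in inputs:
            genes = genotype_io.read_genes(
                inputs["genes"], inputs.get("pathway_map")
            )
    result = PipelineResult(
        config=config, geno=geno, meta=meta, pheno=pheno, truth=truth, genes=genes
    )
    stage_done(
        "simulate", n_accessions=geno.n_accessions, n_snps=geno.n_snps,
        n_genes=len(genes),
    )
    if "correlation" not in stages:
        _finish(result, manifest, outdir, t_all)
        return result

    # ---- trait correlations ---------------------------------------------
    t_stage = time.time()
    result.correlation = trait_correlation.correlate_traits(pheno, meta)
    result.correlation.correlations.to_csv(
        outdir / "trait_correlations.tsv", sep="\t", index=False
    )
    result.correlation.descriptives.to_csv(
        outdir / "trait_descriptives.tsv", sep="\t", index=False
    )
    stage_done("correlation", n_cells=len(result.correlation.correlations))
    if "scan" not in stages:
        _finish(result, manifest, outdir, t_all)
        return result

    # ---- association scans ----------------------------------------------
    t_stage = time.time()
    populations = config["populations"]
    environments = config["environments"]
    traits = config["traits"]
    mode = config.get("association", "mode")
    pop_data: dict[str, dict[str, Any]] = {}
    for pop in populations:
        accs = meta.accessions_in(pop)
        sub = geno.subset_accessions(accs)
        sub = genotype_io.filter_genotypes(
            sub, min_maf=config.get("io", "min_maf"),
            max_missing=config.get("io", "max_missing"),
        )
        K = association.compute_kinship(sub)
        n_pcs = (
            config.get("association", "n_pcs_full")
            if pop == "full"
            else config.get("association", "n_pcs_subspecies")
        )
        pcs = association.compute_pcs(sub, n_pcs)
        spectral = association.SpectralK.from_kinship(K)
        pop_data[pop] = {
            "geno": sub, "K": K, "pcs": pcs, "spectral": spectral, "accs": accs,
        }
    scan_rows = 0
    for pop, env, trait in itertools.product(populations, environments, traits):
        data = pop_data[pop]
        y = pheno.vector(trait, env, data["accs"]).to_numpy()
        assoc = association.mlm_scan(
            data["geno"], y, data["K"], data["pcs"], mode=mode,
            trait=trait, population=pop, environment=env,
        )
        result.assoc[(pop, env, trait)] = assoc
        scan_rows += len(assoc)
    pd.concat(result.assoc.values(), ignore_index=True).to_csv(
        outdir / "association.tsv", sep="\t", index=False
    )
    stage_done("scan", n_rows=scan_rows)
    if "threshold" not in stages:
        _finish(result, manifest, outdir, t_all)
        return result

    # ---- permutation thresholds ------------------------------------------
    t_stage = time.time()
    perm = config.raw["permutation"]
    thr_rows = []
    for key, assoc in result.assoc.items():
        pop, env, trait = key
        data = pop_data[pop]
        y = pheno.vector(trait, env, data["accs"]).to_numpy()
        ok = ~np.isnan(y)
        if not ok.all():
            # decompose/permutate over phenotyped accessions only
            sub_geno = genotype_io.GenotypeMatrix(
                list(data["geno"].snps),
                [a for a, m in zip(data["geno"].accessions, ok) if m],
                data["geno"].dosage[ok],
            )
            K = association.KinshipMatrix(
                sub_geno.accessions, data["K"].values[np.ix_(ok, ok)]
            )
            pcs = association.PCScores(
                sub_geno.accessions,
                data["pcs"].scores[ok],
                data["pcs"].explained_variance_ratio,
            )
            spectral = association.SpectralK.from_kinship(K)
            yv = y[ok]
        else:
            sub_geno, K, pcs, spectral = (
                data["geno"], data["K"], data["pcs"], data["spectral"],
            )
            yv = y
        decomp = perm_threshold.decompose_phenotype(yv, pcs)
        mask = perm_threshold.candidate_mask_from_scan(
            assoc, perm["candidate_neg_log10_p"]
        )
        thr = perm_threshold.permutation_scan(
            sub_geno, decomp, K, pcs,
            n_perm=perm["n_perm"],
            seed=int(perm["seed"]) + zlib.crc32("/".join(key).encode()) % 100_000,
            candidate_mask=mask,
            threshold_rule=perm["threshold_rule"],
            quantile=perm["quantile"],
            mode=mode,
            spectral=spectral,
        )
        result.thresholds[key] = thr
        result.sig_masks[key] = thr.significant_mask(assoc)
        thr_rows.append(
            {
                "population": pop, "environment": env, "trait": trait,
                "n_perm": thr.n_perm, "seed": thr.seed,
                "p_perm": thr.p_perm,
                "threshold_neg_log10": thr.threshold_neg_log10,
                "n_candidates": thr.n_candidates,
                "n_significant": int(result.sig_masks[key].sum()),
            }
        )
    pd.DataFrame(thr_rows).to_csv(
        outdir / "thresholds.tsv", sep="\t", index=False
    )
    stage_done("threshold", n_scans=len(thr_rows))
    if "callqtl" not in stages:
        _finish(result, manifest, outdir, t_all)
        return result

    # ---- QTL bins ---------------------------------------------------------
    t_stage = time.time()
    binning = config.raw["binning"]
    all_bins = []
    for key, assoc in result.assoc.items():
        bins = qtl_calling.call_qtls(
            assoc, result.sig_masks[key],
            max_gap=binning["max_gap"], min_snps=binning["min_snps"],
        )
        result.bins[key] = bins
        all_bins.extend(bins)
    qtl_calling.bins_to_frame(all_bins).to_csv(
        outdir / "qtl_bins.tsv", sep="\t", index=False
    )
    genotype_io.write_qtl_bed(all_bins, outdir / "qtl_bins.bed")
    stage_done("callqtl", n_bins=len(all_bins))
    if "pleiotropy" not in stages:
        _finish(result, manifest, outdir, t_all)
        return result

    # ---- pleiotropic QTLs --------------------------------------------------
    t_stage = time.time()
    for pop, env in itertools.product(populations, environments):
        for ta, tb in itertools.combinations(sorted(traits), 2):
            bins_a = result.bins.get((pop, env, ta), [])
            bins_b = result.bins.get((pop, env, tb), [])
            if bins_a and bins_b:
                result.pqtls.extend(
                    qtl_calling.intersect_qtls(bins_a, bins_b, genes or None)
                )
    stage_done("pleiotropy", n_pqtls=len(result.pqtls))
    if "ld" not in stages:
        _write_pleiotropy(result, outdir)
        _finish(result, manifest, outdir, t_all)
        return result

    # ---- LD / hitch-hiking ---------------------------------------------------
    t_stage = time.time()
    ld_frames = []
    for pop in populations:
        sub = pop_data[pop]["geno"]
        mine = [q for q in result.pqtls if q.population == pop]
        if mine:
            ld_frames.append(ld_analysis.ld_report(mine, sub))
    if ld_frames:
        pd.concat(ld_frames, ignore_index=True).to_csv(
            outdir / "pqtl_ld.tsv", sep="\t", index=False
        )
    ld_analysis.ld_tiers(result.pqtls).to_csv(
        outdir / "ld_tiers.tsv", sep="\t", index=False
    )
    # hitch-hiking: pool (LD, dPVC) points across populations/environments
    aggregate = config.get("ld", "pvc_aggregate")
    hh_rows = []
    for ta, tb in itertools.permutations(sorted(traits), 2):
        lds: list[float] = []
        dpvcs: list[float] = []
        for pop, env in itertools.product(populations, environments):
            sub_pqtls = [
                q
                for q in result.pqtls
                if q.population == pop and q.environment == env
            ]
            if not sub_pqtls:
                continue
            assoc_by_trait = {
                t: result.assoc[(pop, env, t)] for t in traits
            }
            pl, pd_ = ld_analysis.hitchhiking_points(
                sub_pqtls, assoc_by_trait, ta, tb, aggregate
            )
            lds.extend(pl)
            dpvcs.extend(pd_)
        hh = ld_analysis.hitchhiking_from_points(lds, dpvcs, ta, tb)
        result.hitchhiking.append(hh)
        hh_rows.append(
            {"direction": hh.label, "trait_x": ta, "trait_y": tb,
             "r": hh.r, "n_pqtls": hh.n}
        )
    pd.DataFrame(hh_rows).to_csv(
        outdir / "hitchhiking.tsv", sep="\t", index=False
    )
    _write_pleiotropy(result, outdir)
    stage_done("ld", n_directions=len(hh_rows))
    if "effects" not in stages:
        _finish(result, manifest, outdir, t_all)
        return result

    # ---- effect classes -----------------------------------------------------
    t_stage = time.time()
    eff = config.raw["effects"]
    call_rows = []
    for q in result.pqtls:
        sub = pop_data[q.population]["geno"]
        accs = pop_data[q.population]["accs"]
        for sid in q.psnp_ids:
            partition = effect_classes.snp_allele_partition(sub, sid)
            calls = {}
            for trait in (q.trait_a, q.trait_b):
                y = result.pheno.vector(trait, q.environment, accs)
                per_group = effect_classes.call_effect(
                    partition, y, unit_id=sid, trait=trait,
                    alpha=eff["alpha"], min_group_size=eff["min_group_size"],
                )
                calls[trait] = per_group
            by_group_a = {c.group: c for c in calls[q.trait_a]}
            by_group_b = {c.group: c for c in calls[q.trait_b]}
            for group in by_group_a:
                cls = effect_classes.classify_sd_od(
                    by_group_a[group], by_group_b[group]
                )
                carriers = partition[group]
                result.sdod.append((cls, carriers))
                call_rows.append(
                    {
                        "unit_id": sid, "group": group,
                        "population": q.population, "environment": q.environment,
                        "trait_a": q.trait_a, "trait_b": q.trait_b,
                        "direction_a": cls.direction_a,
                        "direction_b": cls.direction_b,
                        "sd_od": cls.sd_od, "n_carriers": len(carriers),
                    }
                )
    pd.DataFrame(
        call_rows,
        columns=[
            "unit_id", "group", "population", "environment", "trait_a",
            "trait_b", "direction_a", "direction_b", "sd_od", "n_carriers",
        ],
    ).to_csv(outdir / "effect_classes.tsv", sep="\t", index=False)
    if result.sdod:
        effect_classes.distribution_by_variety(result.sdod, meta).to_csv(
            outdir / "variety_distribution.tsv", sep="\t", index=False
        )
    stage_done("effects", n_units=len(call_rows))
    if "pathways" not in stages:
        _finish(result, manifest, outdir, t_all)
        return result

    # ---- shared pathways / iGenes -------------------------------------------
    t_stage = time.time()
    pw = config.raw["pathways"]
    if genes:
        for pop, env in itertools.product(populations, environments):
            assoc_genes: dict[str, set[str]] = {}
            rep_snp: dict[str, str] = {}
            for trait in traits:
                key = (pop, env, trait)
                assoc = result.assoc[key]
                mask = result.sig_masks[key]
                reps = pathway_igenes.peak_snp_per_gene(assoc, genes, mask)
                for gid, sid in reps.items():
                    assoc_genes.setdefault(trait, set()).add(gid)
                    rep_snp.setdefault(gid, sid)
            shared = pathway_igenes.find_shared_pathways(assoc_genes, genes)
            if not shared:
                continue
            result.shared_pathways.extend(shared)
            pheno_by_trait = {
                t: result.pheno.vector(t, env, pop_data[pop]["accs"]).to_numpy()
                for t in traits
            }
            result.igene_pairs.extend(
                pathway_igenes.igene_scan(
                    shared, pop_data[pop]["geno"], pheno_by_trait, rep_snp,
                    alpha=pw["alpha"], collinearity_r2=pw["collinearity_r2"],
                )
            )
    pathway_igenes.igene_pairs_frame(result.igene_pairs).to_csv(
        outdir / "igene_pairs.tsv", sep="\t", index=False
    )
    stage_done(
        "pathways",
        n_shared_pathways=len(result.shared_pathways),
        n_igene_pairs=len(result.igene_pairs),
    )
    _finish(result, manifest, outdir, t_all)
    return result


def _write_pleiotropy(result: PipelineResult, outdir: Path) -> None:
    qtl_calling.pqtls_to_frame(result.pqtls).to_csv(
        outdir / "pqtls.tsv", sep="\t", index=False
    )
    totals = result.qtl_totals()
    involved = {t for q in result.pqtls for t in (q.trait_a, q.trait_b)}
    if result.pqtls and all(totals.get(t, 0) > 0 for t in involved):
        qtl_calling.summarize_pleiotropy(result.pqtls, totals).to_csv(
            outdir / "pleiotropy_summary.tsv", sep="\t", index=False
        )


def _finish(
    result: PipelineResult, manifest: dict, outdir: Path, t_all: float
) -> None:
    manifest["total_wall_time_s"] = round(time.time() - t_all, 3)
    result.manifest = manifest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
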