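import numpy as np
import pytest

from pleiorice import synth_data
from pleiorice.genotype_io import GenotypeMatrix, SNPRecord


@pytest.fixture(scope="session")
def small_panel():
    """A 266-accession, 2000-SNP panel with the default architecture."""
    cfg = synth_data.SimulationConfig(n_snps=2000, seed=11)
    geno, meta = synth_data.simulate_population(cfg)
    pheno, truth = synth_data.simulate_phenotypes(geno, meta, cfg)
    return cfg, geno, meta, pheno, truth


@pytest.fixture(scope="session")
def null_panel():
    """A panel with no causal effects at all (pure background)."""
    cfg = synth_data.SimulationConfig(
        n_snps=1000,
        seed=23,
        pleiotropic=(),
        linked_pairs=(),
        interactions=(),
        n_background_qtl=0,
    )
    geno, meta = synth_data.simulate_population(cfg)
    pheno, truth = synth_data.simulate_phenotypes(geno, meta, cfg)
    return cfg, geno, meta, pheno, truth


def toy_genotypes(dosage, accessions=None, chrom="chr1", spacing=1000):
    """Wrap a literal dosage array (accessions x SNPs) as a GenotypeMatrix."""
    dosage = np.asarray(dosage, dtype=float)
    n_acc, n_snp = dosage.shape
    if accessions is None:
        accessions = [f"A{i + 1}" for i in range(n_acc)]
    snps = [
        SNPRecord(chrom, (j + 1) * spacing, "A", "G", id=f"s{j + 1}")
        for j in range(n_snp)
    ]
    return GenotypeMatrix(snps, list(accessions), dosage)
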