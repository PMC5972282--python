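"""Format I/O and coordinate conventions."""

import numpy as np
import pytest

from pleiorice import genotype_io as gio

from conftest import toy_genotypes

# Hand-transcribed 20-SNP x 12-accession VCF fixture.  EXPECTED below is
# the dosage table transcribed from the GT fields (rows = accessions in
# header order, columns = SNPs in coordinate order).
VCF_FIXTURE = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS01\tS02\tS03\tS04\tS05\tS06\tS07\tS08\tS09\tS10\tS11\tS12
chr1\t1000\tsnp1\tC\tA\t.\t.\t.\tGT\t1/1\t1/1\t0/0\t1/1\t1/1\t0/1\t1/1\t0/0\t0/0\t1/1\t1/1\t0/0
chr1\t2000\tsnp2\tC\tA\t.\t.\t.\tGT\t0/0\t0/0\t1/1\t0/0\t0/0\t1/1\t1/1\t0/0\t0/1\t1/1\t./.\t0/0
chr1\t3000\tsnp3\tC\tG\t.\t.\t.\tGT\t1/1\t./.\t1/1\t1/1\t1/1\t0/0\t0/0\t0/1\t0/0\t0/0\t0/0\t1/1
chr1\t4000\tsnp4\tC\tT\t.\t.\t.\tGT\t1/1\t1/1\t0/0\t1/1\t0/0\t./.\t0/0\t1/1\t0/0\t0/0\t0/0\t./.
chr1\t5000\tsnp5\tT\tC\t.\t.\t.\tGT\t0/0\t1/1\t1/1\t1/1\t0/0\t1/1\t0/0\t0/0\t1/1\t1/1\t0/0\t0/0
chr1\t6000\tsnp6\tT\tG\t.\t.\t.\tGT\t./.\t0/0\t1/1\t1/1\t0/0\t1/1\t0/0\t0/0\t0/0\t1/1\t0/0\t0/1
chr1\t7000\tsnp7\tT\tC\t.\t.\t.\tGT\t1/1\t0/0\t0/0\t1/1\t1/1\t0/0\t0/0\t0/0\t1/1\t0/0\t0/0\t0/0
chr1\t8000\tsnp8\tC\tT\t.\t.\t.\tGT\t1/1\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t1/1\t0/0\t1/1\t1/1
chr1\t9000\tsnp9\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t1/1\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t1/1\t0/0\t1/1
chr1\t10000\tsnp10\tT\tC\t.\t.\t.\tGT\t0/0\t1/1\t0/0\t0/0\t0/0\t0/1\t1/1\t0/0\t./.\t0/0\t0/0\t0/0
chr1\t11000\tsnp11\tA\tG\t.\t.\t.\tGT\t0/0\t1/1\t0/0\t0/0\t0/0\t0/0\t0/0\t1/1\t0/0\t0/1\t1/1\t0/0
chr1\t12000\tsnp12\tT\tG\t.\t.\t.\tGT\t0/1\t./.\t0/0\t0/0\t1/1\t0/0\t0/1\t1/1\t0/0\t0/0\t1/1\t0/0
chr2\t1000\tsnp13\tC\tT\t.\t.\t.\tGT\t1/1\t0/0\t1/1\t1/1\t0/0\t0/0\t1/1\t0/0\t0/0\t0/0\t0/0\t./.
chr2\t2000\tsnp14\tG\tT\t.\t.\t.\tGT\t1/1\t0/0\t1/1\t0/0\t0/0\t1/1\t0/0\t1/1\t0/1\t1/1\t1/1\t1/1
chr2\t3000\tsnp15\tC\tG\t.\t.\t.\tGT\t0/0\t0/0\t1/1\t0/0\t0/0\t0/0\t1/1\t0/0\t0/0\t0/0\t1/1\t0/1
chr2\t4000\tsnp16\tT\tG\t.\t.\t.\tGT\t0/0\t0/0\t1/1\t0/0\t1/1\t1/1\t0/0\t1/1\t0/0\t0/0\t1/1\t1/1
chr2\t5000\tsnp17\tT\tG\t.\t.\t.\tGT\t1/1\t0/0\t0/0\t0/0\t0/0\t1/1\t./.\t0/0\t0/0\t1/1\t0/0\t0/0
chr2\t6000\tsnp18\tT\tA\t.\t.\t.\tGT\t0/0\t0/0\t1/1\t1/1\t0/0\t1/1\t0/0\t1/1\t./.\t1/1\t0/0\t1/1
chr2\t7000\tsnp19\tT\tA\t.\t.\t.\tGT\t1/1\t0/0\t0/0\t1/1\t0/0\t0/0\t1/1\t1/1\t1/1\t0/0\t0/1\t0/0
chr2\t8000\tsnp20\tC\tT\t.\t.\t.\tGT\t1/1\t1/1\t0/0\t1/1\t./.\t1/1\t0/0\t1/1\t1/1\t0/0\t0/0\t0/0
"""

EXPECTED = np.array([
    [2.0, 0.0, 2.0, 2.0, 0.0, np.nan, 2.0, 2.0, 0.0, 0.0, 0.0, 1.0, 2.0, 2.0, 0.0, 0.0, 2.0, 0.0, 2.0, 2.0],
    [2.0, 0.0, np.nan, 2.0, 2.0, 0.0, 0.0, 0.0, 0.0, 2.0, 2.0, np.nan, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0],
    [0.0, 2.0, 2.0, 0.0, 2.0, 2.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 2.0, 2.0, 2.0, 2.0, 0.0, 2.0, 0.0, 0.0],
    [2.0, 0.0, 2.0, 2.0, 2.0, 2.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 0.0, 2.0, 2.0, 2.0],
    [2.0, 0.0, 2.0, 0.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, np.nan],
    [1.0, 2.0, 0.0, np.nan, 2.0, 2.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 2.0, 0.0, 2.0, 2.0, 2.0, 0.0, 2.0],
    [2.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 0.0, 1.0, 2.0, 0.0, 2.0, 0.0, np.nan, 0.0, 2.0, 0.0],
    [0.0, 0.0, 1.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 2.0, 0.0, 2.0, 0.0, 2.0, 0.0, 2.0, 2.0, 2.0],
    [0.0, 1.0, 0.0, 0.0, 2.0, 0.0, 2.0, 2.0, 0.0, np.nan, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, np.nan, 2.0, 2.0],
    [2.0, 2.0, 0.0, 0.0, 2.0, 2.0, 0.0, 0.0, 2.0, 0.0, 1.0, 0.0, 0.0, 2.0, 0.0, 0.0, 2.0, 2.0, 0.0, 0.0],
    [2.0, np.nan, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 0.0, 0.0, 2.0, 2.0, 0.0, 2.0, 2.0, 2.0, 0.0, 0.0, 1.0, 0.0],
    [0.0, 0.0, 2.0, np.nan, 0.0, 1.0, 0.0, 2.0, 2.0, 0.0, 0.0, 0.0, np.nan, 2.0, 1.0, 2.0, 0.0, 2.0, 0.0, 0.0],
])


@pytest.fixture
def fixture_vcf(tmp_path):
    path = tmp_path / "fixture.vcf"
    path.write_text(VCF_FIXTURE)
    return path


class TestReadVCF:
    def test_matches_hand_transcription(self, fixture_vcf):
        geno = gio.read_vcf(fixture_vcf, min_maf=0.0, max_missing=1.0)
        assert geno.accessions == [f"S{i:02d}" for i in range(1, 13)]
        assert [s.id for s in geno.snps] == [f"snp{j}" for j in range(1, 21)]
        np.testing.assert_array_equal(geno.dosage, EXPECTED)

    def test_maf_filter_drops_rare_snps(self, tmp_path):
        # 50 inbred accessions; 3 SNPs carry a single alt homozygote
        # (MAF 0.02), the other 7 are balanced
        rng = np.random.default_rng(0)
        dosage = np.zeros((50, 10))
        for j in range(7):
            dosage[rng.permutation(50)[:25], j] = 2.0
        for j in range(7, 10):
            dosage[j, j] = 2.0
        geno = toy_genotypes(dosage)
        path = tmp_path / "t.vcf"
        gio.write_vcf(geno, path)
        kept = gio.read_vcf(path, min_maf=0.05, max_missing=1.0)
        assert kept.n_snps == 7

    def test_missing_filter(self, tmp_path):
        dosage = np.tile([0.0, 2.0], (10, 2))[:, :3]
        dosage[:6, 0] = np.nan  # 60% missing
        geno = toy_genotypes(dosage)
        path = tmp_path / "t.vcf"
        gio.write_vcf(geno, path)
        kept = gio.read_vcf(path, min_maf=0.0, max_missing=0.5)
        assert kept.n_snps == 2

    def test_round_trip_idempotent(self, fixture_vcf, tmp_path):
        first = gio.read_vcf(fixture_vcf, min_maf=0.0, max_missing=1.0)
        path = tmp_path / "again.vcf"
        gio.write_vcf(first, path)
        second = gio.read_vcf(path, min_maf=0.0, max_missing=1.0)
        np.testing.assert_array_equal(first.dosage, second.dosage)
        assert [(s.chrom, s.pos) for s in first.snps] == [
            (s.chrom, s.pos) for s in second.snps
        ]

    def test_filters_commute(self, fixture_vcf):
        geno = gio.read_vcf(fixture_vcf, min_maf=0.0, max_missing=1.0)
        a = gio.filter_genotypes(
            gio.filter_genotypes(geno, min_maf=0.1, max_missing=1.0),
            min_maf=0.0, max_missing=0.1,
        )
        b = gio.filter_genotypes(
            gio.filter_genotypes(geno, min_maf=0.0, max_missing=0.1),
            min_maf=0.1, max_missing=1.0,
        )
        np.testing.assert_array_equal(a.dosage, b.dosage)

    def test_empty_result_error(self, fixture_vcf):
        with pytest.raises(gio.EmptyResultError):
            gio.read_vcf(fixture_vcf, min_maf=0.501, max_missing=0.0)

    def test_malformed_vcf_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(gio.VCFParseError):
            gio.read_vcf(path)


class TestPhenotypes:
    def test_well_formed(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "accession\ttrait\tenvironment\tvalue\n"
            "A1\tHD\tSY\t80.5\nA1\tGNP\tSY\t150\nA2\tHD\tSY\t95\nA2\tHD\tCS\t100\n"
        )
        tab = gio.read_phenotypes(path)
        assert len(tab.table) == 4

    def test_duplicate_key_errors(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "accession\ttrait\tenvironment\tvalue\n"
            "A1\tHD\tSY\t80.5\nA1\tHD\tSY\t81.0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            gio.read_phenotypes(path)

    def test_na_value_is_missing(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "accession\ttrait\tenvironment\tvalue\nA1\tHD\tSY\tNA\nA2\tHD\tSY\t90\n"
        )
        tab = gio.read_phenotypes(path)
        vec = tab.vector("HD", "SY", ["A1", "A2"])
        assert np.isnan(vec["A1"]) and vec["A2"] == 90

    def test_unknown_trait_errors(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("accession\ttrait\tenvironment\tvalue\nA1\tXX\tSY\t1\n")
        with pytest.raises(ValueError, match="trait"):
            gio.read_phenotypes(path)


class TestGenes:
    def test_bed_coordinates_one_based(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr3\t700000\t710000\tHYRlike\n")
        genes = gio.read_genes(path)
        assert genes[0].start == 700001 and genes[0].end == 710000

    def test_gff3(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=gA\n"
            "chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=gA.1;Parent=gA\n"
            "chr1\tsrc\tgene\t900\t1200\t.\t-\t.\tID=gB\n"
            "chr2\tsrc\tgene\t50\t80\t.\t+\t.\tID=gC\n"
        )
        genes = gio.read_genes(path)
        assert [g.gene_id for g in genes] == ["gA", "gB", "gC"]

    def test_pathway_merge_partial(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t0\t100\tgA\nchr1\t200\t300\tgB\nchr1\t400\t500\tgC\n")
        pw = tmp_path / "pw.tsv"
        pw.write_text("gA\tpath1\ngB\tpath1\ngB\tpath2\ngZ\tpath3\n")
        genes = {g.gene_id: g for g in gio.read_genes(bed, pw)}
        assert genes["gA"].pathways == {"path1"}
        assert genes["gB"].pathways == {"path1", "path2"}
        assert genes["gC"].pathways == frozenset()


class TestQTLBed:
    def test_bed_convention(self, tmp_path):
        from pleiorice.qtl_calling import QTLBin

        b = QTLBin(
            chrom="chr1", start=100, end=110000, snp_ids=["a", "b", "c"],
            snp_positions=[100, 50000, 110000], peak_snp="b",
            peak_neg_log10_p=8.5, trait="HD", population="full",
            environment="SY",
        )
        path = tmp_path / "q.bed"
        gio.write_qtl_bed([b], path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert line.split("\t")[:3] == ["chr1", "99", "110000"]

    def test_empty_list_writes_header(self, tmp_path):
        path = tmp_path / "q.bed"
        gio.write_qtl_bed([], path)
        assert path.read_text().startswith("#")

    def test_round_trip(self, tmp_path):
        from pleiorice.qtl_calling import QTLBin

        bins = [
            QTLBin("chr2", 501, 900, ["x", "y", "z"], [501, 700, 900], "y",
                   12.0, "GNP", "indica", "CS"),
            QTLBin("chr2", 1500, 2200, ["u", "v", "w"], [1500, 1800, 2200],
                   "w", 6.25, "GNP", "indica", "CS"),
        ]
        path = tmp_path / "q.bed"
        gio.write_qtl_bed(bins, path)
        frame = gio.read_qtl_bed(path)
        assert list(frame["start"]) == [501, 1500]
        assert list(frame["end"]) == [900, 2200]
        assert set(frame["trait"]) == {"GNP"}


def test_bed_interval_conversion_inverse():
    for start, end in [(1, 1), (100, 110000), (7, 9)]:
        assert gio.from_bed_interval(*gio.to_bed_interval(start, end)) == (start, end)
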