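"""QTL bin calling, pleiotropic intersection, and percentage summaries."""

import numpy as np
import pandas as pd
import pytest

from pleiorice.genotype_io import GeneModel
from pleiorice.qtl_calling import (
    PleiotropicQTL,
    QTLBin,
    call_qtls,
    distinct_pqtl_intervals,
    intersect_qtls,
    round_percent,
    summarize_pleiotropy,
)


def make_assoc(positions, neg_log10, chrom="chr1", trait="HD"):
    positions = list(positions)
    return pd.DataFrame(
        {
            "chrom": [chrom] * len(positions),
            "pos": positions,
            "id": [f"{chrom}:{p}" for p in positions],
            "neg_log10_p": neg_log10,
            "p": [10.0 ** (-v) for v in neg_log10],
            "trait": trait,
            "population": "full",
            "environment": "SY",
        }
    )


def make_bin(start, end, trait="HD", chrom="chr1", n=3, population="full",
             environment="SY"):
    pos = np.linspace(start, end, n).astype(int).tolist()
    return QTLBin(
        chrom=chrom, start=start, end=end,
        snp_ids=[f"{trait}:{chrom}:{p}" for p in pos], snp_positions=pos,
        peak_snp=f"{trait}:{chrom}:{pos[0]}", peak_neg_log10_p=9.0,
        trait=trait, population=population, environment=environment,
    )


class TestCallQTLs:
    def test_three_snps_within_gaps_form_one_bin(self):
        assoc = make_assoc([100, 50_000, 110_000], [8, 9, 7])
        bins = call_qtls(assoc, np.array([True, True, True]))
        assert len(bins) == 1
        assert (bins[0].start, bins[0].end) == (100, 110_000)
        assert bins[0].peak_snp == "chr1:50000"

    def test_two_snps_no_bin(self):
        assoc = make_assoc([100, 200], [8, 9])
        assert call_qtls(assoc, np.array([True, True])) == []

    def test_gap_of_exactly_70kb_splits(self):
        assoc = make_assoc([0, 10, 20, 70_020, 70_030, 70_040], [5] * 6)
        bins = call_qtls(assoc, np.ones(6, dtype=bool))
        assert len(bins) == 2  # strict < 70 kb rule: a 70 kb gap breaks

    def test_matches_bruteforce_oracle(self):
        # exhaustive maximal-chain oracle over random significance patterns
        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = rng.integers(5, 40)
            pos = np.sort(rng.choice(np.arange(1, 500) * 10_000, m, replace=False))
            sig = rng.random(m) < 0.4
            neg = rng.uniform(3, 12, m)
            assoc = make_assoc(pos.tolist(), neg.tolist())
            bins = call_qtls(assoc, sig, max_gap=70_000, min_snps=3)

            sig_pos = pos[sig]
            chains, cur = [], []
            for p in sig_pos:
                if cur and p - cur[-1] >= 70_000:
                    chains.append(cur)
                    cur = []
                cur.append(p)
            if cur:
                chains.append(cur)
            expected = [(c[0], c[-1]) for c in chains if len(c) >= 3]
            assert [(b.start, b.end) for b in bins] == expected

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(23)
        pos = np.sort(rng.choice(np.arange(1, 300) * 5_000, 30, replace=False))
        neg = rng.uniform(3, 10, 30)
        assoc = make_assoc(pos.tolist(), neg.tolist())
        sig = rng.random(30) < 0.5
        bins1 = call_qtls(assoc, sig)
        shuffle = rng.permutation(30)
        assoc2 = assoc.iloc[shuffle].reset_index(drop=True)
        bins2 = call_qtls(assoc2, sig[shuffle])
        assert [(b.start, b.end, tuple(b.snp_ids)) for b in bins1] == [
            (b.start, b.end, tuple(b.snp_ids)) for b in bins2
        ]

    def test_members_are_significant_and_unique(self):
        rng = np.random.default_rng(29)
        pos = np.sort(rng.choice(np.arange(1, 400) * 3_000, 60, replace=False))
        assoc = make_assoc(pos.tolist(), rng.uniform(3, 10, 60).tolist())
        sig = rng.random(60) < 0.6
        bins = call_qtls(assoc, sig)
        sig_ids = set(assoc.loc[sig, "id"])
        seen = set()
        for b in bins:
            for sid in b.snp_ids:
                assert sid in sig_ids
                assert sid not in seen
                seen.add(sid)


class TestIntersect:
    def test_overlap_yields_merged_interval(self):
        a = make_bin(100, 200, "HD")
        b = make_bin(150, 300, "GNP")
        pq = intersect_qtls([a], [b])
        assert len(pq) == 1
        assert (pq[0].start, pq[0].end) == (100, 300)

    def test_touching_is_not_overlapping(self):
        a = make_bin(100, 200, "HD")
        b = make_bin(201, 300, "GNP")
        assert intersect_qtls([a], [b]) == []

    def test_population_mismatch_errors(self):
        a = make_bin(100, 200, "HD", population="indica")
        b = make_bin(150, 300, "GNP", population="japonica")
        with pytest.raises(ValueError):
            intersect_qtls([a], [b])

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            bins_a = [
                make_bin(s, s + rng.integers(10, 200) * 100, "HD")
                for s in rng.choice(np.arange(1, 100) * 1_000, 5, replace=False)
            ]
            bins_b = [
                make_bin(s, s + rng.integers(10, 200) * 100, "GNP")
                for s in rng.choice(np.arange(1, 100) * 1_000, 5, replace=False)
            ]
            got = {
                (q.bin_a.start, q.bin_a.end, q.bin_b.start, q.bin_b.end)
                for q in intersect_qtls(bins_a, bins_b)
            }
            expected = {
                (a.start, a.end, b.start, b.end)
                for a in bins_a
                for b in bins_b
                if a.start <= b.end and b.start <= a.end
            }
            assert got == expected

    def test_psnps_are_shared_ids(self):
        a = make_bin(100, 300, "HD", n=5)
        b = make_bin(100, 300, "HD", n=5)
        # same positions but different trait prefix: no shared ids
        b2 = make_bin(100, 300, "GNP", n=5)
        pq = intersect_qtls([a], [b2])
        assert pq[0].psnp_ids == []
        # force shared ids
        b3 = make_bin(100, 300, "GNP", n=5)
        b3.snp_ids = list(a.snp_ids)
        pq = intersect_qtls([a], [b3])
        assert pq[0].psnp_ids == sorted(a.snp_ids)

    def test_pgene_annotation_two_tiers(self):
        a = make_bin(100, 1000, "HD", n=4)
        b = make_bin(500, 1500, "GNP", n=4)
        # gene spanning SNPs of both traits
        g1 = GeneModel("gBoth", "chr1", 90, 1600)
        # gene spanning only trait A SNPs
        g2 = GeneModel("gA", "chr1", 90, 110)
        pq = intersect_qtls([a], [b], genes=[g1, g2])[0]
        assert pq.pgene_ids == ["gBoth"]
        assert pq.pgene_with_psnp_ids == []  # no shared significant SNP
        # sharing SNP chr1:100 makes both genes hold a pSNP (gA spans it)
        b.snp_ids[0] = a.snp_ids[0]
        b.snp_positions[0] = a.snp_positions[0]
        pq = intersect_qtls([a], [b], genes=[g1, g2])[0]
        assert pq.pgene_with_psnp_ids == ["gBoth", "gA"]


class TestSummaries:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(5, 77, 6.49), (8, 65, 12.31), (0, 77, 0.0), (1, 71, 1.41),
         (2, 65, 3.08), (1, 3, 33.33), (1, 8, 12.5)],
    )
    def test_round_percent(self, count, total, expected):
        assert round_percent(count, total) == expected

    def test_round_half_up(self):
        assert round_percent(1, 16) == 6.25
        assert round_percent(25, 1000) == 2.5
        assert round_percent(1, 32) == 3.13  # 3.125 rounds up

    def test_summary_counts_and_percentages(self):
        a = make_bin(100, 200, "HD")
        b = make_bin(150, 300, "GNP")
        pq = intersect_qtls([a], [b])
        pq[0].mean_r2 = 0.5
        table = summarize_pleiotropy(pq, {"HD": 77, "GNP": 65})
        all_row = table[table["class"] == "all"].iloc[0]
        assert all_row["count"] == 1
        assert all_row["pct_of_a"] == round_percent(1, 77)
        assert all_row["pct_of_b"] == round_percent(1, 65)
        ld_row = table[table["class"] == "ld_gt_0.2"].iloc[0]
        assert ld_row["count"] == 1

    def test_zero_total_errors(self):
        a = make_bin(100, 200, "HD")
        b = make_bin(150, 300, "GNP")
        pq = intersect_qtls([a], [b])
        with pytest.raises(ValueError):
            summarize_pleiotropy(pq, {"HD": 0, "GNP": 65})


def test_distinct_intervals_counts_multi_trait_loci_once():
    a = make_bin(100, 200, "HD")
    b = make_bin(150, 300, "GNP")
    c = make_bin(180, 260, "PN")
    pqs = (
        intersect_qtls([a], [b]) + intersect_qtls([a], [c]) + intersect_qtls([b], [c])
    )
    assert len(pqs) == 3  # pairwise listing triple-counts the locus
    assert distinct_pqtl_intervals(pqs) == 1


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=150)
@given(
    st.lists(
        st.tuples(st.integers(1, 3_000_000), st.booleans()),
        min_size=3, max_size=40, unique_by=lambda t: t[0],
    )
)
def test_bin_calling_invariants_property(snps):
    positions = sorted(p for p, _ in snps)
    sig = np.array([s for _, s in sorted(snps)])
    assoc = make_assoc(positions, list(np.linspace(4, 9, len(positions))))
    bins = call_qtls(assoc, sig)
    sig_positions = set(np.array(positions)[sig])
    for b in bins:
        assert b.n_snps >= 3
        assert b.start <= b.end
        assert set(b.snp_positions) <= sig_positions
        gaps = np.diff(sorted(b.snp_positions))
        assert (gaps < 70_000).all()
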