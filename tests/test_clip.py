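"""iCLIP read filtering, cross-link calling, enrichment and tRNA profiling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taurna import synthdata
from taurna.clip import (
    AlignedRead,
    CrosslinkSite,
    GenomeAnnotation,
    abundance_compare,
    cluster_reads,
    crosslink_site,
    crosslink_sites,
    enrichment_table,
    preprocess_reads,
    trna_positional_profile,
)


def read(start, end, strand="+", chrom="chrT", score=30, barcode="ACGTACGTA",
         name=""):
    return AlignedRead(
        chrom=chrom, start=start, end=end, strand=strand, score=score,
        random_barcode=barcode, name=name,
    )


class TestPreprocess:
    def test_pcr_duplicates_collapse(self):
        reads = [read(100, 130, name=f"r{i}") for i in range(3)]
        kept, _ = preprocess_reads(reads)
        assert len(kept) == 1

    def test_length_boundary(self):
        kept, _ = preprocess_reads([read(0, 17), read(100, 118)])
        assert [(r.start, r.end) for r in kept] == [(100, 118)]

    def test_score_boundary(self):
        kept, _ = preprocess_reads([read(0, 30, score=9), read(100, 130, score=10)])
        assert [r.score for r in kept] == [10]

    def test_unbarcoded_reads_binned_not_dropped(self):
        reads = [read(0, 30, barcode=""), read(100, 130)]
        kept, unbarcoded = preprocess_reads(reads)
        assert len(kept) == 1 and len(unbarcoded) == 1

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(0)
        reads = [
            read(
                s := int(rng.integers(0, 500)), s + int(rng.integers(18, 40)),
                barcode="".join(rng.choice(list("ACGT"), size=4)),
                name=f"r{i}",
            )
            for i in range(100)
        ]
        once, _ = preprocess_reads(reads)
        twice, _ = preprocess_reads(once)
        assert twice == once
        shuffled = list(reads)
        rng.shuffle(shuffled)
        assert preprocess_reads(shuffled)[0] == once


class TestCrosslinkSites:
    def test_plus_strand_site_is_upstream_of_start(self):
        site = crosslink_site(read(100, 135, "+"))
        assert (site.position, site.strand, site.clamped) == (99, "+", False)

    def test_minus_strand_site_is_at_end(self):
        site = crosslink_site(read(100, 135, "-"))
        assert (site.position, site.strand) == (135, "-")

    def test_chromosome_start_clamped_and_marked(self):
        site = crosslink_site(read(0, 30, "+"))
        assert site.position == 0 and site.clamped

    def test_aggregation_counts_support(self):
        sites = crosslink_sites([read(100, 135), read(100, 140), read(7, 40, "-")])
        by_pos = {(s.position, s.strand): s.count for s in sites}
        assert by_pos == {(99, "+"): 2, (40, "-"): 1}


def toy_annotation():
    intervals = {
        "exon": [("chrT", 100, 300)],
        "tRNA": [("chrT", 400, 476)],
        "rRNA": [("chrT", 600, 700)],
    }
    return GenomeAnnotation(intervals=intervals, chrom_lengths={"chrT": 1000})


class TestEnrichment:
    def test_read_percentages_sum_to_100(self):
        reads, annotation, _, _ = synthdata.gen_clip_dataset(
            n_reads=2000, seed=1
        )
        table = enrichment_table(reads, annotation)
        assert table["read_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_planted_fold_recovered(self):
        _, _, _, base = synthdata.gen_clip_dataset(n_reads=10, seed=0)
        folds = synthdata.fold_vector(base["category_lengths"], {"tRNA": 50.0})
        reads, annotation, _, truth = synthdata.gen_clip_dataset(
            enrichment=folds, n_reads=100_000, seed=2
        )
        table = enrichment_table(reads, annotation).set_index("category")
        assert truth["folds"]["tRNA"] == pytest.approx(50.0, rel=1e-9)
        assert table.loc["tRNA", "fold"] == pytest.approx(50.0, rel=0.1)

    def test_all_reads_intergenic(self):
        annotation = toy_annotation()
        reads = [read(900 + i, 930 + i, name=f"r{i}") for i in range(5)]
        table = enrichment_table(reads, annotation).set_index("category")
        assert table.loc["intergenic", "read_pct"] == 100.0
        assert (table.drop("intergenic")["read_pct"] == 0).all()

    def test_precedence_assigns_single_category(self):
        annotation = GenomeAnnotation(
            intervals={
                "exon": [("chrT", 100, 300)],
                "tRNA": [("chrT", 150, 226)],
            },
            chrom_lengths={"chrT": 1000},
        )
        table = enrichment_table(
            [read(161, 190)], annotation  # site at 160, inside both
        ).set_index("category")
        assert table.loc["tRNA", "read_count"] == 1
        assert table.loc["exon", "read_count"] == 0
        # category totals still partition the genome
        assert table["genome_pct"].sum() == pytest.approx(100.0)


class TestClusters:
    def test_retention_boundary_at_five_reads(self):
        stack5 = [read(100, 140, name=f"a{i}", barcode=f"A{i}AAA") for i in range(5)]
        stack4 = [read(500, 540, name=f"b{i}", barcode=f"B{i}BBB") for i in range(4)]
        clusters = cluster_reads(stack5 + stack4)
        assert len(clusters) == 1
        assert clusters[0].count == 5
        assert clusters[0].start == 100 and clusters[0].end == 140

    def test_gap_separates_clusters(self):
        left = [read(100 + i, 140 + i, name=f"l{i}", barcode=f"L{i}LLL")
                for i in range(5)]
        right = [read(300 + i, 340 + i, name=f"r{i}", barcode=f"R{i}RRR")
                 for i in range(5)]
        clusters = cluster_reads(left + right)
        assert len(clusters) == 2

    def test_strands_do_not_merge(self):
        plus = [read(100, 140, "+", name=f"p{i}", barcode=f"P{i}PPP")
                for i in range(5)]
        minus = [read(100, 140, "-", name=f"m{i}", barcode=f"M{i}MMM")
                 for i in range(5)]
        clusters = cluster_reads(plus + minus)
        assert sorted(c.strand for c in clusters) == ["+", "-"]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_permutation_invariance_and_membership_bound(self, seed):
        rng = np.random.default_rng(seed)
        reads = [
            read(
                s := int(rng.integers(0, 400)),
                s + int(rng.integers(18, 40)),
                strand=rng.choice(["+", "-"]),
                name=f"r{i}",
                barcode="".join(rng.choice(list("ACGT"), size=5)),
            )
            for i in range(60)
        ]
        base = cluster_reads(reads)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        again = cluster_reads(shuffled)
        key = lambda c: (c.chrom, c.strand, c.start, c.end, c.count)
        assert sorted(map(key, base)) == sorted(map(key, again))
        assert sum(c.count for c in base) <= len(reads)


class TestPositionalProfile:
    def make_models(self):
        return synthdata.make_trna_models(block_start=400, n_genes=1, seed=0)

    def test_anticodon_first_nucleotide_is_position_one(self):
        model = self.make_models()[0]
        a0 = model.anticodon[0]
        site = CrosslinkSite("chrT", model.start + a0, "+")
        profile = trna_positional_profile([site], [model])
        assert profile.positions == {1: 1}
        assert profile.element_counts == {"anticodon_loop": 1}

    def test_five_prime_offsets(self):
        model = self.make_models()[0]
        a0 = model.anticodon[0]
        sites = [
            CrosslinkSite("chrT", model.start + a0 - 1, "+"),  # position 0
            CrosslinkSite("chrT", model.start + a0 - 2, "+"),  # position -1
            CrosslinkSite("chrT", model.start + a0 + 3, "+"),  # position 4
        ]
        profile = trna_positional_profile(sites, [model])
        assert profile.positions == {0: 1, -1: 1, 4: 1}

    def test_outside_sites_unassigned(self):
        model = self.make_models()[0]
        profile = trna_positional_profile(
            [CrosslinkSite("chrT", 5, "+", count=3)], [model]
        )
        assert profile.unassigned == 3 and profile.total == 0

    def test_biased_simulation_mode_in_anticodon_loop(self):
        reads, _, models, _ = synthdata.gen_clip_dataset(
            enrichment={"tRNA": 30.0}, n_reads=3000, seed=7
        )
        kept, _ = preprocess_reads(reads)
        sites = crosslink_sites(kept)
        profile = trna_positional_profile(sites, models)
        assert profile.total >= 500
        mode_label_counts = profile.element_counts
        assert max(mode_label_counts, key=mode_label_counts.get) == "anticodon_loop"
        assert -3 <= profile.mode <= 5  # mode inside the anticodon loop span


class TestAbundanceCompare:
    def test_identical_pools_are_flat(self):
        counts = {"g1": 10, "g2": 20, "g3": 70}
        table = abundance_compare(counts, dict(counts))
        assert np.allclose(table["log2_ratio"], 0.0)

    def test_tenfold_fraction_gives_log2_ten(self):
        clip = {"g1": 10, "g2": 90}
        background = {"g1": 1, "g2": 99}
        table = abundance_compare(clip, background).set_index("gene")
        assert table.loc["g1", "log2_ratio"] == pytest.approx(np.log2(10), abs=1e-9)

    def test_disjoint_pools_all_flagged(self):
        table = abundance_compare({"a": 5}, {"b": 7})
        assert table["pseudocount_dependent"].all()

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            abundance_compare({}, {"a": 1})
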