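import itertools

import numpy as np
import pandas as pd
import pytest

from deaseq import landscape
from deaseq.formats import GeneModel, GenomeRef, IntervalSet
from deaseq.landscape import (
    AnnotationConfig,
    annotate_feature,
    annotate_features,
    classify_context,
    enumerate_cytosines,
    kmer_context_freq,
    mark_overlap,
    te_overlap,
    te_zone_lengths,
    tss_distance_profile,
)
from conftest import make_records

COMP = str.maketrans("ACGTN", "TGCAN")


def oracle_context(seq: str, pos: int, strand: str):
    """Independent string-logic classifier: context from the two bases 3' of
    the C on its own strand, AMBIG when N or the sequence end intervenes."""
    if strand == "-":
        seq = seq.translate(COMP)[::-1]
        pos = len(seq) - 1 - pos
    assert seq[pos] == "C"
    n1 = seq[pos + 1] if pos + 1 < len(seq) else "N"
    n2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
    tri = "C" + n1 + n2
    if n1 == "G":
        return "CG", tri
    if n1 == "N":
        return "AMBIG", tri
    if n2 == "G":
        return "CHG", tri
    if n2 == "N":
        return "AMBIG", tri
    return "CHH", tri


class TestContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGT", 1, "+", ("CG", "CGT")),
            ("ACCG", 1, "+", ("CHG", "CCG")),
            ("TTCGAA", 3, "-", ("CG", "CGA")),
            ("AC", 1, "+", ("AMBIG", "CNN")),
            ("ACNG", 1, "+", ("AMBIG", "CNG")),
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        assert classify_context(seq, None, pos, strand) == expected

    def test_non_cytosine_rejected(self):
        with pytest.raises(ValueError, match="not C"):
            classify_context("AAGT", None, 0, "+")
        with pytest.raises(ValueError, match="not C"):
            classify_context("AAGT", None, 0, "-")

    def test_agrees_with_bruteforce_oracle_over_all_5mers(self):
        """Exhaustive check against an independent oracle: every 5-mer, both
        strands, classifying the centre base where it is a cytosine."""
        for bases in itertools.product("ACGT", repeat=5):
            seq = "".join(bases)
            if seq[2] == "C":
                assert classify_context(seq, None, 2, "+") == oracle_context(seq, 2, "+")
            if seq[2] == "G":
                assert classify_context(seq, None, 2, "-") == oracle_context(seq, 2, "-")

    def test_enumeration_matches_scalar_classifier(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGTN"), 500, p=[0.2, 0.3, 0.3, 0.18, 0.02]))
        genome = GenomeRef({"chr1": seq})
        cyt = enumerate_cytosines(genome)
        # every C on either strand appears exactly once
        n_plus = seq.count("C")
        n_minus = seq.count("G")
        assert len(cyt) == n_plus + n_minus
        for row in cyt.sample(60, random_state=0).itertuples(index=False):
            ctx, tri = classify_context(seq, None, row.pos - 1, row.strand)
            assert (row.context, row.trinucleotide) == (ctx, tri)


class TestFeatures:
    @pytest.fixture
    def genes(self):
        # gene A: + strand, two exons with one intron; gene B downstream
        a = GeneModel("A", "chr1", "+", 10_000, 13_000, [(10_000, 11_000), (12_000, 13_000)])
        b = GeneModel("B", "chr1", "+", 14_000, 15_000, [(14_000, 15_000)])
        return [a, b]

    def test_promoter_window_upstream_of_tss(self, genes):
        assert annotate_feature("chr1", 9_501, genes) == "promoter"  # 500 bp upstream
        assert annotate_feature("chr1", 7_999, genes) == "distal_intergenic"

    def test_intron_and_downstream(self, genes):
        assert annotate_feature("chr1", 11_500, genes) == "intron"
        assert annotate_feature("chr1", 15_100, genes) == "downstream"
        assert annotate_feature("chr1", 15_400, genes) == "distal_intergenic"

    def test_promoter_precedence_over_intron(self, genes):
        # 11_500..13_000 is gene A intron/exon but also within 2 kb of B's TSS
        assert annotate_feature("chr1", 12_500, genes) == "promoter"
        # precedence is configurable: exon wins under a different total order
        cfg = AnnotationConfig(
            precedence=("exon", "intron", "promoter", "downstream", "distal_intergenic")
        )
        assert annotate_feature("chr1", 12_500, genes, cfg) == "exon"

    def test_minus_strand_orientation(self):
        g = GeneModel("M", "chr1", "-", 10_000, 12_000, [(10_000, 12_000)])
        assert annotate_feature("chr1", 12_500, [g]) == "promoter"
        assert annotate_feature("chr1", 9_800, [g]) == "downstream"

    def test_no_genes_everything_distal(self):
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1, 50, 100]})
        feats = annotate_features(sites, [])
        assert (feats == "distal_intergenic").all()

    def test_categories_partition_sites(self, genes):
        rng = np.random.default_rng(0)
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(1, 20_000, 500)}
        )
        feats = annotate_features(sites, genes)
        assert len(feats) == 500
        assert feats.value_counts().sum() == 500
        pd.testing.assert_series_equal(feats, annotate_features(sites, genes))


class TestTssProfile:
    def test_sites_at_tss_land_in_central_bin(self):
        genes = [GeneModel("A", "chr1", "+", 5_000, 6_000, [(5_000, 6_000)])]
        sites = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [5_001] * 4})
        prof = tss_distance_profile(sites, genes)
        assert prof.within_window_fraction == 1.0
        central = prof.table[(prof.table["bin_start"] == 0)]
        assert central["fraction"].iloc[0] == 1.0

    def test_uniform_sites_match_analytic_fraction(self):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", s, s + 1_000, [(s, s + 1_000)])
            for i, s in enumerate(range(25_000, 200_000, 50_000))
        ]
        sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 200_000, 10)})
        prof = tss_distance_profile(sites, genes)
        assert prof.within_window_fraction == pytest.approx(6000 / 50000, abs=0.01)

    def test_no_genes_is_an_error(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1]})
        with pytest.raises(ValueError, match="without gene models"):
            tss_distance_profile(sites, [])

    def test_empty_sites_flagged_undefined(self):
        genes = [GeneModel("A", "chr1", "+", 0, 100, [(0, 100)])]
        prof = tss_distance_profile(pd.DataFrame(columns=["chrom", "pos"]), genes)
        assert not prof.defined
        assert np.isnan(prof.within_window_fraction)

    def test_minus_strand_sign_is_orientation_aware(self):
        genes = [GeneModel("A", "chr1", "-", 5_000, 6_000, [(5_000, 6_000)])]
        # 100 bp downstream of a minus-strand TSS lies at lower coordinate
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [5_900]})
        prof = tss_distance_profile(sites, genes)
        row = prof.table[prof.table["count"] > 0].iloc[0]
        assert row["bin_start"] >= 0  # positive signed distance


class TestTeZones:
    TE = IntervalSet("TE", {"chr1": [(5_000, 6_000)]})

    @pytest.mark.parametrize(
        "pos,zone",
        [
            (5_500, "inside"),   # TE midpoint
            (4_002, "flank"),    # 999 bp before TE start (0-based 4001)
            (4_000, "outside"),  # 1001 bp before
            (4_001, "flank"),    # exactly 1000 bp: flank is closed at 1000
            (7_000, "flank"),    # 1000 bp past last TE base (0-based 6999)
            (7_001, "outside"),
        ],
    )
    def test_zone_boundaries(self, pos, zone):
        sites = make_records([("chr1", pos, "+", 1, 1, "CHH")])
        rep = te_overlap(sites, self.TE)
        assert rep.loc[rep["n_sites"] == 1, "zone"].iloc[0] == zone

    def test_fraction_counting(self):
        rows = [("chr1", 4_500 + i, "+", 1, 1, "CHH") for i in range(17)]
        rows += [("chr1", 100_000 + i, "+", 1, 1, "CHH") for i in range(83)]
        rep = te_overlap(make_records(rows), self.TE).set_index("zone")
        assert rep.loc["flank", "fraction"] == pytest.approx(0.17)
        assert rep.loc["outside", "fraction"] == pytest.approx(0.83)

    def test_zone_lengths_partition_chromosome(self):
        te = IntervalSet("TE", {"chr1": [(5_000, 6_000), (5_500, 8_000), (40_000, 41_000)]})
        lengths = te_zone_lengths(te, {"chr1": 100_000}, flank_bp=1_000)
        assert sum(lengths.values()) == 100_000
        assert lengths["inside"] == 4_000

    def test_mean_ratio_per_zone(self):
        rows = [("chr1", 5_500, "+", 9, 1, "CHH"), ("chr1", 90_000, "+", 1, 9, "CHH")]
        rep = te_overlap(make_records(rows), self.TE).set_index("zone")
        assert rep.loc["inside", "mean_ratio"] == pytest.approx(0.9)
        assert rep.loc["outside", "mean_ratio"] == pytest.approx(0.1)


class TestMarkOverlap:
    def test_all_inside_single_interval(self):
        marks = {"H3K4me3": IntervalSet("H3K4me3", {"chr1": [(0, 10_000)]})}
        sites = make_records([("chr1", p, "+", 9, 1, "CG") for p in (10, 20, 30)])
        rep = mark_overlap(sites, marks)
        assert rep.loc[0, "fraction_inside"] == 1.0
        assert rep.loc[0, "n_inside"] == 3
        assert np.isnan(rep.loc[0, "mean_ratio_outside"])

    def test_inside_outside_ratio_split(self):
        marks = {"H3K9me1": IntervalSet("H3K9me1", {"chr1": [(0, 100)]})}
        sites = make_records(
            [("chr1", 50, "+", 9, 1, "CG"), ("chr1", 500, "+", 1, 9, "CG")]
        )
        rep = mark_overlap(sites, marks).iloc[0]
        assert rep["mean_ratio_inside"] == pytest.approx(0.9)
        assert rep["mean_ratio_outside"] == pytest.approx(0.1)

    def test_empty_interval_set_guarded(self):
        marks = {"H3K9me3": IntervalSet("H3K9me3", {})}
        sites = make_records([("chr1", 50, "+", 9, 1, "CG")])
        rep = mark_overlap(sites, marks).iloc[0]
        assert rep["fraction_inside"] == 0.0
        assert np.isnan(rep["mean_ratio_inside"])


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), 120_000, p=[0.18, 0.32, 0.32, 0.18]))
    return GenomeRef({"chr1": seq})


class TestKmerEnrichment:
    def test_even_k_rejected(self, genome):
        sites = make_records([("chr1", 10, "+", 1, 1, "CG")])
        with pytest.raises(ValueError, match="odd"):
            kmer_context_freq(sites, genome, k=4)

    def test_rows_sum_to_valid_site_count(self, genome):
        cyt = enumerate_cytosines(genome)
        pick = cyt.sample(300, random_state=1)
        sites = make_records(
            [(r.chrom, r.pos, r.strand, 1, 1, r.context) for r in pick.itertuples(index=False)]
        )
        df = kmer_context_freq(sites, genome, k=3)
        assert df["n_sites"].sum() == df.attrs["n_valid"]
        assert df.attrs["n_valid"] + df.attrs["n_skipped"] == 300

    def test_uniform_sites_show_no_enrichment(self, genome):
        cyt = enumerate_cytosines(genome)
        pick = cyt.sample(1_000, random_state=7)
        sites = make_records(
            [(r.chrom, r.pos, r.strand, 1, 1, r.context) for r in pick.itertuples(index=False)]
        )
        df = kmer_context_freq(sites, genome, k=3)
        assert not df["enriched"].any()

    def test_planted_trinucleotide_detected(self, genome):
        cyt = enumerate_cytosines(genome)
        cac = cyt[cyt["trinucleotide"] == "CAC"].head(400)
        sites = make_records(
            [(r.chrom, r.pos, r.strand, 1, 1, r.context) for r in cac.itertuples(index=False)]
        )
        df = kmer_context_freq(sites, genome, k=3)
        hit = df[df["enriched"]]
        assert len(hit) >= 1
        # a site whose downstream trinucleotide is CAC has centred 3-mer
        # (left)CA, so every enriched k-mer ends in CA and together they
        # must carry essentially all planted sites
        assert hit["kmer"].str[1:].eq("CA").all()
        assert hit["n_sites"].sum() >= 350
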