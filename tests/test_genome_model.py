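"""Feature partitioning, peak annotation and target assignment."""

import numpy as np
import pytest

from ire_screen.genome_model import (
    AnnotatedPeak,
    GeneModel,
    annotate_peak,
    annotate_peaks,
    assign_target_gene,
    build_feature_map,
    genomic_distribution,
)
from ire_screen.io_formats import GenomicInterval
from ire_screen.peaks import Peak


def make_gene(gene_id, chrom, start, exon_pairs, strand="+"):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs)
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, exon_pairs[0][0], exon_pairs[-1][1], strand),
        strand=strand,
        exons=exons,
    )


def brute_force_label(genes, promoter_window, chrom, pos):
    """Independent per-base labeler: loop over genes, feature priority."""
    up, down = promoter_window
    for feature in ("promoter", "exon", "intron"):
        for g in genes:
            if g.interval.chrom != chrom:
                continue
            if feature == "promoter":
                if g.strand == "+":
                    lo, hi = g.tss - up, g.tss + down
                else:
                    lo, hi = g.tss - down + 1, g.tss + up + 1
                if lo <= pos < hi:
                    return "promoter"
            elif feature == "exon":
                if any(e.start <= pos < e.end for e in g.exons):
                    return "exon"
            else:
                if (g.interval.start <= pos < g.interval.end
                        and not any(e.start <= pos < e.end for e in g.exons)):
                    return "intron"
    return "intergenic"


@pytest.fixture
def toy_genes():
    # plus-strand gene with 2 exons, minus-strand gene downstream, plus a
    # gene whose promoter window covers an exon of its neighbour
    return [
        make_gene("gA", "t", 3000, [(3000, 3500), (5000, 6000)], "+"),
        make_gene("gB", "t", 9000, [(9000, 9400), (11000, 12000)], "-"),
        make_gene("gC", "t", 13000, [(13000, 13200), (14000, 15000)], "+"),
    ]


class TestFeatureMap:
    def test_no_genes_all_intergenic(self):
        fmap = build_feature_map([], (2000, 500))
        assert fmap.label("anything", 12345) == "intergenic"

    def test_two_exon_gene_labels(self, toy_genes):
        fmap = build_feature_map(toy_genes[:1], (2000, 500))
        assert fmap.label("t", 5500) == "exon"       # inside exon 2
        assert fmap.label("t", 4000) == "intron"     # between exons
        assert fmap.label("t", 2000) == "promoter"   # 1 kb upstream of TSS
        assert fmap.label("t", 8000) == "intergenic"

    def test_promoter_priority_over_neighbour_exon(self):
        # gD's promoter window reaches into gE's exon: promoter wins
        gd = make_gene("gD", "t", 5000, [(5000, 5100), (5900, 6000)], "+")
        ge = make_gene("gE", "t", 3500, [(3500, 4500)], "+")
        fmap = build_feature_map([gd, ge], (2000, 500))
        assert brute_force_label([gd, ge], (2000, 500), "t", 4000) == "promoter"
        assert fmap.label("t", 4000) == "promoter"

    def test_matches_brute_force_on_toy_genome(self, toy_genes):
        fmap = build_feature_map(toy_genes, (2000, 500))
        rng = np.random.default_rng(0)
        for pos in rng.integers(0, 20000, size=2000):
            assert fmap.label("t", int(pos)) == brute_force_label(
                toy_genes, (2000, 500), "t", int(pos)
            ), f"mismatch at {pos}"

    def test_strand_symmetry(self, toy_genes):
        """Mirroring coordinates and flipping strands mirrors the labels."""
        L = 20000
        mirrored = []
        for g in toy_genes:
            strand = "-" if g.strand == "+" else "+"
            exons = tuple(
                GenomicInterval("t", L - e.end, L - e.start, strand)
                for e in reversed(g.exons)
            )
            mirrored.append(GeneModel(
                gene_id=g.gene_id,
                interval=GenomicInterval(
                    "t", L - g.interval.end, L - g.interval.start, strand
                ),
                strand=strand, exons=exons,
            ))
        fwd = build_feature_map(toy_genes, (2000, 500))
        rev = build_feature_map(mirrored, (2000, 500))
        rng = np.random.default_rng(1)
        for pos in rng.integers(0, L, size=500):
            assert fwd.label("t", int(pos)) == rev.label("t", int(L - 1 - pos))

    def test_unknown_chromosome_with_namespace_raises(self, toy_genes):
        fmap = build_feature_map(toy_genes, (2000, 500), chromosomes=["t"])
        with pytest.raises(KeyError):
            fmap.label("chrUn", 100)


def peak_at(chrom, summit, halfwidth=50, **kw):
    return Peak(
        interval=GenomicInterval(chrom, summit - halfwidth, summit + halfwidth),
        score=1.0, summit=summit, **kw,
    )


class TestAnnotatePeak:
    def test_summit_rule(self, toy_genes):
        fmap = build_feature_map(toy_genes, (2000, 500))
        # peak spans the exon2/intron boundary but summits in the intron
        p = Peak(GenomicInterval("t", 4900, 5200), score=1.0, summit=4950)
        assert annotate_peak(p, fmap) == "intron"
        assert annotate_peak(peak_at("t", 8000), fmap) == "intergenic"

    def test_multiset_matches_oracle(self, toy_genes):
        fmap = build_feature_map(toy_genes, (2000, 500))
        rng = np.random.default_rng(2)
        summits = rng.integers(100, 19900, size=10)
        got = [annotate_peak(peak_at("t", int(s)), fmap) for s in summits]
        expect = [brute_force_label(toy_genes, (2000, 500), "t", int(s))
                  for s in summits]
        assert got == expect


class TestTargetAssignment:
    def test_peak_inside_gene(self, toy_genes):
        gene, dist = assign_target_gene(peak_at("t", 5500), toy_genes)
        assert (gene, dist) == ("gA", 0)

    def test_beyond_cutoff_is_none(self):
        genes = [make_gene("g", "t", 50000, [(50000, 51000)])]
        p = peak_at("t", 37500, halfwidth=500)  # gap 12,000 bp
        assert assign_target_gene(p, genes) == (None, None)

    def test_equidistant_tie_smaller_start_wins(self):
        genes = [
            make_gene("gRight", "t", 11000, [(11000, 12000)]),
            make_gene("gLeft", "t", 2000, [(2000, 3000)]),
        ]
        p = peak_at("t", 7000, halfwidth=1000)  # 3,000 bp from both spans
        # exhaustive check of the distances
        assert p.interval.distance_to(genes[0].interval) == 3000
        assert p.interval.distance_to(genes[1].interval) == 3000
        gene, dist = assign_target_gene(p, genes)
        assert (gene, dist) == ("gLeft", 3000)

    def test_order_invariance(self, toy_genes):
        rng = np.random.default_rng(3)
        p = peak_at("t", 7500, halfwidth=200)
        results = set()
        for _ in range(5):
            order = rng.permutation(len(toy_genes))
            results.add(assign_target_gene(p, [toy_genes[i] for i in order]))
        assert len(results) == 1

    def test_matches_exhaustive_scan(self, toy_genes):
        rng = np.random.default_rng(4)
        for s in rng.integers(500, 19500, size=50):
            p = peak_at("t", int(s), halfwidth=100)
            best = min(
                ((p.interval.distance_to(g.interval), g.interval.start, g.gene_id)
                 for g in toy_genes),
            )
            expect = (best[2], best[0]) if best[0] <= 10000 else (None, None)
            assert assign_target_gene(p, toy_genes) == expect


class TestDistribution:
    def test_counting(self):
        ann = (
            [AnnotatedPeak(peak_at("t", 100), "intergenic")] * 5
            + [AnnotatedPeak(peak_at("t", 100), "intron")] * 4
            + [AnnotatedPeak(peak_at("t", 100), "promoter")]
        )
        dist = genomic_distribution(ann)
        assert dist == {"promoter": 0.1, "exon": 0.0, "intron": 0.4,
                        "intergenic": 0.5}

    def test_single_category(self):
        ann = [AnnotatedPeak(peak_at("t", 100), "exon")] * 3
        assert genomic_distribution(ann)["exon"] == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            genomic_distribution([])

    def test_fractions_sum_to_one(self, toy_genes):
        fmap = build_feature_map(toy_genes, (2000, 500))
        rng = np.random.default_rng(5)
        peaks = [peak_at("t", int(s)) for s in rng.integers(100, 19900, 200)]
        ann = annotate_peaks(peaks, fmap, toy_genes)
        dist = genomic_distribution(ann)
        assert abs(sum(dist.values()) - 1.0) < 1e-12
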