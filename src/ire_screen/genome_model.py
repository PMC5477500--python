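"""Gene models, genomic feature partitioning and peak annotation.

Every base of the genome receives exactly one feature label out of
{promoter, exon, intron, intergenic}, resolved across overlapping genes with
the priority promoter > exon > intron > intergenic.  Peaks are categorised by
the label at their summit and assigned a target gene (nearest gene within a
distance cutoff, default 10 kb).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GenomicInterval
from .peaks import Peak

__all__ = [
    "GeneModel",
    "FeatureMap",
    "AnnotatedPeak",
    "build_feature_map",
    "annotate_peak",
    "annotate_peaks",
    "assign_target_gene",
    "genomic_distribution",
    "FEATURE_PRIORITY",
]

FEATURE_PRIORITY = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """One gene's merged transcript structure.

    ``exons`` are disjoint, sorted and contained in the gene span; introns are
    the complement of the exons within the span.  The TSS is the 5' end of the
    span by strand (``start`` on +, ``end - 1`` on -).
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = self.interval.start - 1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if ex.start <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end - 1

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gene span minus exons."""
        out = []
        cursor = self.interval.start
        for ex in self.exons:
            if ex.start > cursor:
                out.append(GenomicInterval(
                    self.interval.chrom, cursor, ex.start, self.strand
                ))
            cursor = ex.end
        if cursor < self.interval.end:
            out.append(GenomicInterval(
                self.interval.chrom, cursor, self.interval.end, self.strand
            ))
        return tuple(out)

    def promoter(self, upstream: int, downstream: int) -> GenomicInterval | None:
        """Promoter window around the TSS, oriented by strand and clipped at 0."""
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream + 1, self.tss + upstream + 1
        start = max(0, start)
        if end <= start:
            return None
        return GenomicInterval(self.interval.chrom, start, end, self.strand)


class FeatureMap:
    """Position -> feature label lookup built from a gene set.

    When ``chromosomes`` is supplied, queries on unknown chromosomes raise;
    otherwise any chromosome is accepted and unannotated positions are
    intergenic.
    """

    def __init__(
        self,
        promoter_window: tuple[int, int],
        chromosomes: Iterable[str] | None = None,
    ):
        self.promoter_window = promoter_window
        self.chromosomes = None if chromosomes is None else frozenset(chromosomes)
        self._trees: dict[str, dict[str, IntervalTree]] = {
            label: {} for label in ("promoter", "exon", "intron")
        }

    def _add(self, label: str, iv: GenomicInterval) -> None:
        self._trees[label].setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def label(self, chrom: str, position: int) -> str:
        if self.chromosomes is not None and chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        for feature in ("promoter", "exon", "intron"):
            tree = self._trees[feature].get(chrom)
            if tree is not None and tree.overlaps_point(position):
                return feature
        return "intergenic"


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak with its feature category and (optional) target gene."""

    peak: Peak
    category: str
    target_gene: str | None = None
    target_distance: int | None = None


def build_feature_map(
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (2000, 500),
    chromosomes: Iterable[str] | None = None,
) -> FeatureMap:
    """Label the genome as promoter/exon/intron/intergenic.

    ``promoter_window`` is (upstream_bp, downstream_bp) relative to the TSS,
    oriented by strand.  With no genes every position is intergenic.
    """
    up, down = promoter_window
    if up < 0 or down < 0:
        raise ValueError("promoter window components must be >= 0")
    fmap = FeatureMap(promoter_window, chromosomes=chromosomes)
    for g in genes:
        prom = g.promoter(up, down)
        if prom is not None:
            fmap._add("promoter", prom)
        for ex in g.exons:
            fmap._add("exon", ex)
        for intr in g.introns:
            fmap._add("intron", intr)
    return fmap


def annotate_peak(peak: Peak, fmap: FeatureMap) -> str:
    """Feature category of a peak = label at its summit (single-point rule)."""
    return fmap.label(peak.interval.chrom, peak.effective_summit)


def assign_target_gene(
    peak: Peak, genes: Sequence[GeneModel], max_dist: int = 10000
) -> tuple[str | None, int | None]:
    """Nearest gene within ``max_dist`` bp of the peak, with its distance.

    Distance is measured between the peak interval and the gene span
    (0 when they overlap).  Ties are broken by smaller gene start, then
    lexicographic gene id; result is independent of gene ordering.
    """
    best: tuple[int, int, str] | None = None
    for g in genes:
        if g.interval.chrom != peak.interval.chrom:
            continue
        d = peak.interval.distance_to(g.interval)
        key = (d, g.interval.start, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None or best[0] > max_dist:
        return None, None
    return best[2], best[0]


def annotate_peaks(
    peaks: Sequence[Peak],
    fmap: FeatureMap,
    genes: Sequence[GeneModel] = (),
    max_dist: int = 10000,
) -> list[AnnotatedPeak]:
    """Categorise peaks by summit feature and assign target genes."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    out = []
    for p in peaks:
        category = annotate_peak(p, fmap)
        gene_id, dist = assign_target_gene(
            p, by_chrom.get(p.interval.chrom, ()), max_dist=max_dist
        )
        out.append(AnnotatedPeak(p, category, gene_id, dist))
    return out


def genomic_distribution(annotated: Sequence[AnnotatedPeak]) -> dict[str, float]:
    """Fraction of peaks per feature category (all four categories reported)."""
    if not annotated:
        raise ValueError("cannot compute a distribution over zero peaks")
    counts = Counter(a.category for a in annotated)
    n = len(annotated)
    return {label: counts.get(label, 0) / n for label in FEATURE_PRIORITY}
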