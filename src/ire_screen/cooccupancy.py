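"""Co-occupancy of a peak set with histone-mark peak sets and turnover strata.

Overlap is interval intersection on the full peak intervals (>= 1 bp by
default).  Marks are ranked by the fraction of query peaks they cover, and
mark occupancy can be compared between peaks inside and outside
high-nucleosome-turnover regions with a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import CoverageTrack, GenomicInterval
from .peaks import Peak, summit_window
from .profiles import binned_rpkm

__all__ = [
    "PeakSetOverlap",
    "StratumComparison",
    "overlap_fraction",
    "rank_marks",
    "stratify_by_turnover",
    "mark_occupancy_by_stratum",
]


@dataclass(frozen=True)
class PeakSetOverlap:
    """Fraction of query peaks overlapping at least one subject peak."""

    mark_name: str
    fraction: float
    n_query: int
    n_overlapping: int


def _build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _intervals_of(items) -> list[GenomicInterval]:
    return [p.interval if isinstance(p, Peak) else p for p in items]


def _overlaps_any(
    iv: GenomicInterval, trees: Mapping[str, IntervalTree], min_overlap: int
) -> bool:
    tree = trees.get(iv.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(iv.start, iv.end):
        if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
            return True
    return False


def overlap_fraction(
    query: Sequence[Peak],
    subject,
    mark_name: str = "",
    min_overlap: int = 1,
) -> PeakSetOverlap:
    """Proportion of ``query`` peaks sharing >= ``min_overlap`` bp with
    any ``subject`` peak or interval."""
    if not query:
        raise ValueError("overlap fraction undefined for an empty query set")
    trees = _build_trees(_intervals_of(subject))
    n_hit = sum(
        _overlaps_any(p.interval, trees, min_overlap) for p in query
    )
    return PeakSetOverlap(mark_name, n_hit / len(query), len(query), n_hit)


def rank_marks(
    query: Sequence[Peak],
    marks: Mapping[str, Sequence],
    min_overlap: int = 1,
) -> list[PeakSetOverlap]:
    """Overlap fractions against each named mark set, best first.

    Order is deterministic: fraction descending, then mark name ascending.
    """
    results = [
        overlap_fraction(query, peaks, mark_name=name, min_overlap=min_overlap)
        for name, peaks in marks.items()
    ]
    results.sort(key=lambda r: (-r.fraction, r.mark_name))
    return results


def stratify_by_turnover(
    peaks: Sequence[Peak],
    turnover_regions: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> tuple[list[Peak], list[Peak]]:
    """Partition peaks into (high, low) turnover strata by region overlap."""
    trees = _build_trees(list(turnover_regions))
    high, low = [], []
    for p in peaks:
        (high if _overlaps_any(p.interval, trees, min_overlap) else low).append(p)
    return high, low


@dataclass(frozen=True)
class StratumComparison:
    """Windowed mark occupancy per stratum plus a rank-sum comparison.

    The statistic is descriptive: a two-sample Mann-Whitney U on the
    per-peak mean RPKM values (``alternative`` as configured).
    """

    mark_name: str
    high_values: np.ndarray
    low_values: np.ndarray
    statistic: float
    pvalue: float


def mark_occupancy_by_stratum(
    high: Sequence[Peak],
    low: Sequence[Peak],
    mark_tracks: Mapping[str, CoverageTrack],
    flank: int = 1000,
    alternative: str = "two-sided",
) -> dict[str, StratumComparison]:
    """Mean windowed RPKM of each mark around summits, per turnover stratum.

    For every peak the mark coverage is averaged over the +/- ``flank``
    window around the summit (a single whole-window bin) and the two
    per-stratum value sets are compared with a rank-sum test.
    """
    if not high or not low:
        raise ValueError("both turnover strata must be nonempty")
    out = {}
    for name, track in mark_tracks.items():
        vals = {}
        for label, stratum in (("high", high), ("low", low)):
            windows = [summit_window(p, flank) for p in stratum]
            v = np.array([
                binned_rpkm(track, w, w.length)[0] for w in windows
            ])
            vals[label] = v
        stat, p = stats.mannwhitneyu(
            vals["high"], vals["low"], alternative=alternative
        )
        out[name] = StratumComparison(name, vals["high"], vals["low"],
                                      float(stat), float(p))
    return out
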