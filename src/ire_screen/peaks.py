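"""Peak records plus the ranking, stringency and windowing rules of the screen.

A called peak carries its caller score, its summit (point of maximal
enrichment) and a ChIP/input enrichment ratio.  The screen works with two
nested peak sets: the top-N peaks by score (low stringency) and the subset
whose log2 ChIP/input ratio clears a threshold (high stringency, default
ratio >= 16).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_formats import GenomicInterval

__all__ = ["Peak", "select_top_peaks", "filter_high_stringency", "summit_window"]


@dataclass(frozen=True)
class Peak:
    """A called enrichment region.

    ``summit`` is the 0-based position of maximal signal, or ``None`` when
    the caller reported none; ``effective_summit`` falls back to the integer
    midpoint in that case.  ``enrichment`` is the ChIP/input ratio (> 0).
    """

    interval: GenomicInterval
    score: float
    summit: int | None = None
    enrichment: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.enrichment is not None and self.enrichment <= 0:
            raise ValueError(f"nonpositive enrichment {self.enrichment}")

    @property
    def effective_summit(self) -> int:
        """Summit position, or the peak-centre fallback floor((start+end)/2)."""
        if self.summit is not None:
            return self.summit
        return (self.interval.start + self.interval.end) // 2


def select_top_peaks(peaks, n: int = 3000) -> list[Peak]:
    """The ``n`` highest-score peaks (all of them if fewer exist).

    Boundary ties are broken deterministically by (chrom, start, name).
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    for p in peaks:
        if not math.isfinite(p.score):
            raise ValueError(f"non-finite score on peak {p.name!r}")
    ranked = sorted(
        peaks, key=lambda p: (-p.score, p.interval.chrom, p.interval.start, p.name)
    )
    return ranked[:n]


def filter_high_stringency(peaks, log2_threshold: float = 4.0) -> list[Peak]:
    """Peaks whose log2(ChIP/input ratio) is >= ``log2_threshold``.

    The default threshold 4 keeps peaks with an enrichment ratio of 16 or
    more (the boundary value is retained).  Peaks must carry a positive
    enrichment ratio.
    """
    out = []
    for p in peaks:
        if p.enrichment is None or p.enrichment <= 0:
            raise ValueError(f"peak {p.name!r} lacks a positive enrichment ratio")
        if math.log2(p.enrichment) >= log2_threshold:
            out.append(p)
    return out


def summit_window(peak: Peak, flank: int) -> GenomicInterval:
    """The interval ``[summit - flank, summit + flank)`` clipped at position 0.

    Used as the reference window for occupancy profiles; peaks without a
    called summit are windowed around their midpoint.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    s = peak.effective_summit
    return GenomicInterval(
        peak.interval.chrom, max(0, s - flank), s + flank, peak.interval.strand
    )
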