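"""Readers, writers and coordinate conventions for the standard genomic formats.

All coordinates are held internally as 0-based half-open intervals, the native
convention of BED/narrowPeak/bedGraph.  GTF records and printed UCSC-style
region strings (1-based closed) are converted on parse and converted back on
write, so off-by-one arithmetic lives in exactly one module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "parse_region_string",
    "format_region",
    "read_gene_models",
    "write_gtf",
    "read_peaks",
    "write_narrowpeak",
    "read_bed",
    "write_bed",
    "read_coverage",
    "write_bedgraph",
    "read_table",
    "write_tsv",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between closest boundaries; 0 when the intervals overlap
        or abut.  Raises on different chromosomes."""
        if self.chrom != other.chrom:
            raise ValueError(f"intervals on different chromosomes "
                             f"({self.chrom} vs {other.chrom})")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a UCSC-style region string such as ``chr3:151,022,847-151,023,000``.

    Printed coordinates are 1-based closed; the returned interval is 0-based
    half-open, so its ``length`` equals ``printed_end - printed_start + 1``.
    Thousands separators are accepted and stripped.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed region string: {text!r}")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 < 1:
        raise ValueError(f"1-based start must be >= 1 in {text!r}")
    if start1 > end1:
        raise ValueError(f"start {start1} exceeds end {end1} in {text!r}")
    return GenomicInterval(m.group("chrom"), start1 - 1, end1)


def format_region(interval: GenomicInterval, thousands: bool = True) -> str:
    """Inverse of :func:`parse_region_string` (1-based closed, with commas)."""
    fmt = "{:,d}" if thousands else "{:d}"
    return (
        f"{interval.chrom}:{fmt.format(interval.start + 1)}"
        f"-{fmt.format(interval.end)}"
    )


class CoverageTrack:
    """Per-base read coverage over a genome, queryable by interval.

    Stored as sorted non-overlapping constant-value runs per chromosome; the
    sum of per-bp values over any interval is an O(log n) prefix-sum query.
    ``total_reads`` defaults to the genome-wide per-bp sum and is the library
    size used for RPKM normalisation.
    """

    def __init__(
        self,
        intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_reads: float | None = None,
    ):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        total = 0.0
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(values < 0):
                raise ValueError(f"negative coverage value on {chrom}")
            if np.any(ends <= starts):
                raise ValueError(f"empty coverage interval on {chrom}")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage intervals on {chrom}")
            mass = values * (ends - starts)
            cum = np.concatenate([[0.0], np.cumsum(mass)])
            self._chroms[chrom] = (starts, ends, values, cum)
            total += float(mass.sum())
        self.total_reads = float(total if total_reads is None else total_reads)

    @classmethod
    def from_array(
        cls, chrom: str, coverage: np.ndarray, total_reads: float | None = None
    ) -> "CoverageTrack":
        """Run-length encode a dense per-bp coverage array for one chromosome."""
        coverage = np.asarray(coverage)
        if coverage.size == 0:
            return cls({chrom: (np.array([]), np.array([]), np.array([]))},
                       total_reads=total_reads)
        change = np.flatnonzero(np.diff(coverage)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [coverage.size]])
        values = coverage[starts].astype(np.float64)
        keep = values != 0
        return cls(
            {chrom: (starts[keep], ends[keep], values[keep])},
            total_reads=total_reads,
        )

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._chroms))

    def _prefix(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Per-bp coverage summed over ``[0, pos)`` for each position."""
        if chrom not in self._chroms:
            return np.zeros(len(positions), dtype=float)
        starts, ends, values, cum = self._chroms[chrom]
        if len(starts) == 0:
            return np.zeros(len(positions), dtype=float)
        k = np.searchsorted(ends, positions, side="left")
        out = cum[k]
        partial = k < len(starts)
        idx = np.where(partial, k, 0)
        overlap = np.clip(positions - starts[idx], 0, None)
        out = out + np.where(partial, values[idx] * overlap, 0.0)
        return out

    def query(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-bp coverage over ``[start, end)``."""
        if end <= start:
            raise ValueError("empty query interval")
        lo, hi = self._prefix(chrom, np.array([max(start, 0), max(end, 0)]))
        return float(hi - lo)

    def query_interval(self, interval: GenomicInterval) -> float:
        return self.query(interval.chrom, interval.start, interval.end)

    def binned_counts(
        self, chrom: str, start: int, end: int, bin_size: int
    ) -> np.ndarray:
        """Per-bin coverage sums over contiguous ``bin_size`` bins in [start, end)."""
        if (end - start) % bin_size != 0:
            raise ValueError("bin_size must divide the window length")
        edges = np.arange(start, end + bin_size, bin_size)
        prefix = self._prefix(chrom, np.clip(edges, 0, None))
        return np.diff(prefix)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self._chroms):
            starts, ends, values, _ = self._chroms[chrom]
            rows.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": values}
            ))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end", "value"])
        return pd.concat(rows, ignore_index=True)


def read_coverage(path: str | Path, total_reads: float | None = None) -> CoverageTrack:
    """Read a bedGraph file into a :class:`CoverageTrack`.

    Intervals must be non-overlapping per chromosome and values non-negative;
    violations raise ``ValueError``.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if len(df) and (df["value"] < 0).any():
        bad = df.index[df["value"] < 0][0]
        raise ValueError(f"negative coverage value at record {bad} in {path}")
    grouped = {
        chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
        for chrom, g in df.groupby("chrom", sort=True)
    }
    return CoverageTrack(grouped, total_reads=total_reads)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    df = track.to_frame()
    # integral values are written as integers so integer tracks round-trip exactly
    if len(df) and np.allclose(df["value"], np.round(df["value"])):
        df["value"] = df["value"].astype(np.int64)
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gene_models(path: str | Path):
    """Parse a GTF file into :class:`~ire_screen.genome_model.GeneModel` objects.

    Exons are merged per ``gene_id`` across transcripts; GTF 1-based closed
    coordinates are converted to the internal convention.  Genes are returned
    sorted by (chrom, start, gene_id).  Malformed records raise ``ValueError``
    naming the offending line number.
    """
    from .genome_model import GeneModel  # local import avoids a cycle

    gene_spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"line {lineno}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            start1, end1 = int(start1), int(end1)
            if start1 > end1:
                raise ValueError(f"line {lineno}: start {start1} > end {end1}")
            if strand not in ("+", "-"):
                raise ValueError(f"line {lineno}: unknown strand {strand!r}")
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if not gene_id:
                raise ValueError(f"line {lineno}: missing gene_id attribute")
            iv = (chrom, strand, start1 - 1, end1)
            if feature == "gene":
                gene_spans[gene_id] = GenomicInterval(chrom, start1 - 1, end1, strand)
            else:
                exons.setdefault(gene_id, []).append(iv)

    models = []
    for gene_id, ex in exons.items():
        chroms = {e[0] for e in ex}
        strands = {e[1] for e in ex}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gene_id}: exons on multiple chromosomes/strands")
        chrom, strand = ex[0][0], ex[0][1]
        merged = _merge_intervals([(e[2], e[3]) for e in ex])
        span = gene_spans.get(gene_id)
        if span is None:
            span = GenomicInterval(chrom, merged[0][0], merged[-1][1], strand)
        else:
            if merged[0][0] < span.start or merged[-1][1] > span.end:
                raise ValueError(f"gene {gene_id}: exon outside declared gene span")
        models.append(GeneModel(
            gene_id=gene_id,
            interval=span,
            strand=strand,
            exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged),
        ))
    for gene_id, span in gene_spans.items():
        if gene_id not in exons:
            models.append(GeneModel(
                gene_id=gene_id, interval=span, strand=span.strand,
                exons=(GenomicInterval(span.chrom, span.start, span.end, span.strand),),
            ))
    models.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return models


def _merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def write_gtf(genes, path: str | Path) -> None:
    """Write gene models as GTF (gene + exon features, 1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            fh.write("\t".join([
                g.interval.chrom, "ire_screen", "gene",
                str(g.interval.start + 1), str(g.interval.end),
                ".", g.strand, ".", attrs,
            ]) + "\n")
            for ex in g.exons:
                fh.write("\t".join([
                    ex.chrom, "ire_screen", "exon",
                    str(ex.start + 1), str(ex.end),
                    ".", g.strand, ".", attrs,
                ]) + "\n")


# ---------------------------------------------------------------------------
# Peaks (BED / narrowPeak)
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path):
    """Read a narrowPeak (BED6+4) or plain BED file into ``Peak`` objects.

    narrowPeak column 10 is the summit offset from ``start``; an offset of
    -1 means "no summit called".  Peaks are returned sorted by (chrom, start).
    """
    from .peaks import Peak  # local import avoids a cycle

    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 and f[3] != "." else f"peak_{lineno}"
            try:
                score = float(f[4]) if len(f) > 4 else 0.0
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric score {f[4]!r}")
            strand = f[5] if len(f) > 5 and f[5] in STRANDS else "."
            enrichment = None
            summit = None
            if len(f) >= 10:  # narrowPeak
                signal = float(f[6])
                enrichment = signal if signal > 0 else None
                offset = int(f[9])
                if offset >= end - start:
                    raise ValueError(
                        f"line {lineno}: summit offset {offset} >= peak length"
                    )
                summit = start + offset if offset >= 0 else None
            peaks.append(Peak(
                interval=GenomicInterval(chrom, start, end, strand),
                score=score, summit=summit, enrichment=enrichment, name=name,
            ))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.name))
    return peaks


def write_narrowpeak(peaks, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            offset = -1 if p.summit is None else p.summit - p.interval.start
            enr = 0 if p.enrichment is None else f"{p.enrichment:g}"
            fh.write("\t".join([
                p.interval.chrom, str(p.interval.start), str(p.interval.end),
                p.name, f"{p.score:g}", p.interval.strand,
                str(enr), "-1", "-1", str(offset),
            ]) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED columns")
            strand = f[5] if len(f) > 5 and f[5] in STRANDS else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end),
                f"region_{i}", "0", iv.strand,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    """Read a TSV table with a header row (expression or clinical data)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
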