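"""Summit-centred occupancy profiles.

The central object is a peaks x bins matrix of RPKM (reads per kilobase per
million mapped reads) computed over fixed-width bins spanning a symmetric
window around each peak summit.  Rows can be sorted or grouped by the
expression of the peak's target gene, and per-group average profiles can be
smoothed with a locally weighted linear regression (lowess, tricube kernel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GenomicInterval
from .peaks import Peak, summit_window

__all__ = [
    "ProfileMatrix",
    "binned_rpkm",
    "profile_matrix",
    "sort_rows_by_expression",
    "expression_groups",
    "group_average_profile",
    "lowess_smooth",
]


def binned_rpkm(
    track: CoverageTrack, window: GenomicInterval, bin_size: int
) -> np.ndarray:
    """RPKM per bin over ``window`` split into contiguous ``bin_size`` bins.

    RPKM = (coverage sum in bin) / (bin length in kb) / (library size in
    millions of reads).  ``bin_size`` must divide the window length.
    """
    if bin_size <= 0 or window.length % bin_size != 0:
        raise ValueError(
            f"bin_size {bin_size} must divide window length {window.length}"
        )
    if track.total_reads <= 0:
        raise ValueError("library size (total_reads) must be positive")
    counts = track.binned_counts(window.chrom, window.start, window.end, bin_size)
    return counts / (bin_size / 1000.0) / (track.total_reads / 1e6)


@dataclass(frozen=True)
class ProfileMatrix:
    """RPKM of peaks x bins around summits, with per-row metadata.

    ``values`` has shape (n_peaks, 2*flank/bin_size); ``valid`` masks bins
    that fall off the chromosome start for clipped windows.  ``row_meta``
    carries peak name, target gene, expression value and expression group,
    aligned with the rows.
    """

    values: np.ndarray
    valid: np.ndarray
    flank: int
    bin_size: int
    row_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")
        if self.values.shape[0] != len(self.row_meta):
            raise ValueError("row metadata does not align with matrix rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin centre offsets relative to the summit."""
        edges = np.arange(-self.flank, self.flank + self.bin_size, self.bin_size)
        return (edges[:-1] + edges[1:]) / 2.0

    def row_means(self) -> np.ndarray:
        """Mean RPKM per row over valid bins."""
        with np.errstate(invalid="ignore"):
            sums = np.where(self.valid, self.values, 0.0).sum(axis=1)
            counts = self.valid.sum(axis=1)
        return sums / np.maximum(counts, 1)

    def take(self, order: np.ndarray) -> "ProfileMatrix":
        return replace(
            self,
            values=self.values[order],
            valid=self.valid[order],
            row_meta=self.row_meta.iloc[order].reset_index(drop=True),
        )


def profile_matrix(
    peaks: Sequence[Peak],
    track: CoverageTrack,
    flank: int = 2000,
    bin_size: int = 20,
    target_genes: Sequence[str | None] | None = None,
    expression: Mapping[str, float] | None = None,
) -> ProfileMatrix:
    """Build the summit-centred RPKM matrix, one row per peak in input order.

    Windows extending past position 0 are kept, with the out-of-genome bins
    masked rather than dropped.  ``target_genes`` (aligned with ``peaks``)
    and ``expression`` (per gene) populate the row metadata when given.
    """
    if flank <= 0 or flank % bin_size != 0:
        raise ValueError("flank must be a positive multiple of bin_size")
    n_bins = 2 * flank // bin_size
    values = np.zeros((len(peaks), n_bins))
    valid = np.ones((len(peaks), n_bins), dtype=bool)
    for i, p in enumerate(peaks):
        s = p.effective_summit
        start, end = s - flank, s + flank
        # bins aligned to the unclipped window; those reaching below 0 are masked
        edges = np.arange(start, end + bin_size, bin_size)
        mask = edges[:-1] >= 0
        window = GenomicInterval(p.interval.chrom, max(0, start), end)
        if start >= 0:
            values[i] = binned_rpkm(track, window, bin_size)
        else:
            counts = track.binned_counts(p.interval.chrom, start, end, bin_size)
            rpkm = counts / (bin_size / 1000.0) / (track.total_reads / 1e6)
            values[i] = np.where(mask, rpkm, 0.0)
        valid[i] = mask
    meta = pd.DataFrame({
        "peak": [p.name for p in peaks],
        "target_gene": list(target_genes) if target_genes is not None
        else [None] * len(peaks),
    })
    if expression is not None:
        meta["expression"] = [
            expression.get(g, np.nan) if g is not None else np.nan
            for g in meta["target_gene"]
        ]
    else:
        meta["expression"] = np.nan
    return ProfileMatrix(values, valid, flank, bin_size, meta)


def sort_rows_by_expression(
    matrix: ProfileMatrix, expression: Mapping[str, float] | None = None
) -> tuple[ProfileMatrix, int]:
    """Rows sorted by descending target-gene expression.

    Rows without a target gene or without an expression value are dropped;
    the number dropped is returned alongside the sorted matrix.  Ties are
    broken by gene id for determinism.
    """
    meta = matrix.row_meta.copy()
    if expression is not None:
        meta["expression"] = [
            expression.get(g, np.nan) if g is not None else np.nan
            for g in meta["target_gene"]
        ]
    keep = meta["expression"].notna() & meta["target_gene"].notna()
    dropped = int((~keep).sum())
    kept = np.flatnonzero(keep.to_numpy())
    sub = matrix.take(kept)
    if expression is not None:
        sub = replace(sub, row_meta=meta.loc[keep].reset_index(drop=True))
    order = sub.row_meta.sort_values(
        ["expression", "target_gene"], ascending=[False, True], kind="stable"
    ).index.to_numpy()
    return sub.take(order), dropped


def expression_groups(values: Sequence[float]) -> np.ndarray:
    """Equal-count tertile labels {high, intermediate, low} by rank.

    Group sizes differ by at most one (the low group absorbs the first
    remainder, then the intermediate group); ties are resolved by stable
    rank, so equal values keep their input order.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values to form tertiles")
    order = np.argsort(values, kind="stable")  # ascending, stable in ties
    labels = np.empty(len(values), dtype=object)
    thirds = np.array_split(order, 3)
    for chunk, name in zip(thirds, ("low", "intermediate", "high")):
        labels[chunk] = name
    return labels


def group_average_profile(
    matrix: ProfileMatrix, labels: Sequence[str]
) -> dict[str, np.ndarray]:
    """Per-group arithmetic mean per bin, excluding masked bins.

    Raises if any named group is empty; bins with no valid row in a group
    come out as NaN.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != matrix.n_rows:
        raise ValueError("labels do not align with matrix rows")
    out = {}
    for name in pd.unique(labels):
        rows = labels == name
        if not rows.any():
            raise ValueError(f"group {name!r} is empty")
        vals = np.where(matrix.valid[rows], matrix.values[rows], 0.0)
        counts = matrix.valid[rows].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = vals.sum(axis=0) / counts
    return out


def lowess_smooth(y: Sequence[float], f: float = 0.3) -> np.ndarray:
    """Locally weighted linear regression over the index axis.

    At each index the span is the ceil(f*n) nearest points, weighted by the
    tricube kernel on distance scaled by the span radius; a single weighted
    least-squares line is fitted (no robustness iterations).  A constant
    input is reproduced exactly, as is a linear input at f = 1.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 points to smooth")
    if not (0 < f <= 1):
        raise ValueError(f"smoothing fraction must be in (0, 1], got {f}")
    k = min(n, max(2, math.ceil(f * n)))
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            out[i] = y[i]
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0:
            out[i] = ym
        else:
            b = (w * (x - xm) * (y - ym)).sum() / sxx
            out[i] = ym + b * (x[i] - xm)
    return out
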