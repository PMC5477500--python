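"""Differential-expression selection and ChIP x DEG target nomination.

A gene is differentially expressed when it changes more than a fold
threshold in at least one of the overexpression / knockdown contrasts AND
responds in opposite directions in the two contrasts (up on overexpression
and down on knockdown -> positively regulated; the reverse -> negatively
regulated).  DEGs are intersected with genes whose introns carry
(mark-co-occupied) ChIP peaks to nominate direct targets, at a low-stringency
(top-N peaks, top-N probes) and a high-stringency (enrichment-filtered
peaks, thresholded DEGs) level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cooccupancy import _build_trees, _intervals_of, _overlaps_any
from .genome_model import (
    AnnotatedPeak,
    GeneModel,
    annotate_peaks,
    build_feature_map,
    genomic_distribution,
)
from .peaks import Peak, filter_high_stringency, select_top_peaks

__all__ = [
    "DegResult",
    "select_degs",
    "rank_degs",
    "genes_with_cooccupied_introns",
    "nominate_targets",
    "ScreenResult",
    "run_screen",
]

REQUIRED_COLUMNS = ("control", "overexpression", "knockdown")


def _fold_changes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fold changes for the two contrasts.

    ``oe_fold`` = overexpression / control; ``kd_fold`` = knockdown divided
    by its own control column when present, else by the shared control.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"expression table lacks required column {col!r}")
    if not table.index.is_unique:
        raise ValueError("expression table row ids must be unique")
    numeric = table[[c for c in table.columns if c != "gene"]]
    if (numeric <= 0).any().any():
        raise ValueError("expression intensities must be positive")
    kd_control = (
        table["knockdown_control"]
        if "knockdown_control" in table.columns
        else table["control"]
    )
    return pd.DataFrame({
        "oe_fold": table["overexpression"] / table["control"],
        "kd_fold": table["knockdown"] / kd_control,
    })


@dataclass(frozen=True)
class DegResult:
    """Opposite-direction differentially expressed genes.

    ``positive``: up on overexpression and down on knockdown;
    ``negative``: the reverse.  The two sets are disjoint by construction.
    """

    positive: tuple[str, ...]
    negative: tuple[str, ...]
    fold_changes: pd.DataFrame

    @property
    def all_degs(self) -> frozenset[str]:
        return frozenset(self.positive) | frozenset(self.negative)


def select_degs(
    table: pd.DataFrame,
    fold_threshold: float = 2.0,
    require_both: bool = False,
) -> DegResult:
    """Opposite-direction DEGs at a fold-change threshold.

    The fold threshold must be cleared in at least one contrast (both when
    ``require_both``); opposite directionality is always required in both
    contrasts.  No significance filter is applied.
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold threshold must exceed 1, got {fold_threshold}")
    fc = _fold_changes(table)
    oe, kd = fc["oe_fold"], fc["kd_fold"]
    combine = np.logical_and if require_both else np.logical_or
    pos = combine(oe > fold_threshold, 1 / kd > fold_threshold) & (oe > 1) & (kd < 1)
    neg = combine(1 / oe > fold_threshold, kd > fold_threshold) & (oe < 1) & (kd > 1)
    return DegResult(
        positive=tuple(sorted(fc.index[pos])),
        negative=tuple(sorted(fc.index[neg])),
        fold_changes=fc,
    )


def rank_degs(table: pd.DataFrame, n: int = 3000) -> tuple[str, ...]:
    """Top-``n`` opposite-direction probes by magnitude of change.

    The ranking key is max(|log2 overexpression fold|, |log2 knockdown
    fold|) among probes responding in opposite directions; ties break by
    probe id.
    """
    fc = _fold_changes(table)
    oe, kd = fc["oe_fold"], fc["kd_fold"]
    opposite = ((oe > 1) & (kd < 1)) | ((oe < 1) & (kd > 1))
    key = np.maximum(np.abs(np.log2(oe)), np.abs(np.log2(kd)))[opposite]
    order = sorted(key.index, key=lambda g: (-key[g], g))
    return tuple(order[:n])


def genes_with_cooccupied_introns(
    intronic_peaks: Sequence[AnnotatedPeak],
    mark_peaks,
    min_overlap: int = 1,
) -> frozenset[str]:
    """Target genes with >= 1 intronic peak overlapping >= 1 mark peak."""
    trees = _build_trees(_intervals_of(mark_peaks))
    hits = set()
    for ap in intronic_peaks:
        if ap.target_gene is None:
            continue
        if _overlaps_any(ap.peak.interval, trees, min_overlap):
            hits.add(ap.target_gene)
    return frozenset(hits)


def nominate_targets(chip_genes, deg_genes) -> frozenset[str]:
    """Exact intersection of ChIP-occupied genes and DEGs."""
    return frozenset(chip_genes) & frozenset(deg_genes)


@dataclass(frozen=True)
class ScreenResult:
    """All intermediate gene sets of the target-nomination funnel."""

    annotated: tuple[AnnotatedPeak, ...]
    distribution: dict[str, float]
    intronic_target_genes: frozenset[str]
    cooccupied_genes: frozenset[str]
    degs: DegResult
    low_stringency_targets: frozenset[str]
    high_stringency_genes: frozenset[str]
    high_stringency_targets: frozenset[str]


def run_screen(
    genes: Sequence[GeneModel],
    peaks: Sequence[Peak],
    enhancer_mark_peaks,
    expression_table: pd.DataFrame,
    top_n_peaks: int = 3000,
    log2_threshold: float = 4.0,
    fold_threshold: float = 2.0,
    top_n_probes: int = 3000,
    promoter_window: tuple[int, int] = (2000, 500),
    max_target_dist: int = 10000,
) -> ScreenResult:
    """The full nomination funnel from peak calls and expression contrasts.

    Low stringency: top-N peaks -> intronic target genes -> genes whose
    intronic peaks are co-occupied by the enhancer mark -> intersect with the
    top-N opposite-direction probes.  High stringency: enrichment-filtered
    peaks in gene features (promoter/exon/intron) -> target genes ->
    intersect with the thresholded opposite-direction DEGs.
    """
    fmap = build_feature_map(genes, promoter_window)
    top = select_top_peaks(peaks, top_n_peaks)
    annotated = tuple(annotate_peaks(top, fmap, genes, max_dist=max_target_dist))
    distribution = genomic_distribution(annotated)

    intronic = [a for a in annotated if a.category == "intron"]
    intronic_genes = frozenset(
        a.target_gene for a in intronic if a.target_gene is not None
    )
    cooccupied = genes_with_cooccupied_introns(intronic, enhancer_mark_peaks)

    degs = select_degs(expression_table, fold_threshold=fold_threshold)
    low_probes = rank_degs(expression_table, n=top_n_probes)
    low_targets = nominate_targets(cooccupied, low_probes)

    hs_peaks = set(
        id(p) for p in filter_high_stringency(top, log2_threshold=log2_threshold)
    )
    hs_genes = frozenset(
        a.target_gene
        for a in annotated
        if id(a.peak) in hs_peaks
        and a.category in ("promoter", "exon", "intron")
        and a.target_gene is not None
    )
    hs_targets = nominate_targets(hs_genes, degs.all_degs)

    return ScreenResult(
        annotated=annotated,
        distribution=distribution,
        intronic_target_genes=intronic_genes,
        cooccupied_genes=cooccupied,
        degs=degs,
        low_stringency_targets=low_targets,
        high_stringency_genes=hs_genes,
        high_stringency_targets=hs_targets,
    )
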