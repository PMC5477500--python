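"""Synthetic data with the statistical structure the screen assumes.

The generator emits a toy genome, ChIP coverage and peak calls, histone-mark
peak sets and coverage tracks, nucleosome-turnover regions, an
overexpression/knockdown expression table and a survival cohort — together
with the ground truth used to plant them, so that every pipeline stage can be
tested without external data.

Planted structure:

* intronic peak amplitudes scale with target-gene expression
  (``amplitude = base * exp(slope * z(expr)) * exp(noise)``), while promoter
  and intergenic amplitudes are drawn independently of expression;
* a configurable number of positive/negative opposite-direction DEGs are
  planted in the expression contrasts at a fixed fold effect;
* exactly one gene (the planted target, an analogue of an intronic-element
  regulated gene) carries a high-stringency, enhancer-mark-co-occupied
  intronic peak *and* is a planted DEG, so the high-stringency funnel
  nominates it uniquely;
* survival times are exponential with log-hazard linear in the standardised
  expression of one or two genes (plus an optional interaction), with
  uniform censoring.

Each stage draws from its own seeded substream, so stages can be regenerated
independently and in any order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CoverageTrack,
    GenomicInterval,
    write_bed,
    write_bedgraph,
    write_gtf,
    write_narrowpeak,
    write_tsv,
)
from .genome_model import GeneModel
from .peaks import Peak

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedData",
    "simulate_genome",
    "simulate_expression",
    "simulate_chip",
    "simulate_marks",
    "simulate_turnover",
    "simulate_cohort",
    "simulate_all",
]

# substream indices, one per generation stage
_STAGE = {"genome": 1, "expression": 2, "chip": 3, "marks": 4,
          "turnover": 5, "cohort": 6}

PEAK_SIGMA = 150     # Gaussian coverage shape, bp
PEAK_HALFWIDTH = 600  # 4 sigma: called peak interval half-width, bp


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    # genome
    n_genes: int = 300
    chrom: str = "chrS"
    exons_per_gene: int = 3
    exon_length: int = 600
    intron_length: int = 3000
    gene_spacing: int = 20000
    margin: int = 3000
    chrom_length: int | None = None
    # ChIP
    n_intronic_peaks: int = 300
    n_promoter_peaks: int = 300
    n_intergenic_peaks: int = 299
    background_coverage: int = 2
    base_amplitude: float = 8.0
    occupancy_expression_slope: float = 0.5
    amplitude_noise_sd: float = 0.3
    target_enrichment: float = 32.0
    nontarget_enrichment_cap: float = 8.0
    # expression contrasts
    deg_counts: tuple[int, int] = (50, 30)
    fold_effect: float = 4.0
    noise_sd: float = 0.1
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    # marks
    mark_cooccupancy_probs: Mapping[str, float] = field(default_factory=lambda: {
        "H4K20me1": 0.80, "H3K36me3": 0.75, "H3K79me2": 0.70,
        "H3K4me1": 0.60, "H3K4me3": 0.30, "H3K27me3": 0.08,
    })
    enhancer_mark: str = "H3K4me1"
    # turnover stratification
    turnover_fraction: float = 0.5
    turnover_active_amp: float = 20.0
    turnover_quiet_amp: float = 2.0
    active_track: str = "H3K9ac"
    repressive_track: str = "H3K27me3"
    # cohort
    n_patients: int = 200
    hazard_log_hr: Mapping[str, float] = field(default_factory=lambda: {
        "H3F3A": math.log(2.0), "GPR87": math.log(2.0),
    })
    hazard_interaction: float = math.log(1.5)
    baseline_hazard: float = 0.1
    censoring_horizon: float = 20.0

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage]])

    @property
    def gene_span(self) -> int:
        return (self.exons_per_gene * self.exon_length
                + (self.exons_per_gene - 1) * self.intron_length)

    @property
    def effective_chrom_length(self) -> int:
        if self.chrom_length is not None:
            return self.chrom_length
        return 2 * self.margin + self.n_genes * self.gene_spacing


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for verifying recovery."""

    positive_degs: tuple[str, ...]
    negative_degs: tuple[str, ...]
    target_gene: str | None
    peak_info: pd.DataFrame        # name, category, host_gene, amplitude, enrichment
    high_turnover_peaks: tuple[str, ...]
    hazard_log_hr: dict


def _standardize(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        return x
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> list[GeneModel]:
    """Regularly spaced non-overlapping genes with alternating strands.

    Each gene has ``exons_per_gene`` equal exons separated by equal introns.
    The layout is deterministic; an over-full chromosome raises.
    """
    span = config.gene_span
    if span + 2 * PEAK_HALFWIDTH >= config.gene_spacing:
        raise ValueError("gene_spacing too small for the gene span")
    needed = 2 * config.margin + config.n_genes * config.gene_spacing
    if needed > config.effective_chrom_length:
        raise ValueError(
            f"chromosome too small: need {needed} bp, "
            f"have {config.effective_chrom_length}"
        )
    genes = []
    for i, gid in enumerate(gene_ids(config.n_genes)):
        start = config.margin + i * config.gene_spacing
        exons = []
        for e in range(config.exons_per_gene):
            ex_start = start + e * (config.exon_length + config.intron_length)
            exons.append(GenomicInterval(
                config.chrom, ex_start, ex_start + config.exon_length,
                "+" if i % 2 == 0 else "-",
            ))
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(
            gene_id=gid,
            interval=GenomicInterval(config.chrom, start, start + span, strand),
            strand=strand,
            exons=tuple(exons),
        ))
    return genes


# ---------------------------------------------------------------------------
# Expression contrasts
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, tuple[str, ...], tuple[str, ...]]:
    """Overexpression/knockdown expression table with planted DEGs.

    Baselines are lognormal; planted positive DEGs are multiplied by the
    fold effect under overexpression and divided under knockdown (negative
    DEGs the reverse); every measurement carries independent multiplicative
    lognormal noise.  Returns (table, positive ids, negative ids).
    """
    rng = config.rng("expression")
    ids = list(ids) if ids is not None else gene_ids(config.n_genes)
    n = len(ids)
    n_pos, n_neg = config.deg_counts
    if n_pos + n_neg > n:
        raise ValueError("more planted DEGs than genes")
    planted = rng.choice(n, size=n_pos + n_neg, replace=False)
    pos_idx, neg_idx = planted[:n_pos], planted[n_pos:]

    baseline = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sd, n))
    oe_factor = np.ones(n)
    kd_factor = np.ones(n)
    oe_factor[pos_idx] = config.fold_effect
    kd_factor[pos_idx] = 1.0 / config.fold_effect
    oe_factor[neg_idx] = 1.0 / config.fold_effect
    kd_factor[neg_idx] = config.fold_effect

    def noisy(values: np.ndarray) -> np.ndarray:
        return values * np.exp(rng.normal(0.0, config.noise_sd, n))

    table = pd.DataFrame({
        "control": noisy(baseline),
        "overexpression": noisy(baseline * oe_factor),
        "knockdown": noisy(baseline * kd_factor),
        "knockdown_control": noisy(baseline),
    }, index=pd.Index(ids, name="gene"))
    positive = tuple(ids[i] for i in sorted(pos_idx))
    negative = tuple(ids[i] for i in sorted(neg_idx))
    return table, positive, negative


# ---------------------------------------------------------------------------
# ChIP peaks and coverage
# ---------------------------------------------------------------------------

def _add_gaussian(coverage: np.ndarray, summit: int, amplitude: float) -> None:
    lo = max(0, summit - PEAK_HALFWIDTH)
    hi = min(coverage.size, summit + PEAK_HALFWIDTH)
    x = np.arange(lo, hi)
    coverage[lo:hi] += np.rint(
        amplitude * np.exp(-((x - summit) ** 2) / (2.0 * PEAK_SIGMA**2))
    ).astype(coverage.dtype)


def simulate_chip(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    expression: Mapping[str, float],
    force_high: frozenset[str] = frozenset(),
    cap_low: frozenset[str] = frozenset(),
) -> tuple[list[Peak], CoverageTrack, pd.DataFrame]:
    """ChIP peak calls plus 1-bp coverage with planted occupancy structure.

    Intronic peak amplitudes follow ``base * exp(slope * z(log expr))`` times
    lognormal noise; promoter and intergenic amplitudes are independent of
    expression.  Genes in ``force_high`` get the high target enrichment and
    genes in ``cap_low`` are capped below the high-stringency threshold
    (used to make the planted nomination target unique).  Returns
    (peaks, coverage track, per-peak truth table).
    """
    rng = config.rng("chip")
    if config.n_intronic_peaks > len(genes):
        raise ValueError("more intronic peaks than genes")
    if config.n_promoter_peaks > len(genes):
        raise ValueError("more promoter peaks than genes")
    if config.n_intergenic_peaks > max(len(genes) - 1, 0):
        raise ValueError("more intergenic peaks than inter-gene gaps")
    bg = config.background_coverage
    coverage = np.full(config.effective_chrom_length, bg, dtype=np.int64)
    peaks: list[Peak] = []
    truth_rows = []

    host_idx = sorted(
        rng.choice(len(genes), size=config.n_intronic_peaks, replace=False)
    )
    # forced genes must receive an intronic peak: swap them in if missing
    chosen = {genes[i].gene_id for i in host_idx}
    by_id = {g.gene_id: i for i, g in enumerate(genes)}
    for gid in sorted(force_high - chosen):
        if gid not in by_id:
            continue
        for j, i in enumerate(host_idx):
            if genes[i].gene_id not in force_high:
                host_idx[j] = by_id[gid]
                break
        host_idx.sort()
    hosts = [genes[i] for i in host_idx]
    logexpr = np.log([expression[g.gene_id] for g in hosts])
    z = _standardize(logexpr)
    indep_sd = math.hypot(config.occupancy_expression_slope,
                          config.amplitude_noise_sd)

    def finalize(amplitude: float, host: str | None) -> tuple[float, float]:
        """Apply the force/cap rules; return (amplitude, enrichment)."""
        enrichment = 1.0 + amplitude / bg
        if host is not None and host in force_high:
            enrichment = config.target_enrichment
        elif host is not None and host in cap_low:
            enrichment = min(enrichment, config.nontarget_enrichment_cap)
        return (enrichment - 1.0) * bg, enrichment

    # intronic peaks, one per host gene, in the intron farthest from the TSS
    for g, zi in zip(hosts, z):
        introns = g.introns
        intron = introns[-1] if g.strand == "+" else introns[0]
        center = (intron.start + intron.end) // 2
        summit = int(center + rng.integers(-200, 201))
        amp = config.base_amplitude * math.exp(
            config.occupancy_expression_slope * zi
            + config.amplitude_noise_sd * rng.normal()
        )
        amp, enr = finalize(amp, g.gene_id)
        _add_gaussian(coverage, summit, amp)
        peaks.append(Peak(
            interval=GenomicInterval(config.chrom, summit - PEAK_HALFWIDTH,
                                     summit + PEAK_HALFWIDTH),
            score=amp, summit=summit, enrichment=enr,
            name=f"intronic_{g.gene_id}",
        ))
        truth_rows.append(("intronic_" + g.gene_id, "intron", g.gene_id, amp, enr))

    # promoter peaks, 500 bp upstream of the TSS by strand
    prom_hosts = [genes[i] for i in sorted(
        rng.choice(len(genes), size=config.n_promoter_peaks, replace=False)
    )]
    for g in prom_hosts:
        offset = 500 + int(rng.integers(-100, 101))
        summit = g.tss - offset if g.strand == "+" else g.tss + offset
        amp = config.base_amplitude * math.exp(indep_sd * rng.normal())
        amp, enr = finalize(amp, g.gene_id)
        _add_gaussian(coverage, summit, amp)
        peaks.append(Peak(
            interval=GenomicInterval(config.chrom, summit - PEAK_HALFWIDTH,
                                     summit + PEAK_HALFWIDTH),
            score=amp, summit=summit, enrichment=enr,
            name=f"promoter_{g.gene_id}",
        ))
        truth_rows.append(("promoter_" + g.gene_id, "promoter", g.gene_id, amp, enr))

    # intergenic peaks: one per sampled inter-gene gap, 3.5-8 kb past the
    # previous gene so the nearest gene is always within the 10 kb cutoff
    gaps = sorted(rng.choice(len(genes) - 1, size=config.n_intergenic_peaks,
                             replace=False)) if config.n_intergenic_peaks else []
    for gi in gaps:
        prev_end = genes[gi].interval.end
        summit = int(prev_end + rng.integers(3500, 8001))
        amp = config.base_amplitude * math.exp(indep_sd * rng.normal())
        amp, enr = finalize(amp, None)
        _add_gaussian(coverage, summit, amp)
        name = f"intergenic_{gi:04d}"
        peaks.append(Peak(
            interval=GenomicInterval(config.chrom, summit - PEAK_HALFWIDTH,
                                     summit + PEAK_HALFWIDTH),
            score=amp, summit=summit, enrichment=enr, name=name,
        ))
        truth_rows.append((name, "intergenic", None, amp, enr))

    track = CoverageTrack.from_array(config.chrom, coverage)
    truth = pd.DataFrame(
        truth_rows,
        columns=["name", "category", "host_gene", "amplitude", "enrichment"],
    ).set_index("name")
    return peaks, track, truth


# ---------------------------------------------------------------------------
# Histone-mark peak sets
# ---------------------------------------------------------------------------

def simulate_marks(
    config: SimulationConfig,
    intronic_peaks: Sequence[Peak],
    force_cooccupied: Mapping[str, frozenset[str]] | None = None,
) -> dict[str, list[Peak]]:
    """Mark peak sets overlapping each intronic peak with per-mark probability.

    ``force_cooccupied`` maps mark name -> peak names that must overlap
    (used to guarantee the planted target is enhancer-mark co-occupied).
    """
    rng = config.rng("marks")
    force_cooccupied = force_cooccupied or {}
    marks: dict[str, list[Peak]] = {}
    for mark in sorted(config.mark_cooccupancy_probs):
        p = config.mark_cooccupancy_probs[mark]
        forced = force_cooccupied.get(mark, frozenset())
        out = []
        for peak in intronic_peaks:
            if rng.random() < p or peak.name in forced:
                s = peak.effective_summit + int(rng.integers(-100, 101))
                out.append(Peak(
                    interval=GenomicInterval(config.chrom, s - 300, s + 300),
                    score=1.0, name=f"{mark}_{peak.name}",
                ))
        marks[mark] = out
    return marks


# ---------------------------------------------------------------------------
# Turnover regions and mark coverage tracks
# ---------------------------------------------------------------------------

def simulate_turnover(
    config: SimulationConfig,
    intronic_peaks: Sequence[Peak],
    force_high: frozenset[str] = frozenset(),
) -> tuple[list[GenomicInterval], dict[str, CoverageTrack], tuple[str, ...]]:
    """High-turnover regions plus active/repressive mark coverage tracks.

    A random fraction of the intronic peaks is declared high-turnover; the
    active mark track gets the high amplitude at those peaks and the quiet
    amplitude elsewhere, the repressive track the reverse.  Returns
    (regions, tracks, names of high-turnover peaks).
    """
    rng = config.rng("turnover")
    high_flags = rng.random(len(intronic_peaks)) < config.turnover_fraction
    regions = []
    high_names = []
    active = np.ones(config.effective_chrom_length, dtype=np.int64)
    repressive = np.ones(config.effective_chrom_length, dtype=np.int64)
    for peak, flag in zip(intronic_peaks, high_flags):
        is_high = bool(flag) or peak.name in force_high
        s = peak.effective_summit
        if is_high:
            regions.append(GenomicInterval(config.chrom, s - 500, s + 500))
            high_names.append(peak.name)
        a_amp = config.turnover_active_amp if is_high else config.turnover_quiet_amp
        r_amp = config.turnover_quiet_amp if is_high else config.turnover_active_amp
        _add_gaussian(active, s, a_amp)
        _add_gaussian(repressive, s, r_amp)
    tracks = {
        config.active_track: CoverageTrack.from_array(config.chrom, active),
        config.repressive_track: CoverageTrack.from_array(config.chrom, repressive),
    }
    return regions, tracks, tuple(high_names)


# ---------------------------------------------------------------------------
# Survival cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Cohort with exponential survival and log-hazard linear in expression.

    ``time`` is the minimum of the event time and an independent uniform
    censoring horizon; ``event`` flags observed events and ``relapse`` is
    "yes" for patients whose event occurred before censoring.
    """
    rng = config.rng("cohort")
    n = config.n_patients
    if n < 4:
        raise ValueError("need at least 4 patients")
    genes = list(config.hazard_log_hr)
    expr = {
        g: np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))
        for g in genes
    }
    z = {g: _standardize(np.log(expr[g])) for g in genes}
    log_hazard = sum(
        config.hazard_log_hr[g] * z[g] for g in genes
    )
    if len(genes) >= 2:
        log_hazard = log_hazard + config.hazard_interaction * z[genes[0]] * z[genes[1]]
    rate = config.baseline_hazard * np.exp(log_hazard)
    event_time = rng.exponential(1.0 / rate)
    horizon = rng.uniform(0.0, config.censoring_horizon, n)
    event = (event_time <= horizon).astype(int)
    time = np.maximum(np.minimum(event_time, horizon), 1e-9)
    cohort = pd.DataFrame({
        **{g: expr[g] for g in genes},
        "time": time,
        "event": event,
        "relapse": np.where(event == 1, "yes", "no"),
    }, index=pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id"))
    return cohort


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    """Everything one run of the generator produces, plus the ground truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    expression_table: pd.DataFrame
    peaks: list[Peak]
    chip_track: CoverageTrack
    marks: dict[str, list[Peak]]
    turnover_regions: list[GenomicInterval]
    mark_tracks: dict[str, CoverageTrack]
    cohort: pd.DataFrame
    truth: GroundTruth

    @property
    def control_expression(self) -> dict[str, float]:
        return self.expression_table["control"].to_dict()

    @property
    def intronic_peaks(self) -> list[Peak]:
        return [p for p in self.peaks if p.name.startswith("intronic_")]

    def write(self, outdir: str | Path) -> None:
        """Emit all inputs as plain-text files plus ``truth.json``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.genes, outdir / "genes.gtf")
        write_narrowpeak(self.peaks, outdir / "chip.narrowPeak")
        write_bedgraph(self.chip_track, outdir / "chip.bedGraph")
        (outdir / "marks").mkdir(exist_ok=True)
        for mark, peaks in self.marks.items():
            write_narrowpeak(peaks, outdir / "marks" / f"{mark}.narrowPeak")
        write_bed(self.turnover_regions, outdir / "turnover.bed")
        (outdir / "tracks").mkdir(exist_ok=True)
        for name, track in self.mark_tracks.items():
            write_bedgraph(track, outdir / "tracks" / f"{name}.bedGraph")
        write_tsv(self.expression_table, outdir / "expr.tsv")
        write_tsv(self.cohort, outdir / "cohort.tsv")
        truth = {
            "positive_degs": list(self.truth.positive_degs),
            "negative_degs": list(self.truth.negative_degs),
            "target_gene": self.truth.target_gene,
            "high_turnover_peaks": list(self.truth.high_turnover_peaks),
            "hazard_log_hr": dict(self.truth.hazard_log_hr),
            "total_reads": {
                "chip": self.chip_track.total_reads,
                **{name: t.total_reads for name, t in self.mark_tracks.items()},
            },
            "peak_info": self.truth.peak_info.reset_index().to_dict("records"),
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True, default=str)


def simulate_all(config: SimulationConfig = SimulationConfig()) -> SimulatedData:
    """Generate the complete dataset with a unique planted nomination target.

    The planted target is the first planted positive DEG: its intronic peak
    is forced to the high-stringency enrichment and to enhancer-mark
    co-occupancy, while the peaks of every other planted DEG are capped
    below the stringency threshold.
    """
    genes = simulate_genome(config)
    table, positive, negative = simulate_expression(config)
    target = positive[0] if positive else None
    degs = frozenset(positive) | frozenset(negative)
    force_high = frozenset({target}) if target else frozenset()
    cap_low = frozenset(degs - force_high)
    expression = table["control"].to_dict()
    peaks, chip_track, peak_info = simulate_chip(
        config, genes, expression, force_high=force_high, cap_low=cap_low
    )
    intronic = [p for p in peaks if p.name.startswith("intronic_")]
    force_mark = (
        {config.enhancer_mark: frozenset({f"intronic_{target}"})}
        if target else None
    )
    marks = simulate_marks(config, intronic, force_cooccupied=force_mark)
    force_turnover = frozenset({f"intronic_{target}"}) if target else frozenset()
    regions, mark_tracks, high_names = simulate_turnover(
        config, intronic, force_high=force_turnover
    )
    cohort = simulate_cohort(config)
    truth = GroundTruth(
        positive_degs=positive,
        negative_degs=negative,
        target_gene=target,
        peak_info=peak_info,
        high_turnover_peaks=high_names,
        hazard_log_hr=dict(config.hazard_log_hr),
    )
    return SimulatedData(
        config=config, genes=genes, expression_table=table, peaks=peaks,
        chip_track=chip_track, marks=marks, turnover_regions=regions,
        mark_tracks=mark_tracks, cohort=cohort, truth=truth,
    )
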