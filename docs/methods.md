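# Methods

## The screen

The package operationalises a multi-evidence screen for intronic regulatory
elements bound by a histone variant. Its stages, and the statistical claims
each one rests on, are:

**Feature partition and peak annotation.** Gene models (merged exons per
gene) induce a labelling of every base as promoter, exon, intron or
intergenic. The promoter is a fixed window around the TSS, oriented by
strand; the default (−2,000, +500) bp is a common convention — the source
annotation practice leaves it open — and is a parameter. Overlapping genes
are resolved with the fixed priority promoter > exon > intron, on the
grounds that a regulatory label should not be masked by a neighbouring gene
body. A peak's category is the label at its *summit* (single-point rule);
annotation by any-overlap would inflate multi-feature peaks. Peaks lacking
summits fall back to the integer midpoint ⌊(start+end)/2⌋. Target genes are
the nearest gene span within 10 kb of the peak interval, boundary to
boundary; ties break by smaller gene start, then gene id, making the
assignment independent of input order. Measuring to gene spans rather than
TSSs is a documented choice: an intronic element regulates its host, which
the span criterion captures with distance 0.

**Stringency levels.** The low-stringency set is the top N = 3,000 peaks by
caller score; the high-stringency subset requires log₂(ChIP/input) ≥ 4.
The ratio-16 boundary is *retained* (≥, not >): the two phrasings of the
cutoff differ only on a measure-zero boundary and the log-scale form is
taken as canonical. Both N and the threshold are parameters.

**Profiles.** Occupancy is quantified as RPKM per fixed-width bin (default
20 bp) over a ±2 kb (or ±5 kb) window centred on the summit:
`RPKM = count / (bin/1000) / (total_reads/10⁶)`, where `count` sums
per-bp coverage (fragment depth, not read 5′ ends — the generator emits
matching semantics). This makes the conservation identity
Σ_bins RPKM·bin_kb·lib_millions = window coverage exact, which the tests
assert to 1e-9. Windows clipped at the chromosome start keep their row with
the out-of-genome bins masked, so row counts are stable. Rows are sorted by
target-gene expression and split into equal-count tertiles by rank
(stable in ties; the low group absorbs the first remainder). Group averages
are smoothed by locally weighted linear regression with tricube weights,
span ⌈f·n⌉ nearest points (f = 0.3) and zero robustness iterations — the
iteration count of the classical function family is unspecified, and zero
makes the result deterministic and exactly reproducible by a
direct-summation oracle (agreement to 1e-8 per point is a test).

**Co-occupancy and turnover.** A query peak co-occurs with a mark if the
full intervals share ≥ 1 bp (no minimum-overlap fraction is assumed; the
threshold is a parameter). Marks are ranked by the fraction of query peaks
covered. For nucleosome-turnover stratification, peaks overlapping any
high-turnover region form the high stratum; per-mark occupancy is the mean
RPKM over the ±1 kb summit window (whole-window mean; no sub-binning is
needed for a scalar summary), and the two strata are compared with a
Mann–Whitney rank-sum test, reported as descriptive.

**DEG rule.** With intensities for control, overexpression (OE) and
knockdown (KD) — KD divided by its own control column when present —
a gene is a *positive* DEG when (OE-fold > θ or 1/KD-fold > θ) **and**
OE-fold > 1 **and** KD-fold < 1, with θ = 2; negative DEGs are the mirror
image. The fold threshold is thus required in at least one contrast
("either"), opposite directionality in both; the stricter both-contrast
variant is a flag. The rule is fold-change-only (no significance filter).
The low-stringency probe list ranks opposite-direction probes by
max(|log₂ OE-fold|, |log₂ KD-fold|) — the ranking key behind "top
probes" is not standardised, so this documented choice is used — and when
probes must collapse to genes, the maximum absolute log₂ fold per gene is
taken. Exchanging the OE and KD columns exchanges the positive and negative
sets exactly (an asserted invariant).

**Nomination.** Low stringency: genes targeted by intronic top-N peaks →
genes whose intronic peak overlaps the enhancer mark (H3K4me1) → intersect
with the top-N probes. High stringency: target genes of high-stringency
peaks in promoter/exon/intron categories (intergenic peaks are excluded
from the occupied-gene set) intersected with the thresholded DEGs.
Nominations are exact set intersections, hence subsets of each input.

**Survival.** Cohorts are split at the per-gene median; values strictly
above the median are "high" (the median patient lands in "low"), and the
quantile is a parameter since the original cutoff convention is unstated.
The dual-gene analysis crosses two median splits into four groups.
Relapse groups are compared with Welch's unequal-variance t-test. The
Kaplan–Meier estimator and the log-rank test (aggregated risk sets for
ties; χ² with k−1 df) are delegated to lifelines; hand-computed
product-limit and log-rank oracles on small examples pin the wrappers down
in the tests. Multivariate proportional-hazards modelling is intentionally
out of scope — it is off-the-shelf statistics on external cohort data —
and the cohort table is emitted in a form any survival package consumes.

## The synthetic generator

`synthetic_data` emulates the *structure* of the real inputs, not their
scale. Defaults are the study conditions used throughout the tests and the
acceptance script:

* **Genome** — 300 regularly spaced genes (3 exons × 600 bp, introns
  3,000 bp, spacing 20 kb, alternating strands) on one ~6 Mb chromosome.
  The spacing is chosen so that promoter, intronic and intergenic peaks are
  ≥ 2.6 kb apart and the ±2 kb profile windows of different peaks never
  overlap — without this, promoter windows would absorb correlated intronic
  signal and blur the planted contrast.
* **ChIP** — background 2 counts/bp plus Gaussian bumps (σ = 150 bp,
  support ±600 bp, rounded to integer counts) at one intronic peak per
  gene (placed in the intron farthest from the TSS), one promoter peak
  (500 bp upstream of the TSS) and one intergenic peak per inter-gene gap
  (3.5–8 kb past the previous gene, so a target gene is always within
  10 kb). Intronic amplitudes follow
  `8·exp(0.5·z(log control expression) + 0.3·ε)`; promoter/intergenic
  amplitudes use the same marginal law but independent of expression.
  The slope 0.5 with noise 0.3 yields a Spearman ρ ≈ 0.85 at n = 300 rows
  — a strong planted effect appropriate for a structural recovery check.
  Enrichment is defined as summit height over background; the caller score
  is the amplitude.
* **Contrasts** — lognormal baselines (log-mean 6, log-sd 1), 50 positive
  and 30 negative planted DEGs at fold 4, measurement noise σ = 0.1
  (multiplicative lognormal). At these settings recovery is exact with
  overwhelming margin (a false positive requires a ~5 σ noise excursion).
* **Uniqueness construction** — the nomination target is the first planted
  positive DEG; its intronic peak is forced to enrichment 32 and to
  enhancer-mark co-occupancy and its region to high turnover, while peaks
  hosted by every *other* planted DEG are capped at enrichment 8 (< 16).
  Genes that are not DEGs may acquire high-stringency peaks by chance but
  cannot be nominated, so the high-stringency funnel returns exactly the
  target.
* **Marks** — each intronic peak is co-occupied by each mark with a
  per-mark probability (gene-body marks 0.7–0.8, enhancer mark 0.6,
  promoter mark 0.3, repressive mark 0.08), echoing the qualitative
  ranking expected for an active-chromatin variant.
* **Turnover** — half the intronic peaks are high-turnover; the active
  mark track has amplitude 20 at high-turnover summits and 2 elsewhere,
  the repressive track the reverse (10× contrast).
* **Cohorts** — exponential survival with
  log-hazard = log 2·z_A + log 2·z_B + log 1.5·z_A·z_B over standardised
  log-expression of two genes, baseline hazard 0.1 per time unit, uniform
  censoring horizon 20 (≈ 40 % censoring). These effect sizes place the
  four-group ordering (high/high worst, low/low best) far from the noise
  floor at n = 400.

Each stage draws from `default_rng([seed, stage_index])`, so stages are
independently reproducible and the chip stage can consume the expression
stage's output without a sequential-stream ordering constraint. Identical
configurations produce byte-identical files (asserted in the tests).

**What the generator does not emulate** — and hence what passing tests do
*not* show about real data: read-level noise and mappability artefacts,
overlapping/nested genes and isoform structure, peak-width and spacing
heterogeneity, probe-level microarray effects, batch/platform differences
between cohorts, and non-proportional hazards. Recovery results here
demonstrate correctness of the computations under the planted model, not
field performance.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere internally; GTF and printed
  region strings convert at the I/O boundary, and chromosome names match
  exactly (no "chr" aliasing — a mismatch raises).
* Coverage queries are prefix-sum differences over run-length-encoded
  non-overlapping intervals; bin sums are exact (integer-weighted), which
  is what makes the RPKM conservation identity exact.
* Deterministic tie-breaks throughout: peak ranking by (−score, chrom,
  start, name); target assignment by (distance, gene start, gene id); mark
  ranking by (−fraction, name); probe ranking by (−key, id); tertiles by
  stable rank.
* Degenerate inputs raise rather than guess: empty peak collections for
  distributions, empty strata, all-identical expression for a median
  split, fewer than three values for tertiles, single survival groups,
  non-positive intensities, overlapping bedGraph records, inverted or
  empty intervals.
* lowess span is clamped to at least 2 points; a zero bandwidth (possible
  only with repeated x positions, which index-based smoothing excludes)
  returns the observed value.

## Sizes used in tests and the acceptance script

Problem sizes were chosen to exercise every claim at meaningful power while
keeping the default runs desk-scale: 300 profile rows per peak category,
1,000 genes for DEG recovery, 200 seeded replicates for log-rank null
calibration (KS uniformity) and power at hazard ratio 3 (n = 200 patients),
and 400 patients for the four-group ordering. The full test suite runs in
well under a minute; the acceptance script in ~10 s.

## Known limitations

* Annotation is gene-level: no isoform-specific introns, UTR
  subcategories, or enhancer calling.
* The occupied-gene funnel treats any intronic peak/mark overlap as
  co-occupancy; no signal-proportional weighting.
* The log-rank χ² approximation is used as implemented in lifelines; exact
  small-sample permutation p-values are not provided (the null-calibration
  test covers the approximation at the cohort sizes used).
* Turnover regions are consumed as intervals; estimating turnover from
  time-course data is out of scope.
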