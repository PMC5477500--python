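# ire-screen

Integrative discovery of **intronic regulatory elements (IREs)** occupied by
the histone variant H3.3, for epigenomics analysts working with ChIP-seq
peak calls, expression contrasts and clinical survival cohorts.

The histone variant H3.3 (encoded by *H3F3A*) is deposited
replication-independently at active chromatin. When deposited inside an
intron it can act as a *cis*-regulatory element that activates its host
gene. `ire-screen` implements the complete computational screen for such
elements:

1. **Peak annotation** — partition the genome into
   promoter / exon / intron / intergenic features (priority
   promoter > exon > intron), categorise each ChIP peak by the feature at
   its summit, and assign the nearest gene within 10 kb as its target.
2. **Occupancy–expression profiles** — summit-centred peaks × bins matrices
   of RPKM (`count / bin_kb / (library/10⁶)`), sorted into expression
   tertiles, averaged per group and smoothed with lowess (tricube kernel,
   span `⌈f·n⌉`, default `f = 0.3`). Intronic occupancy correlating with
   target expression — while promoter/intergenic occupancy does not — is
   the screen's core signature.
3. **Histone-mark co-occupancy** — ranking of mark peak sets by the fraction
   of query peaks they overlap (≥ 1 bp), and comparison of mark occupancy
   between high- and low-nucleosome-turnover peaks (rank-sum test on mean
   windowed RPKM, ±1 kb).
4. **Opposite-direction DEG selection** — a gene is differentially expressed
   when it changes > 2-fold in at least one of the overexpression/knockdown
   contrasts *and* responds in opposite directions in both.
5. **Target nomination** — intersection of DEGs with genes whose introns
   carry (enhancer-mark-co-occupied) peaks, at a low-stringency level
   (top-3000 peaks × top-3000 probes) and a high-stringency level
   (log₂ ChIP/input ≥ 4, i.e. ratio ≥ 16).
6. **Survival stratification** — median-split and dual-gene four-group
   Kaplan–Meier estimation with log-rank tests, plus Welch's *t* comparison
   of relapse groups.

Because the original sequencing/array cohorts are external, the package
ships a first-class **synthetic data generator** (`ire_screen.synthetic_data`)
that emits every input format with the planted statistical structure the
analysis assumes — including a unique planted nomination target — together
with the ground truth, so the whole pipeline is testable offline.

All coordinates are 0-based half-open internally; GTF records and printed
`chrom:start-end` region strings (1-based closed, thousands separators
accepted) are converted on parse.

## Worked example

```python
import ire_screen as irs
from ire_screen.synthetic_data import SimulationConfig, simulate_all

sim = simulate_all(SimulationConfig(seed=1))
screen = irs.run_screen(
    sim.genes, sim.peaks, sim.marks["H3K4me1"], sim.expression_table,
)
print("peak categories:", {k: round(v, 3) for k, v in screen.distribution.items()})
print("genes with intronic peaks:", len(screen.intronic_target_genes))
print("...co-occupied by H3K4me1:", len(screen.cooccupied_genes))
print("opposite-direction DEGs:", len(screen.degs.positive), "positive,",
      len(screen.degs.negative), "negative")
print("high-stringency nominated targets:", sorted(screen.high_stringency_targets))
print("planted target:", sim.truth.target_gene)
```

prints

```
peak categories: {'promoter': 0.334, 'exon': 0.0, 'intron': 0.334, 'intergenic': 0.333}
genes with intronic peaks: 300
...co-occupied by H3K4me1: 175
opposite-direction DEGs: 50 positive, 30 negative
high-stringency nominated targets: ['G0000']
planted target: G0000
```

The 900 simulated peaks split evenly across the three placed categories;
all 300 genes carry an intronic peak, of which 175 are co-occupied by the
enhancer mark; all 80 planted DEGs are recovered; and the high-stringency
funnel (enrichment ≥ 16 × input, intersected with the DEGs) nominates
exactly the single planted target gene. On the same dataset the intronic
occupancy–expression association is strong and specific:

```
intronic occupancy vs expression: Spearman rho=0.848, p=4.5e-84
```

while the promoter and intergenic peak sets show no association
(p > 0.05; see `scripts/acceptance.py` output).

A command-line interface mirrors the library
(`ire-screen simulate | annotate | filter | profile | cooccupy | turnover |
degs | nominate | survival | convert-region | validate`); run
`ire-screen --help`.

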