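# ipskit

Desk-scale comparative genomics for bark-beetle genome projects.

`ipskit` packages, as one tested Python library plus CLI, the analysis
stages that surround a typical insect genome assembly — exemplified by the
Eurasian spruce bark beetle *Ips typographus*, a Scolytinae weevil whose
genome project motivated the toolkit:

- **Assembly QC** (`ipskit.assembly`, `ipskit.annotation`): contig
  N50/L50, Nx curve, GC% (N excluded), size-class summaries; gene-model
  statistics from GFF3 (gene/exon/intron lengths, % genome covered).
- **Telomere scanning** (`ipskit.assembly.scan_telomeres`): tandem arrays
  of the ancestral insect telomere repeat TTAGG (or any motif) near contig
  termini, with forward/reverse strand attribution — evidence that contigs
  approach chromosome scale.
- **K-mer genome-size estimation** (`ipskit.kmers`): canonical k-mer depth
  histograms from reads and the transparent peak-ratio size estimate
  `round(sum_{d >= valley} d·c_d / peak_depth)`, with an error-valley cut
  and uni-/multi-modality (homozygosity) classification.
- **Gene-family expansion testing** (`ipskit.expansion`): once-per-protein
  Pfam-domain counts per species; per-domain Fisher exact tests of a focal
  species against the leave-one-out background average, with gene totals as
  the table margins; Benjamini–Hochberg FDR; `q < 0.05 AND direction up`
  expansion calls; domain×species z-score heatmap matrices.
- **Effect sizes** (`ipskit.effectsize`): Hedges *g* — the standardized
  mean difference `d = (m1 − m2)/s_pooled` corrected by
  `J = 1 − 3/(4·df − 1)` — with noncentral-*t* (default) or
  normal-approximation confidence intervals.
- **Expression matrices** (`ipskit.expression`): TPM from counts,
  `log2(TPM + 1)` transform and per-gene row scaling for heatmaps.
- **Synthetic data** (`ipskit.synthetic`): deterministic generators for
  every input — genomes with target GC, fragmented contigs with planted
  telomeres, error-bearing read sets, Poisson domain-count tables with
  planted fold-change expansions, expression counts — all with ground-truth
  tables, so every downstream stage is testable without external data.

A packaged reference table (`ipskit.datasets.load_detox_domain_counts`)
holds the detoxification/pesticide-resistance domain repertoires of 12
Coleoptera species (8 Pfam families plus published totals) used by the
effect-size workflow.

## Worked example

Comparing the total detoxification-domain repertoires of the three
scolytine bark beetles against nine other coleopterans:

```python
from ipskit import datasets
from ipskit.effectsize import compare_species_sets

counts = datasets.load_detox_domain_counts(drop_total=True)
res = compare_species_sets(
    counts, datasets.SCOLYTINE_SPECIES, datasets.OTHER_COLEOPTERA
)
print(res.summary())
```

```
Hedges g effect size
  group 1: n=3, mean=327.67, sd=37.58
  group 2: n=9, mean=527.56, sd=125.86
  mean difference: -199.89
  pooled sd: 113.82
  d = -1.756, J = 0.9231, g = -1.6
  95% CI (noncentral_t): -3.0 to -0.2
```

The scolytines carry on average ~200 fewer detoxification-domain proteins
than the other beetles; scaled by the pooled SD and bias-corrected, that is
a strong negative effect (g = −1.6) whose wide CI reflects the tiny group
sizes. A fully synthetic end-to-end run — genome, fragmented contigs with
planted telomeres, 50× error-bearing reads, k-mer histogram — prints, for a
100 kb genome at seed 1:

```
Peak k-mer depth 38, estimated haploid genome length 101,448 bp (1 peak(s): homozygous-like)
Telomeric motifs at the ends of 5 contigs (4 forward strands, 3 reverse strands)
```

i.e. the estimator recovers the simulated genome size to ~1.4% and the scan
recovers every planted telomeric terminus.

The same stages are exposed as CLI subcommands
(`ipskit simulate | asm-stats | annot-stats | telomeres | kmer-hist |
genome-size | count-domains | expand | effect-size | expr-matrix | report`);
`ipskit report --fasta contigs.fasta` emits assembly-, annotation- and
effect-size blocks in the familiar genome-paper table layout.

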