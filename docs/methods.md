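# Methods

This note documents the statistical and algorithmic choices behind each
stage, the parameters that matter, and what the synthetic-data generator
does and does not emulate.

## Assembly statistics

N50 is the length of the contig at which the descending-sorted cumulative
length first reaches at least half the assembly total; L50 is the number of
contigs needed to get there. The `>=` tie convention (a cumulative sum
landing exactly on total/2 takes that contig's length) matches common
assembler reports. The Nx curve applies the same rule at 10%–90%.

GC% is `100·(G+C)/(A+C+G+T)`: N bases are excluded from the denominator so
the figure reflects base composition only and is insensitive to gap/
ambiguity content. Size-class summaries report, per threshold, the count of
contigs at or above it and the fraction of total assembly length they
carry.

Annotation statistics treat GFF3 coordinates as 1-based inclusive; gene
length is `end − start + 1`; introns are the gaps between a gene's exons
after merging overlapping exon intervals (isoform exons may tile the same
region); average values are printed as integers rounded half away from
zero, the convention of published annotation tables. Aggregate-only inputs
(gene count + total gene length + genome length) are supported through
`AnnotationStats.from_totals`, which fully determines the average gene
length and percent-covered figures.

## Telomere scanning

A hit is at least `min_copies` exact tandem copies of the motif (forward
strand) or of its reverse complement (reverse strand) whose
terminus-proximal end lies within `window_bp` of a contig end. Defaults:
motif `TTAGG` (the ancestral insect telomere repeat), `min_copies = 5`,
`window_bp = 1000`. These are exposed as CLI flags; only exact copies are
counted — degenerate-repeat tolerance is a known limitation. When a single
array falls within the window of both termini of a short contig it is
assigned to the nearer terminus (tie → 5′). At most one hit is reported
per (contig, terminus), keeping the highest copy count. Scanning a
reverse-complemented assembly mirrors termini and strands exactly.

## K-mer counting and genome-size estimation

K-mers are canonicalized as the lexicographic minimum of each k-mer and its
reverse complement (equivalently the smaller 2-bit packed code), making
counting strand-independent; windows containing N are skipped. Counting is
exact and in-memory (packed 64-bit codes + `np.unique`), which caps k at 31
— ample at desk scale, where genomes are kilobases to megabases. Depths
above `max_depth` (default 10,000) accumulate in an overflow bin, mirroring
common histogram dialects. Histograms read and write the two-column
`depth<TAB>count` text dialect.

The size estimator is the transparent peak-ratio rule: find the error
valley (first local minimum of smoothed counts vs depth), take the coverage
peak as the smoothed argmax beyond it, and report
`round(sum_{d >= valley} d·c_d / peak_depth)`. Numerical choices:

- smoothing is a centred moving average, window 3, to suppress shot noise;
- valley/peak detection smooths along the *occupied*-depth grid, which is
  identical to dense smoothing for the contiguous histograms real surveys
  produce but keeps the estimate exactly invariant under uniform depth
  rescaling (e.g. duplicating the read set);
- a leading decreasing slope is treated as the error component only when
  the support starts at depth ≤ 2, where error k-mers live; a histogram
  that only decreases raises an estimation error (no coverage peak);
- peak multiplicity is counted on the dense depth axis with
  `scipy.signal.find_peaks` and a prominence floor of 2.5% of the maximum,
  so well-separated modes of comparable mass register as distinct; one
  peak ⇒ "homozygous-like", more ⇒ "heterozygous-like". Peak counting
  assumes an essentially contiguous histogram.

The integer peak depth bounds attainable accuracy: at coverage giving mean
k-mer depth λ the discretization alone contributes up to ~0.5/λ relative
error, and ±1–2 bins of peak jitter at λ ≈ 35–40 keeps simulated 100 kb
estimates within 5% of truth at 50×. The estimator deliberately omits the
negative-binomial mixture fit of GenomeScope-class tools, so published
model-fit figures are context, not targets; heterozygosity and repeat
fractions are not estimated.

## Domain expansion testing

Counting: a protein contributes at most once per domain (`nunique` over
protein ids), so every count is bounded by its species' gene total. Inputs
are 3-column TSVs or hmmscan `--tblout` files (accession preferred over
target name, version suffix stripped).

The test compares focal species f against the leave-one-out background:
the per-domain mean count and mean gene total of the remaining species.
The gene totals are the normalisation — they form the margins of the 2×2
table

```
[[c_f, G_f − c_f],
 [round(mean_bg_count), round(mean_bg_genes) − round(mean_bg_count)]]
```

(rounding half away from zero keeps the table integer for an exact test).
A pooled-background variant (summing instead of averaging the remaining
species) is available behind a flag; rounded-mean is the default. The
two-sided Fisher p is computed in-package in log space from the
hypergeometric pmf via log-gamma, summing probabilities not exceeding the
observed pmf with the customary 1+1e-7 relative tie slack; this stays
exact-to-double for margins up to ~1e5 (real proteome scale). A one-sided
(upper tail) variant backs the CLI's `--one-sided` flag. The sample odds
ratio uses the conventions 0/positive → 0, positive/0 → +inf, 0/0 → 1.

The test is two-sided with a separate direction gate (focal proportion vs
unrounded background proportion) because repertoires both expand and
contract; an expansion call requires BH-FDR q < alpha (default 0.05) AND
direction up. The multiple-testing family defaults to all domains with a
nonzero count in at least one species; `focal_nonzero` and `all` variants
are available since the right family is genuinely ambiguous. BH-FDR is
delegated to `statsmodels.stats.multitest`.

Z-score heatmap matrices standardise each domain row across species with
the sample SD (n−1); constant rows map to zero. Cell values are literally
"standard deviations from the cross-species mean".

## Effect sizes

Hedges g: pooled SD `sqrt(((n1−1)s1² + (n2−1)s2²)/df)` with
`df = n1+n2−2`, `d = (m1−m2)/s_pooled`, and correction
`J = 1 − 3/(4·df − 1)`; the exact gamma-ratio J is available behind a flag
and differs by <0.1% at the group sizes involved here. The default CI
inverts the noncentral t distribution: with
`t = d·sqrt(n1·n2/(n1+n2))`, the noncentrality bounds solve
`P(T_{df,λ} ≤ t) = 1−α/2` and `α/2` (Brent root-finding on an adaptively
expanded bracket, tolerance 1e-12) and are rescaled to the g scale. The
normal approximation `g ± z·sqrt((n1+n2)/(n1·n2) + g²/(2(n1+n2)))` is kept
for comparison. At the packaged 3-vs-9 comparison the two intervals are
similar in width (the noncentral-t interval is in fact slightly narrower
and asymmetric about g); neither dominates, and the default is
noncentral-t because it respects the exact small-sample distribution.
Presentation rounds g and CI bounds to one decimal.

The packaged 12-species repertoire table is internally consistent (family
counts sum to the printed totals everywhere). One known discrepancy of the
source: the scolytine group's printed mean (327) truncates rather than
rounds the computed 327.67; the package computes and rounds (328) and the
fixture test documents the difference.

## Expression matrices

TPM divides each count by its gene's effective length and rescales each
sample column to sum to 1e6; effective length is the annotated transcript
length with no fragment-length correction (the module's documented
dialect). All-zero columns stay zero with a warning rather than erroring.
Heatmap values are `log2(TPM+1)` followed by per-gene centring and scaling
by the across-sample SD (n−1), matching the standard "scale" behaviour;
constant genes map to zero rows and fewer than two samples is an error.
Replicate averaging before scaling is off by default; matrices round-trip
through TSV at 6 significant digits.

## Synthetic data

The generators emulate the study conditions of a bark-beetle genome
project, scaled to desk size:

- genomes are i.i.d. base sequences with target GC 0.352 (the composition
  of the assembled genome); no repeats, heterozygosity or chromosome
  structure;
- reads are uniform forward-strand substrings (canonical k-mer counting
  makes strand irrelevant downstream) with i.i.d. substitutions, constant
  FASTQ quality, no indels and no long-read length model; defaults follow
  the 150 bp short-read survey design, with per-experiment coverage
  (tests use 30–100× where the real survey ran ~230×);
- fragmentation draws breakpoints uniformly without replacement (short
  fragments redrawn), and each terminus independently receives a planted
  telomere array with probability 0.5 — sparse, as in the real assembly
  where only 8 of 272 contig ends carried the motif: the motif is
  prepended at 5′ ends and its reverse complement appended at 3′ ends;
- domain counts are Poisson with rate proportional to each species' gene
  total (`baseline_rate · G_s / mean G`), matching the implicit count
  model of a Fisher 2×2 on totals; planted expansions multiply the focal
  rate by a fold change > 1. Overdispersion (negative binomial) is a
  possible extension, not the default: passing tests therefore show FDR
  control under the Poisson null, not under arbitrary overdispersion;
- expression counts are Poisson around log-normal gene baselines with
  ~2-fold sample depth variation and uniform 500–5000 bp lengths.

Everything is deterministic under one global integer seed; each operation
draws from a named CRC-keyed substream so stages can be re-run
independently.

Simulation scales used by the test suite — 100 kb genomes at 50× for
genome-size recovery (10 seeds), 500-domain/5-species tables with gene
totals 18–22k for expansion power (50 seeds) and null calibration (50
replicates), 1000 random length multisets for the N50 oracle, 500 random
2×2 tables (total ≤ 200) for the exact-enumeration Fisher check — were
chosen as the smallest sizes at which the quantities of interest are
well-resolved; they keep the default suite under a minute.

## Known limitations

- The telomere scanner requires exact repeat copies; diverged arrays are
  missed.
- The genome-size estimator is peak-ratio only; repeat-rich or highly
  heterozygous genomes need a mixture-model tool.
- The expansion test conditions on rounded background margins; with very
  small backgrounds the rounding can matter (the pooled variant avoids
  it at the cost of weighting species by proteome size).
- CLI `simulate` plants expansions only in the first simulated species;
  the library API supports arbitrary focal species per domain.
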