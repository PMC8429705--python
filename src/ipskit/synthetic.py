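"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is deterministic under a single global integer seed; each
operation draws from a named substream of that seed so stages can be re-run
independently (see :func:`ipskit._util.substream_rng`).

The generators emulate the study conditions of a bark-beetle genome project:
a ~hundreds-of-Mb haploid genome surveyed with short error-bearing reads at
high fold-coverage, an assembly fragmented into contigs whose termini may
carry the ancestral insect telomere repeat (TTAGG), multi-species
Pfam-domain count tables with Poisson baselines and planted fold-change
expansions, and gene x sample expression count tables. Scale is dialled
down to desk size through the spec objects; the structure is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contigs import ContigSet
from .exceptions import InputError
from ._util import reverse_complement, substream_rng

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# genome + fragmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """A random genome: i.i.d. bases with a target GC fraction.

    Defaults mirror the composition of the assembled bark-beetle genome
    (GC ~ 35.2%); ``length_bp`` is chosen per experiment since desk-scale
    runs use kb-to-Mb genomes rather than the real 237 Mb.
    """

    length_bp: int
    gc_fraction: float = 0.352
    seed: int = 0


def generate_genome(spec: GenomeSpec) -> ContigSet:
    """Sample a single-contig genome under ``spec``."""
    if spec.length_bp < 1:
        raise InputError("genome length_bp must be >= 1")
    if not 0.0 <= spec.gc_fraction <= 1.0:
        raise InputError("gc_fraction must lie in [0, 1]")
    rng = substream_rng(spec.seed, "genome")
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=spec.length_bp, p=p).astype(np.uint8)
    return ContigSet([("genome", _decode(codes))])


def fragment_genome(
    genome: ContigSet,
    n_contigs: int,
    telomere_motif: str = "TTAGG",
    telomere_copies: int = 0,
    seed: int = 0,
    plant_probability: float = 0.5,
    min_fragment_bp: int = 1,
) -> tuple[ContigSet, pd.DataFrame]:
    """Cut the genome into contigs and plant telomeric repeats at termini.

    Breakpoints are drawn uniformly without replacement; draws producing a
    fragment shorter than ``min_fragment_bp`` are rejected and redrawn.
    Each contig terminus independently receives a planted repeat array with
    probability ``plant_probability`` (the study recovered telomeres at only
    8 of 272 contig ends, so planting is sparse by design): the motif as
    given, tandem ``telomere_copies`` times, prepended at 5' termini, and
    its reverse complement appended at 3' termini.

    Returns the contig set and a truth table with columns
    ``contig_id, terminus, motif, copies`` recording exactly the planted
    termini. Stripping the planted repeats and concatenating the contigs in
    order reconstructs the genome.
    """
    if n_contigs < 1:
        raise InputError("n_contigs must be >= 1")
    if telomere_copies < 0:
        raise InputError("telomere_copies must be >= 0")
    full = "".join(genome.sequences())
    if n_contigs > len(full):
        raise InputError("n_contigs exceeds genome length")
    rng = substream_rng(seed, "fragment")

    if n_contigs == 1:
        bounds = [0, len(full)]
    else:
        for _ in range(1000):
            cuts = np.sort(rng.choice(np.arange(1, len(full)), size=n_contigs - 1, replace=False))
            bounds = [0, *cuts.tolist(), len(full)]
            if min(np.diff(bounds)) >= max(1, min_fragment_bp):
                break
        else:
            raise InputError(
                "could not draw fragment breakpoints honouring min_fragment_bp"
            )

    motif = telomere_motif.upper()
    if set(motif) - set("ACGT"):
        raise InputError("telomere_motif must be over {A,C,G,T}")
    rc_motif = reverse_complement(motif)

    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for i in range(n_contigs):
        name = f"contig_{i + 1:03d}"
        seq = full[bounds[i] : bounds[i + 1]]
        if telomere_copies > 0:
            if rng.random() < plant_probability:
                seq = motif * telomere_copies + seq
                truth_rows.append(
                    {"contig_id": name, "terminus": "5p", "motif": motif,
                     "copies": telomere_copies}
                )
            if rng.random() < plant_probability:
                seq = seq + rc_motif * telomere_copies
                truth_rows.append(
                    {"contig_id": name, "terminus": "3p", "motif": motif,
                     "copies": telomere_copies}
                )
        records.append((name, seq))

    truth = pd.DataFrame(truth_rows, columns=["contig_id", "terminus", "motif", "copies"])
    return ContigSet(records), truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSimSpec:
    """Uniform forward-strand read sampling with i.i.d. substitution errors.

    Defaults follow the short-read genome survey design (150 bp reads);
    coverage is set per experiment (the survey itself ran at ~230-fold).
    No indels and no quality model: a constant-quality FASTQ dialect.
    """

    coverage: float
    read_length_bp: int = 150
    error_rate: float = 0.0
    seed: int = 0


def simulate_reads(genome: ContigSet, spec: ReadSimSpec) -> ContigSet:
    """Sample reads from ``genome`` under ``spec``.

    The number of reads is ``round(coverage * genome_length / read_length)``.
    Read ids encode the origin (``read_N source:start``) so tests can verify
    reads against the template. Reads never span contig boundaries.
    """
    if spec.coverage <= 0:
        raise InputError("coverage must be > 0")
    if spec.read_length_bp < 1:
        raise InputError("read_length_bp must be >= 1")
    if not 0.0 <= spec.error_rate < 1.0:
        raise InputError("error_rate must lie in [0, 1)")
    L = spec.read_length_bp
    lengths = np.array(genome.lengths)
    if L > lengths.max():
        raise InputError("read length exceeds every contig length")
    rng = substream_rng(spec.seed, "reads")

    n_reads = int(round(spec.coverage * lengths.sum() / L))
    starts_per = np.maximum(lengths - L + 1, 0)
    usable = starts_per > 0
    weights = starts_per[usable] / starts_per[usable].sum()
    contig_idx = np.flatnonzero(usable)[
        rng.choice(usable.sum(), size=n_reads, p=weights)
    ]

    encode = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        encode[ord(b)] = i
    encode[ord("N")] = 4
    seq_codes = [
        encode[np.frombuffer(c.seq.encode("ascii"), dtype=np.uint8)] for c in genome
    ]

    records: list[tuple[str, str]] = []
    offsets = np.arange(L)
    for ci in np.unique(contig_idx):
        n_here = int((contig_idx == ci).sum())
        starts = rng.integers(0, starts_per[ci], size=n_here)
        block = seq_codes[ci][starts[:, None] + offsets[None, :]].copy()
        if spec.error_rate > 0:
            mask = rng.random(block.shape) < spec.error_rate
            mask &= block < 4  # leave N untouched
            shift = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
            block[mask] = (block[mask] + shift) % 4
        name = genome[int(ci)].id
        for j in range(n_here):
            row = block[j]
            seq = (
                np.where(row < 4, _BASES[np.minimum(row, 3)], ord("N"))
                .astype(np.uint8)
                .tobytes()
                .decode("ascii")
            )
            records.append((f"read_{len(records)} {name}:{int(starts[j])}", seq))
    return ContigSet(records)


# ---------------------------------------------------------------------------
# domain count simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpansionSimSpec:
    """Multi-species domain-count table with planted expansions.

    Non-expanded cells are Poisson with a rate proportional to each species'
    gene total (``baseline_rate * gene_total_s / mean(gene_totals)``);
    planted cells multiply that rate by ``fold_change`` in the focal species.
    Poisson rather than negative-binomial baseline: it matches the implicit
    count model of a Fisher 2x2 on totals; overdispersion is a possible
    config extension, not the default study condition.
    """

    n_species: int
    n_domains: int
    gene_totals: tuple[int, ...]
    baseline_rate: float
    expanded_set: dict[str, tuple[str, float]] = field(default_factory=dict)
    seed: int = 0
    species_names: tuple[str, ...] = ()

    def resolved_species(self) -> list[str]:
        if self.species_names:
            return list(self.species_names)
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


def simulate_domain_counts(
    spec: ExpansionSimSpec,
) -> tuple["pd.DataFrame", pd.Series, pd.DataFrame]:
    """Simulate a species x domain count table under ``spec``.

    Returns ``(counts, gene_totals, truth)`` where ``counts`` is a
    species x domain integer DataFrame, ``gene_totals`` a per-species Series
    and ``truth`` a table of planted expansions
    (``domain, focal_species, fold_change``). Counts are clipped at each
    species' gene total, preserving the once-per-protein invariant.
    """
    if spec.n_species < 3:
        raise InputError("n_species must be >= 3")
    if spec.n_domains < 1:
        raise InputError("n_domains must be >= 1")
    if len(spec.gene_totals) != spec.n_species:
        raise InputError("gene_totals must have one entry per species")
    if any(g < 1 for g in spec.gene_totals):
        raise InputError("gene_totals must be positive")
    if spec.baseline_rate < 0:
        raise InputError("baseline_rate must be >= 0")

    species = spec.resolved_species()
    domains = [f"PF{i + 1:05d}" for i in range(spec.n_domains)]
    domain_set = set(domains)
    for dom, (focal, fold) in spec.expanded_set.items():
        if dom not in domain_set:
            raise InputError(f"expanded domain {dom!r} outside the domain universe")
        if focal not in species:
            raise InputError(f"focal species {focal!r} unknown")
        if fold <= 1:
            raise InputError("fold_change must be > 1")

    rng = substream_rng(spec.seed, "domain-counts")
    totals = np.asarray(spec.gene_totals, dtype=float)
    rates = np.tile(
        (spec.baseline_rate * totals / totals.mean())[:, None], (1, spec.n_domains)
    )
    for dom, (focal, fold) in spec.expanded_set.items():
        rates[species.index(focal), domains.index(dom)] *= fold

    counts = rng.poisson(rates)
    counts = np.minimum(counts, np.asarray(spec.gene_totals)[:, None])
    counts_df = pd.DataFrame(counts, index=species, columns=domains)
    gene_totals = pd.Series(spec.gene_totals, index=species, name="gene_total")
    truth = pd.DataFrame(
        [
            {"domain": dom, "focal_species": focal, "fold_change": fold}
            for dom, (focal, fold) in sorted(spec.expanded_set.items())
        ],
        columns=["domain", "focal_species", "fold_change"],
    )
    return counts_df, gene_totals, truth


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    n_genes: int, n_samples: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a gene x sample count table plus per-gene transcript lengths.

    Per-gene baseline expression is log-normal (a heavy right tail, as in
    real RNA-seq), per-sample depth varies ~2-fold, and counts are Poisson
    around ``baseline * length/1kb * depth``. Lengths are uniform on
    [500, 5000] bp.
    """
    if n_genes < 1 or n_samples < 1:
        raise InputError("n_genes and n_samples must be >= 1")
    rng = substream_rng(seed, "expression")
    lengths = pd.Series(
        rng.integers(500, 5001, size=n_genes),
        index=[f"gene_{i + 1:05d}" for i in range(n_genes)],
        name="length_bp",
    )
    base = rng.lognormal(mean=1.0, sigma=1.2, size=n_genes)
    depth = rng.uniform(0.5, 2.0, size=n_samples)
    lam = base[:, None] * (lengths.to_numpy()[:, None] / 1000.0) * depth[None, :]
    counts = pd.DataFrame(
        rng.poisson(lam),
        index=lengths.index,
        columns=[f"sample_{j + 1:02d}" for j in range(n_samples)],
    )
    return counts, lengths


# ---------------------------------------------------------------------------
# truth-table I/O (TSV dialects shared with the CLI)
# ---------------------------------------------------------------------------


def write_telomere_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_expansion_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
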