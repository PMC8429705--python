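"""Assembly contiguity/composition statistics and terminal telomere scanning.

``contig_stats`` reproduces the standard assembly-report quantities
(N50/L50, Nx curve, GC%, extreme contig lengths, size-class summary);
``scan_telomeres`` looks for tandem arrays of a telomeric motif — TTAGG,
the ancestral insect telomere repeat, by default — near contig termini,
the desk-scale equivalent of running a telomere finder over an assembly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contigs import ContigSet
from .exceptions import InputError
from ._util import reverse_complement

DEFAULT_SIZE_THRESHOLDS = (10_000, 100_000, 1_000_000, 10_000_000)


# ---------------------------------------------------------------------------
# contiguity / composition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssemblyStats:
    total_length_bp: int
    n_contigs: int
    n50_bp: int
    l50: int
    nx_curve: dict[int, int]
    max_contig_bp: int
    min_contig_bp: int
    gc_percent: float
    size_class_summary: dict[int, tuple[int, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_length_bp", self.total_length_bp),
            ("n_contigs", self.n_contigs),
            ("n50_bp", self.n50_bp),
            ("l50", self.l50),
            ("max_contig_bp", self.max_contig_bp),
            ("min_contig_bp", self.min_contig_bp),
            ("gc_percent", round(self.gc_percent, 2)),
        ]
        for x, v in self.nx_curve.items():
            rows.append((f"n{x}_bp", v))
        for thr, (count, frac) in self.size_class_summary.items():
            rows.append((f"contigs_ge_{thr}bp", count))
            rows.append((f"fraction_ge_{thr}bp", round(frac, 4)))
        return pd.DataFrame(rows, columns=["statistic", "value"])

    def format_table(self) -> str:
        """Assembly-report style aligned text block."""
        lines = [
            ("Genome size (Mb)", f"{self.total_length_bp / 1e6:.2f}"),
            ("Number of contigs", f"{self.n_contigs:,}"),
            ("Contig N50 (Mb)", f"{self.n50_bp / 1e6:.2f}"),
            ("Contig L50", f"{self.l50:,}"),
            ("Max. contig length (Mb)", f"{self.max_contig_bp / 1e6:.2f}"),
            ("Min. contig length (kb)", f"{self.min_contig_bp / 1e3:.2f}"),
            ("GC (%)", f"{self.gc_percent:.2f}"),
        ]
        for thr, (count, frac) in self.size_class_summary.items():
            lines.append(
                (f"Contigs >= {thr:,} bp", f"{count:,} ({100 * frac:.0f}% of assembly)")
            )
        width = max(len(k) for k, _ in lines)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in lines)


def _nx(sorted_desc: np.ndarray, cumulative: np.ndarray, total: int, x: int) -> tuple[int, int]:
    """(Nx length, Lx count): first contig where the cumulative sum reaches
    >= x% of the total, under the >= tie convention of common assemblers."""
    target = total * x / 100.0
    idx = int(np.searchsorted(cumulative, target, side="left"))
    return int(sorted_desc[idx]), idx + 1


def contig_stats(
    contigs: ContigSet, size_thresholds: Sequence[int] = DEFAULT_SIZE_THRESHOLDS
) -> AssemblyStats:
    """Compute assembly statistics for a contig set.

    GC% is ``100 * (G+C) / (A+C+G+T)`` — N bases are excluded from the
    denominator so the figure reflects composition only.
    """
    lengths = np.array(contigs.lengths)
    total = int(lengths.sum())
    desc = np.sort(lengths)[::-1]
    cum = np.cumsum(desc)

    n50, l50 = _nx(desc, cum, total, 50)
    nx_curve = {x: _nx(desc, cum, total, x)[0] for x in range(10, 100, 10)}

    counts = {b: 0 for b in "ACGTN"}
    for seq in contigs.sequences():
        for b in counts:
            counts[b] += seq.count(b)
    acgt = sum(counts[b] for b in "ACGT")
    if acgt == 0:
        raise InputError("assembly contains no A/C/G/T bases; GC% undefined")
    gc_percent = 100.0 * (counts["G"] + counts["C"]) / acgt

    size_summary = {}
    for thr in sorted(size_thresholds):
        mask = lengths >= thr
        size_summary[int(thr)] = (int(mask.sum()), float(lengths[mask].sum() / total))

    return AssemblyStats(
        total_length_bp=total,
        n_contigs=len(contigs),
        n50_bp=n50,
        l50=l50,
        nx_curve=nx_curve,
        max_contig_bp=int(desc[0]),
        min_contig_bp=int(desc[-1]),
        gc_percent=gc_percent,
        size_class_summary=size_summary,
    )


# ---------------------------------------------------------------------------
# telomere scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TelomereHit:
    contig_id: str
    terminus: str  # "5p" | "3p"
    strand: str  # "forward" | "reverse"
    motif: str
    tandem_copies: int
    offset_bp: int  # 0-based distance from the terminus inward to the array


@dataclass(frozen=True)
class TelomereScanSummary:
    n_contigs_with_hits: int
    n_forward: int
    n_reverse: int
    hits: tuple[TelomereHit, ...] = field(repr=False, default=())

    def format_line(self) -> str:
        return (
            f"Telomeric motifs at the ends of {self.n_contigs_with_hits} contigs "
            f"({self.n_forward} forward strands, {self.n_reverse} reverse strands)"
        )


def scan_telomeres(
    contigs: ContigSet,
    motif: str = "TTAGG",
    min_copies: int = 5,
    window_bp: int = 1000,
) -> tuple[list[TelomereHit], TelomereScanSummary]:
    """Find tandem telomere-repeat arrays near contig termini.

    A hit is at least ``min_copies`` exact tandem copies of the motif
    (forward strand) or of its reverse complement (reverse strand) whose
    terminus-proximal end starts within ``window_bp`` of a contig terminus.
    At most one hit is reported per (contig, terminus), keeping the highest
    copy count. Only exact copies count; degenerate repeats are ignored.
    """
    motif = motif.upper()
    if len(motif) < 2:
        raise InputError("motif length must be >= 2")
    if set(motif) - set("ACGT"):
        raise InputError("motif must be over {A,C,G,T}")
    if min_copies < 1:
        raise InputError("min_copies must be >= 1")
    if window_bp < min_copies * len(motif):
        raise InputError("window_bp must be >= min_copies * len(motif)")

    rc = reverse_complement(motif)
    patterns = [(motif, "forward")]
    if rc != motif:
        patterns.append((rc, "reverse"))

    best: dict[tuple[str, str], TelomereHit] = {}
    for contig in contigs:
        L = len(contig.seq)
        for pat, strand in patterns:
            regex = re.compile(f"(?:{pat}){{{min_copies},}}")
            for m in regex.finditer(contig.seq):
                copies = (m.end() - m.start()) // len(pat)
                candidates = [
                    (terminus, offset)
                    for terminus, offset in (("5p", m.start()), ("3p", L - m.end()))
                    if offset < window_bp
                ]
                if len(candidates) == 2:
                    # short contig: the array qualifies for both termini;
                    # assign it to the nearer one (tie -> 5p)
                    candidates = [min(candidates, key=lambda t: (t[1], t[0]))]
                for terminus, offset in candidates:
                    key = (contig.id, terminus)
                    hit = TelomereHit(
                        contig_id=contig.id,
                        terminus=terminus,
                        strand=strand,
                        motif=motif,
                        tandem_copies=copies,
                        offset_bp=offset,
                    )
                    if key not in best or copies > best[key].tandem_copies:
                        best[key] = hit

    order = {cid: i for i, cid in enumerate(contigs.ids)}
    hits = sorted(
        best.values(), key=lambda h: (order[h.contig_id], h.terminus)
    )
    summary = TelomereScanSummary(
        n_contigs_with_hits=len({h.contig_id for h in hits}),
        n_forward=sum(h.strand == "forward" for h in hits),
        n_reverse=sum(h.strand == "reverse" for h in hits),
        hits=tuple(hits),
    )
    return hits, summary


def telomere_hits_frame(hits: Iterable[TelomereHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": h.contig_id,
                "terminus": h.terminus,
                "strand": h.strand,
                "motif": h.motif,
                "copies": h.tandem_copies,
                "offset": h.offset_bp,
            }
            for h in hits
        ],
        columns=["contig_id", "terminus", "strand", "motif", "copies", "offset"],
    )
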