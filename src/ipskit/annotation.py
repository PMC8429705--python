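"""Gene-model summary statistics from GFF3 (gene + exon features).

Coordinates are 1-based inclusive; gene length is ``end - start + 1``;
introns are the gaps between a gene's exons after merging overlapping exon
intervals (isoforms may tile the same stretch); CDS features are ignored.
Printed averages follow the integer-table convention: nearest integer,
ties away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd

from .exceptions import DataError, InputError
from ._util import round_half_away


@dataclass(frozen=True)
class AnnotationStats:
    n_genes: int
    total_gene_length_bp: int
    avg_gene_length_bp: int
    pct_genome_covered: int
    longest_gene_bp: Optional[int] = None
    avg_exon_length_bp: Optional[int] = None
    avg_intron_length_bp: Optional[int] = None
    avg_exons_per_gene: Optional[int] = None
    avg_introns_per_gene: Optional[int] = None

    @classmethod
    def from_totals(
        cls, n_genes: int, total_gene_length_bp: int, genome_length_bp: int
    ) -> "AnnotationStats":
        """Summary from aggregate totals alone (no per-gene records).

        Supports the common situation where only an annotation report's
        totals are available: average gene length and percent genome
        coverage are fully determined by them.
        """
        if n_genes < 1:
            raise InputError("n_genes must be >= 1")
        if genome_length_bp < 1:
            raise InputError("genome_length_bp must be >= 1")
        return cls(
            n_genes=n_genes,
            total_gene_length_bp=total_gene_length_bp,
            avg_gene_length_bp=round_half_away(total_gene_length_bp / n_genes),
            pct_genome_covered=round_half_away(
                100.0 * total_gene_length_bp / genome_length_bp
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.__dict__.items() if v is not None]
        return pd.DataFrame(rows, columns=["statistic", "value"])

    def format_table(self) -> str:
        labels = {
            "n_genes": "Number of genes",
            "total_gene_length_bp": "Total gene length (bp)",
            "longest_gene_bp": "Longest gene (bp)",
            "avg_gene_length_bp": "Average gene length (bp)",
            "avg_exon_length_bp": "Average exon length (bp)",
            "avg_intron_length_bp": "Average intron length (bp)",
            "pct_genome_covered": "% of genome covered by genes",
            "avg_exons_per_gene": "Average exons per gene",
            "avg_introns_per_gene": "Average introns per gene",
        }
        lines = [
            (labels[k], f"{v:,}")
            for k, v in self.__dict__.items()
            if v is not None and k in labels
        ]
        width = max(len(k) for k, _ in lines)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in lines)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def annotation_stats(gff3_path: str | Path, genome_length_bp: int) -> AnnotationStats:
    """Compute gene-model statistics from a GFF3 file."""
    if genome_length_bp < 1:
        raise InputError("genome_length_bp must be >= 1")
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    gene_lengths: list[int] = []
    exon_lengths: list[int] = []
    intron_lengths: list[int] = []
    n_exons = 0
    n_introns = 0
    n_genes = 0
    for gene in db.features_of_type("gene"):
        n_genes += 1
        gene_lengths.append(gene.end - gene.start + 1)
        exon_ivals: list[tuple[int, int]] = []
        for exon in db.children(gene, featuretype="exon"):
            if exon.start < gene.start or exon.end > gene.end:
                raise DataError(
                    f"exon {exon.id or exon.attributes.get('ID', ['?'])[0]!s} "
                    f"({exon.seqid}:{exon.start}-{exon.end}) lies outside its gene "
                    f"{gene.id} ({gene.seqid}:{gene.start}-{gene.end})"
                )
            exon_lengths.append(exon.end - exon.start + 1)
            n_exons += 1
            exon_ivals.append((exon.start, exon.end))
        merged = _merge_intervals(exon_ivals)
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            intron_lengths.append(s2 - e1 - 1)
            n_introns += 1
    if n_genes == 0:
        raise InputError(f"no gene features found in {gff3_path}")

    total = sum(gene_lengths)

    def avg(values: list[int]) -> Optional[int]:
        return round_half_away(sum(values) / len(values)) if values else 0

    return AnnotationStats(
        n_genes=n_genes,
        total_gene_length_bp=total,
        avg_gene_length_bp=round_half_away(total / n_genes),
        pct_genome_covered=round_half_away(100.0 * total / genome_length_bp),
        longest_gene_bp=max(gene_lengths),
        avg_exon_length_bp=avg(exon_lengths),
        avg_intron_length_bp=avg(intron_lengths),
        avg_exons_per_gene=round_half_away(n_exons / n_genes),
        avg_introns_per_gene=round_half_away(n_introns / n_genes),
    )


def write_gff3(
    genes: Iterable[tuple[str, str, int, int, list[tuple[int, int]]]],
    path: str | Path,
) -> None:
    """Write gene/exon records as GFF3.

    ``genes`` is an iterable of ``(seqid, gene_id, start, end, exons)`` with
    1-based inclusive coordinates and ``exons`` a list of (start, end).
    The module's own reader round-trips this dialect unchanged.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, gene_id, start, end, exons in genes:
            fh.write(
                f"{seqid}\tipskit\tgene\t{start}\t{end}\t.\t+\t.\tID={gene_id}\n"
            )
            for i, (es, ee) in enumerate(exons, 1):
                fh.write(
                    f"{seqid}\tipskit\texon\t{es}\t{ee}\t.\t+\t.\t"
                    f"ID={gene_id}.exon{i};Parent={gene_id}\n"
                )
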