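"""Ordered, named nucleotide sequence sets (contigs or reads) with FASTA/FASTQ I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InputError
from ._util import reverse_complement

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


class ContigSet:
    """Ordered collection of uniquely named sequences over {A,C,G,T,N}.

    The unit of assembly QC, telomere scanning and read simulation.
    Sequences are upper-cased on construction; empty sequences and duplicate
    ids are rejected.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        self._contigs: list[Contig] = []
        seen: set[str] = set()
        for name, seq in records:
            if not seq:
                raise InputError(f"contig {name!r} has an empty sequence")
            if name in seen:
                raise InputError(f"duplicate contig id {name!r}")
            seq = seq.upper()
            extra = set(seq) - _ALPHABET
            if extra:
                raise InputError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(extra)}"
                )
            seen.add(name)
            self._contigs.append(Contig(name, seq))
        if not self._contigs:
            raise InputError("a ContigSet needs at least one sequence")

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def __getitem__(self, key: int | str) -> Contig:
        if isinstance(key, str):
            for c in self._contigs:
                if c.id == key:
                    return c
            raise KeyError(key)
        return self._contigs[key]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self._contigs]

    @property
    def lengths(self) -> list[int]:
        return [len(c) for c in self._contigs]

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def sequences(self) -> list[str]:
        return [c.seq for c in self._contigs]

    def reverse_complement(self) -> "ContigSet":
        return ContigSet((c.id, reverse_complement(c.seq)) for c in self._contigs)

    # ---- I/O ------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ContigSet":
        records = SeqIO.parse(str(path), "fasta")
        pairs = [(r.id, str(r.seq)) for r in records]
        if not pairs:
            raise InputError(f"no FASTA records found in {path}")
        return cls(pairs)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ContigSet":
        pairs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]
        if not pairs:
            raise InputError(f"no FASTQ records found in {path}")
        return cls(pairs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ContigSet":
        """Sniff FASTA vs FASTQ from the first byte."""
        with open(path) as fh:
            first = fh.read(1)
        if first == "@":
            return cls.from_fastq(path)
        return cls.from_fasta(path)

    def to_fasta(self, path: str | Path, wrap: int = 80) -> None:
        records = [
            SeqRecord(Seq(c.seq), id=c.id, description="") for c in self._contigs
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
            writer.write_file(records)

    def to_fastq(self, path: str | Path, quality_char: str = "I") -> None:
        qual = ord(quality_char) - 33
        records = []
        for c in self._contigs:
            rec = SeqRecord(Seq(c.seq), id=c.id, description="")
            rec.letter_annotations["phred_quality"] = [qual] * len(c.seq)
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")
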