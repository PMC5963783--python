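"""Domain types and readers/writers for FASTA, FASTQ and TSV tables.

Reference transcripts are single-stranded cDNA in sense orientation, strict
ACGT; sequencing reads may carry N. Gene labels ride in FASTA headers as a
``gene=`` token so the reference database stays self-contained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

_DNA_RE = re.compile(r"^[ACGT]+$")
_READ_RE = re.compile(r"^[ACGTN]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Transcript:
    """A polyadenylated cDNA sequence with a gene label."""

    id: str
    gene_label: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValidationError(f"transcript {self.id}: empty sequence")
        if not _DNA_RE.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGT"))
            raise ValidationError(
                f"transcript {self.id}: non-ACGT characters {bad} in reference sequence"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


class FastqRead(NamedTuple):
    id: str
    seq: str
    qual: str

    @property
    def has_n(self) -> bool:
        return "N" in self.seq


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (complement of N is N)."""
    if seq and not _READ_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValidationError(f"cannot reverse-complement characters {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def _gene_label(record: SeqRecord) -> str:
    for token in record.description.split():
        if token.startswith("gene="):
            return token[len("gene="):]
    return record.id


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read reference transcripts; gene label from a ``gene=`` header token."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"FASTA file not found: {path}")
    out: list[Transcript] = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            seq = str(record.seq).upper()
            out.append(Transcript(id=record.id, gene_label=_gene_label(record), seq=seq))
    except ValueError as exc:  # malformed record
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.seq), id=t.id, description=f"gene={t.gene_label}")
        for t in transcripts
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Lazily stream reads; N bases are preserved.

    Truncated records and sequence/quality length mismatches raise
    :class:`ParseError` carrying the record index.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"FASTQ file not found: {path}")

    def _gen() -> Iterator[FastqRead]:
        index = 0
        parser = SeqIO.parse(str(path), "fastq")
        while True:
            try:
                record = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(f"{path}: record {index}: {exc}") from exc
            seq = str(record.seq).upper()
            if not _READ_RE.match(seq):
                raise ParseError(
                    f"{path}: record {index}: non-ACGTN characters in read {record.id}"
                )
            qual = "".join(chr(q + 33) for q in record.letter_annotations["phred_quality"])
            yield FastqRead(record.id, seq, qual)
            index += 1

    return _gen()


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")
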