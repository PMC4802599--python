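"""Small shared helpers: sequence arithmetic and FASTA/FASTQ round-trip IO.

Coordinates are 0-based half-open everywhere inside the package; 1-based
positions appear only in human-readable reports (degradome cleavage sites,
GFF-style exports say so explicitly).
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned as DNA)."""
    return seq.translate(_COMPLEMENT)[::-1]


def as_dna(seq: str) -> str:
    """Uppercase and convert U->T so RNA and DNA inputs compare equal."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (DNA alphabet)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = as_dna(str(rec.seq))
    return records


def read_fasta_with_descriptions(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """Read FASTA as (id, description-after-id, sequence), order preserved."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append((rec.id, desc, as_dna(str(rec.seq))))
    return out


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write (header, sequence) pairs; header may contain a description."""
    recs = []
    for header, seq in records:
        name, _, desc = header.partition(" ")
        recs.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(recs, str(path), "fasta")


def iter_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, phred qualities) from a FASTQ file.

    Malformed records raise ValueError identifying the record index.
    """
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            yield rec.id, as_dna(str(rec.seq)), rec.letter_annotations["phred_quality"]
    except ValueError as exc:  # Biopython raises on malformed records
        raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


def write_fastq(
    path: str | os.PathLike, records: Iterable[tuple[str, str, int]]
) -> None:
    """Write (id, sequence, uniform phred quality) records."""
    recs = []
    for name, seq, qual in records:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [qual] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")
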