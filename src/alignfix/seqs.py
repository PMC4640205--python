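"""Small nucleotide/protein sequence helpers shared across the package.

All sequences are plain Python strings, uppercase, over {A,C,G,T,N} for DNA
(U is normalised to T on input) and the 20 amino acids plus X/* for protein.
Coordinates are 0-based half-open internally; 1-based inclusive only in
external files and logs (the tabular-hit convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.Seq import Seq
from Bio.SeqIO import parse as _fasta_parse
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

_DNA_OK = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed input sequences."""


def normalize_dna(seq: str, *, context: str = "") -> str:
    """Uppercase, U→T, and validate the {A,C,G,T,N} alphabet."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise SequenceError(f"empty sequence {context}")
    bad = set(s) - _DNA_OK
    if bad:
        raise SequenceError(f"invalid DNA characters {sorted(bad)} {context}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate in frame 0; trailing partial codon ignored; ambiguous codons → X."""
    n = len(dna) - len(dna) % 3
    return str(Seq(dna[:n]).translate())


def six_frame_translations(dna: str) -> list[tuple[int, str]]:
    """(frame, peptide) for frames +1..+3, -1..-3 (BLAST frame convention)."""
    out = []
    rc = revcomp(dna)
    for off in range(3):
        out.append((off + 1, translate(dna[off:])))
        out.append((-(off + 1), translate(rc[off:])))
    return out


@dataclass(frozen=True)
class Transcript:
    """A nucleotide query sequence (assembled transcript, EST or contig)."""

    id: str
    sequence: str

    @classmethod
    def from_raw(cls, id: str, sequence: str) -> "Transcript":
        return cls(id=id, sequence=normalize_dna(sequence, context=f"in transcript {id!r}"))

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[Transcript]:
    """Read a nucleotide FASTA into Transcripts; ids must be unique."""
    seen: set[str] = set()
    out: list[Transcript] = []
    for rec in _fasta_parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(Transcript.from_raw(rec.id, str(rec.seq)))
    return out


def write_fasta(path, records: Iterable[tuple[str, str]]) -> int:
    """Write (id, sequence) pairs as 60-column-wrapped FASTA; returns count."""
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    return SeqIO.write(recs, str(path), "fasta")


def iter_fasta(path) -> Iterator[tuple[str, str]]:
    for rec in _fasta_parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()
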