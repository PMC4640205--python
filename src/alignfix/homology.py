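"""Homology-search results and putative coding-region identification.

A transcript is declared protein-coding when its best translated-search hit
against a protein database reaches an e-value of 1e-3 or better.  The
putative ORF then spans from the earliest start to the furthest end over all
HSPs of that top hit, even when the HSPs do not overlap (a frame-shift in
the transcript typically splits one protein hit into two HSPs in different
frames).  Candidate homologs for the gap analysis come from a nucleotide
search against a database of in-frame coding sequences at e ≤ 1e-10.

Search execution itself (external BLAST+ or the internal seeded-alignment
fallback) lives in :mod:`alignfix.search`; this module owns the data model
and the decisions made on top of the hits.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .seqs import Transcript, iter_fasta, normalize_dna, revcomp, translate, write_fasta

log = logging.getLogger(__name__)

DEFAULT_PROTEIN_EVALUE = 1e-3
DEFAULT_NUCLEOTIDE_EVALUE = 1e-10
DEFAULT_K_HOMOLOGS = 3


class HitTableError(ValueError):
    """Raised for unparseable hit-table rows."""


@dataclass(frozen=True)
class Hsp:
    """One high-scoring segment pair, coordinates 1-based inclusive.

    ``query_start <= query_end`` always (plus-strand representation); the
    strand of the hit is carried by the sign of ``frame``.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    frame: int
    evalue: float
    bit_score: float

    @property
    def strand(self) -> str:
        return "-" if self.frame < 0 else "+"

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass
class HomologyHit:
    """All HSPs of one query/subject pair from a single search."""

    subject_id: str
    subject_kind: str  # "protein" | "nucleotide"
    hsps: list[Hsp]
    subject_seq: Optional[str] = None  # filled in by the search engine

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.hsps)

    @property
    def total_bit_score(self) -> float:
        return sum(h.bit_score for h in self.hsps)

    @property
    def best_hsp(self) -> Hsp:
        return min(self.hsps, key=lambda h: (h.evalue, -h.bit_score))


@dataclass
class CodingRegion:
    """The putative ORF span on the working (plus-orientated) sequence.

    ``start``/``end`` are 1-based inclusive on ``working_sequence``, which is
    the transcript itself for plus-strand hits and its reverse complement for
    minus-strand hits.
    """

    transcript_id: str
    start: int
    end: int
    strand: str
    origin: str  # "merged_hsps" | "top_hsp"
    top_hit_id: str
    top_hit_protein: str
    working_sequence: str
    top_hsp_start: int  # span of the single best HSP, for the fallback ORF
    top_hsp_end: int

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:  # half-open
        return self.end

    def region_sequence(self) -> str:
        return self.working_sequence[self.start0 : self.end0]

    def top_hsp_sequence(self) -> str:
        return self.working_sequence[self.top_hsp_start - 1 : self.top_hsp_end]


@dataclass(frozen=True)
class Homolog:
    """A nucleotide homolog oriented co-directionally with the working sequence."""

    id: str
    sequence: str


def sort_hits(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Best-first ordering: e-value asc, summed bit score desc, subject id."""
    return sorted(hits, key=lambda h: (h.best_evalue, -h.total_bit_score, h.subject_id))


def _remap_hsp_minus(h: Hsp, length: int) -> Hsp:
    """Remap plus-strand query coordinates onto the reverse complement."""
    return Hsp(
        query_start=length - h.query_end + 1,
        query_end=length - h.query_start + 1,
        subject_start=h.subject_start,
        subject_end=h.subject_end,
        frame=h.frame,
        evalue=h.evalue,
        bit_score=h.bit_score,
    )


def identify_coding_region(
    transcript: Transcript,
    protein_hits: list[HomologyHit],
    evalue_threshold: float = DEFAULT_PROTEIN_EVALUE,
) -> Optional[CodingRegion]:
    """Decide whether the transcript is protein coding and locate its ORF.

    Returns ``None`` when no hit reaches ``evalue_threshold``.  For the top
    hit, HSP query spans are merged from the earliest start to the furthest
    end; HSPs on the opposite strand from the best-scoring HSP are ignored.
    Minus-strand hits flip the working sequence to the reverse complement
    and remap all coordinates onto it.
    """
    length = len(transcript)
    for hit in sort_hits(protein_hits):
        malformed = [h for h in hit.hsps if h.query_end < h.query_start]
        if malformed:
            log.warning(
                "transcript %s: rejecting malformed hit %s (end < start)",
                transcript.id,
                hit.subject_id,
            )
            continue
        if hit.best_evalue > evalue_threshold:
            return None  # hits are sorted: nothing better follows
        best = hit.best_hsp
        strand = best.strand
        same_strand = [h for h in hit.hsps if h.strand == strand]
        if strand == "-":
            working = revcomp(transcript.sequence)
            same_strand = [_remap_hsp_minus(h, length) for h in same_strand]
            best = _remap_hsp_minus(best, length)
        else:
            working = transcript.sequence
        start = min(h.query_start for h in same_strand)
        end = max(h.query_end for h in same_strand)
        return CodingRegion(
            transcript_id=transcript.id,
            start=start,
            end=end,
            strand=strand,
            origin="merged_hsps" if len(same_strand) > 1 else "top_hsp",
            top_hit_id=hit.subject_id,
            top_hit_protein=hit.subject_seq or "",
            working_sequence=working,
            top_hsp_start=best.query_start,
            top_hsp_end=best.query_end,
        )
    return None


def select_homologs(
    transcript: Transcript,
    nucleotide_hits: list[HomologyHit],
    k: int = DEFAULT_K_HOMOLOGS,
    evalue_threshold: float = DEFAULT_NUCLEOTIDE_EVALUE,
    working_strand: str = "+",
) -> list[Homolog]:
    """Pick up to ``k`` coding-sequence homologs at e ≤ ``evalue_threshold``.

    Returned homologs are oriented co-directionally with the working
    sequence: a subject hit on the opposite strand of the transcript is
    reverse-complemented, and everything is flipped once more when the
    working sequence itself is the reverse complement of the transcript.
    Fewer than ``k`` results (including none) is a valid outcome.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: list[Homolog] = []
    for hit in sort_hits(nucleotide_hits):
        if len(out) >= k:
            break
        if hit.best_evalue > evalue_threshold:
            break
        if hit.subject_seq is None:
            log.warning("homolog %s not retrievable from database; skipping", hit.subject_id)
            continue
        seq = hit.subject_seq
        hit_strand = hit.best_hsp.strand
        if hit_strand != working_strand:
            seq = revcomp(seq)
        out.append(Homolog(id=hit.subject_id, sequence=seq))
    return out


# ---------------------------------------------------------------------------
# hit tables


_TABULAR_COLUMNS = 12  # std outfmt-6; optional 13th column = query frame


def _parse_tabular_row(fields: list[str], lineno: int) -> tuple[str, str, Hsp]:
    if len(fields) < _TABULAR_COLUMNS:
        raise HitTableError(f"line {lineno}: expected >= {_TABULAR_COLUMNS} columns, got {len(fields)}")
    try:
        qid, sid = fields[0], fields[1]
        qstart, qend = int(fields[6]), int(fields[7])
        sstart, send = int(fields[8]), int(fields[9])
        evalue = float(fields[10])
        bits = float(fields[11])
        frame = int(fields[12]) if len(fields) > _TABULAR_COLUMNS else 0
    except ValueError as exc:
        raise HitTableError(f"line {lineno}: {exc}") from exc
    if frame == 0:
        # infer orientation: nucleotide hits flag minus strand via subject coords
        frame = -1 if (qstart > qend or sstart > send) else 1
    if frame > 0 and qstart > qend:
        raise HitTableError(f"line {lineno}: query_start > query_end on plus frame")
    if qstart > qend:
        qstart, qend = qend, qstart
    if evalue < 0:
        raise HitTableError(f"line {lineno}: negative e-value")
    return qid, sid, Hsp(qstart, qend, min(sstart, send), max(sstart, send), frame, evalue, bits)


def load_hit_table(path, dialect: str = "tabular", subject_kind: str = "nucleotide") -> dict[str, list[HomologyHit]]:
    """Load pre-computed hits keyed by transcript id.

    ``dialect`` is ``tabular`` (12-column outfmt-6 plus an optional frame
    column) or ``xml`` (NCBI BlastOutput).  Rows that violate the HSP
    invariants raise :class:`HitTableError` naming the offending line.
    """
    path = Path(path)
    grouped: dict[str, dict[str, HomologyHit]] = {}

    def add(qid: str, sid: str, hsp: Hsp) -> None:
        bucket = grouped.setdefault(qid, {})
        if sid not in bucket:
            bucket[sid] = HomologyHit(subject_id=sid, subject_kind=subject_kind, hsps=[])
        bucket[sid].hsps.append(hsp)

    if dialect == "tabular":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                qid, sid, hsp = _parse_tabular_row(line.split("\t"), lineno)
                add(qid, sid, hsp)
    elif dialect == "xml":
        from Bio import SearchIO

        for qresult in SearchIO.parse(str(path), "blast-xml"):
            for hit in qresult:
                for hsp in hit.hsps:
                    frame = getattr(hsp, "query_frame", 1) or 1
                    add(
                        qresult.id,
                        hit.id,
                        Hsp(
                            query_start=hsp.query_start + 1,
                            query_end=hsp.query_end,
                            subject_start=hsp.hit_start + 1,
                            subject_end=hsp.hit_end,
                            frame=frame,
                            evalue=hsp.evalue,
                            bit_score=hsp.bitscore,
                        ),
                    )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return {qid: sort_hits(list(bucket.values())) for qid, bucket in grouped.items()}


# ---------------------------------------------------------------------------
# reference databases


@dataclass
class DatabaseBundle:
    """Cleaned reference databases plus (optional) external BLAST indexes."""

    protein_fasta: Path
    nucleotide_fasta: Path
    proteins: dict[str, str]
    nucleotides: dict[str, str]
    blast_protein_db: Optional[Path] = None
    blast_nucleotide_db: Optional[Path] = None
    report: dict = field(default_factory=dict)


def prepare_reference_db(
    cds_fasta,
    proteins_fasta,
    out_dir,
    run_makeblastdb: Optional[bool] = None,
) -> DatabaseBundle:
    """Clean and index the reference databases.

    CDS entries must be in-frame coding sequences: records not beginning
    with ATG are dropped, as are records whose length is not a multiple of
    three (codon phase at any position must equal position mod 3).  When the
    external ``makeblastdb`` binary is available the cleaned FASTAs are
    indexed with sequence-id parsing enabled; a flat JSON index for the
    internal search fallback is always written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    kept: dict[str, str] = {}
    dropped: dict[str, str] = {}
    for sid, seq in iter_fasta(cds_fasta):
        seq = normalize_dna(seq, context=f"in CDS {sid!r}")
        if not seq.startswith("ATG"):
            dropped[sid] = "no ATG start"
        elif len(seq) % 3 != 0:
            dropped[sid] = "not in frame"
        else:
            kept[sid] = seq
    if not kept:
        raise ValueError("no usable coding sequences after filtering (empty database)")

    proteins = {sid: seq for sid, seq in iter_fasta(proteins_fasta)}
    if not proteins:
        raise ValueError("empty protein database")

    nucl_path = out_dir / "cds.clean.fasta"
    prot_path = out_dir / "proteins.fasta"
    write_fasta(nucl_path, kept.items())
    write_fasta(prot_path, proteins.items())

    report = {
        "cds_kept": len(kept),
        "cds_dropped": len(dropped),
        "cds_drop_reasons": dropped,
        "proteins": len(proteins),
    }
    (out_dir / "index.json").write_text(json.dumps(report, indent=1))

    bundle = DatabaseBundle(
        protein_fasta=prot_path,
        nucleotide_fasta=nucl_path,
        proteins=proteins,
        nucleotides=kept,
        report=report,
    )

    if run_makeblastdb is None:
        run_makeblastdb = shutil.which("makeblastdb") is not None
    if run_makeblastdb:
        for path, dbtype, attr in (
            (prot_path, "prot", "blast_protein_db"),
            (nucl_path, "nucl", "blast_nucleotide_db"),
        ):
            subprocess.run(
                ["makeblastdb", "-in", str(path), "-dbtype", dbtype, "-parse_seqids"],
                check=True,
                capture_output=True,
            )
            setattr(bundle, attr, path)
    return bundle


def translated_protein_db(nucleotides: dict[str, str]) -> dict[str, str]:
    """Convenience: translate an in-frame CDS set into a protein set."""
    out = {}
    for sid, seq in nucleotides.items():
        prot = translate(seq).rstrip("*")
        if prot:
            out[sid] = prot
    return out
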