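"""Homology-search execution: external BLAST+ or an internal fallback.

Both engines return the same structures (``{transcript_id: [HomologyHit]}``)
so everything downstream is agnostic to how hits were produced.  The
external path shells out to NCBI BLAST+ (``blastx``/``blastn``) on databases
indexed by :func:`alignfix.homology.prepare_reference_db`.  The internal
fallback performs a translated search by six-frame translation plus seeded
local alignment against the protein set, and a nucleotide search by seeded
local DNA alignment, with Karlin–Altschul e-values computed from the
database size, so the whole pipeline can run without any external binary.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol

from Bio import Align

from .homology import DatabaseBundle, HomologyHit, Hsp, sort_hits
from .seqs import Transcript, revcomp, six_frame_translations, write_fasta

log = logging.getLogger(__name__)

# Gapped Karlin-Altschul parameters for the internal fallback's scoring
# systems: BLOSUM62 with open/extend 11/1 (protein) and match/mismatch 2/-3
# with open/extend 5/2 (nucleotide) -- the standard published values.
PROTEIN_LAMBDA, PROTEIN_K = 0.267, 0.041
NUCLEOTIDE_LAMBDA, NUCLEOTIDE_K = 0.625, 0.41

PROTEIN_WORD_SIZE = 4
NUCLEOTIDE_WORD_SIZE = 11


class SearchEngine(Protocol):
    def search_protein(self, transcripts: list[Transcript]) -> dict[str, list[HomologyHit]]: ...

    def search_nucleotide(self, transcripts: list[Transcript]) -> dict[str, list[HomologyHit]]: ...


def blast_available() -> bool:
    return all(shutil.which(b) for b in ("blastx", "blastn", "makeblastdb"))


def get_engine(
    bundle: DatabaseBundle,
    engine: str = "auto",
    fast: bool = False,
    threads: int = 1,
    protein_evalue: float = 1e-3,
    nucleotide_evalue: float = 1e-10,
) -> SearchEngine:
    if engine == "auto":
        engine = "blast" if blast_available() else "internal"
    if engine == "blast":
        return BlastEngine(bundle, fast=fast, threads=threads,
                           protein_evalue=protein_evalue, nucleotide_evalue=nucleotide_evalue)
    if engine == "internal":
        return InternalEngine(bundle, fast=fast,
                              protein_evalue=protein_evalue, nucleotide_evalue=nucleotide_evalue)
    raise ValueError(f"unknown search engine {engine!r}")


# ---------------------------------------------------------------------------
# external BLAST+


@dataclass
class BlastEngine:
    """Thin wrapper over blastx/blastn with tabular output parsing."""

    bundle: DatabaseBundle
    fast: bool = False
    threads: int = 1
    protein_evalue: float = 1e-3
    nucleotide_evalue: float = 1e-10
    save_xml_to: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.bundle.blast_protein_db is None or self.bundle.blast_nucleotide_db is None:
            raise ValueError("database bundle has no BLAST indexes; run prepare_reference_db "
                             "with makeblastdb available, or use the internal engine")

    def _run(self, prog: str, db: Path, transcripts: list[Transcript], evalue: float,
             extra: list[str]) -> str:
        with tempfile.TemporaryDirectory(prefix="alignfix_blast_") as tmp:
            query = Path(tmp) / "query.fasta"
            write_fasta(query, ((t.id, t.sequence) for t in transcripts))
            cmd = [prog, "-query", str(query), "-db", str(db),
                   "-outfmt", "6 std qframe", "-evalue", f"{evalue:g}",
                   "-num_threads", str(self.threads)] + extra
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(f"{prog} failed: {proc.stderr.strip()}")
            if self.save_xml_to is not None and prog == "blastx":
                cmd_xml = [prog, "-query", str(query), "-db", str(db),
                           "-outfmt", "5", "-evalue", f"{evalue:g}",
                           "-num_threads", str(self.threads),
                           "-out", str(self.save_xml_to)] + extra
                subprocess.run(cmd_xml, capture_output=True, text=True)
            return proc.stdout

    def _parse(self, text: str, subject_kind: str, seqs: dict[str, str]) -> dict[str, list[HomologyHit]]:
        grouped: dict[str, dict[str, HomologyHit]] = {}
        use_qframe = subject_kind == "protein"  # blastn's qframe column is always 1
        for line in text.splitlines():
            if not line.strip():
                continue
            f = line.split("\t")
            qid, sid = f[0], f[1]
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            frame = 0
            if use_qframe and len(f) > 12 and f[12].lstrip("-").isdigit():
                frame = int(f[12])
            if frame == 0:
                frame = -1 if sstart > send else 1
            if qstart > qend:
                qstart, qend = qend, qstart
            hsp = Hsp(qstart, qend, min(sstart, send), max(sstart, send), frame,
                      float(f[10]), float(f[11]))
            bucket = grouped.setdefault(qid, {})
            if sid not in bucket:
                bucket[sid] = HomologyHit(subject_id=sid, subject_kind=subject_kind,
                                          hsps=[], subject_seq=seqs.get(sid))
            bucket[sid].hsps.append(hsp)
        return {qid: sort_hits(list(b.values())) for qid, b in grouped.items()}

    def search_protein(self, transcripts: list[Transcript]) -> dict[str, list[HomologyHit]]:
        if not transcripts:
            return {}
        extra = ["-seg", "no"]
        if self.fast:
            # reduced sensitivity: larger word, low-complexity filter on
            extra = ["-word_size", "5", "-seg", "yes"]
        out = self._run("blastx", self.bundle.blast_protein_db, transcripts,
                        self.protein_evalue, extra)
        return self._parse(out, "protein", self.bundle.proteins)

    def search_nucleotide(self, transcripts: list[Transcript]) -> dict[str, list[HomologyHit]]:
        if not transcripts:
            return {}
        extra = ["-task", "blastn", "-dust", "no"]
        out = self._run("blastn", self.bundle.blast_nucleotide_db, transcripts,
                        self.nucleotide_evalue, extra)
        return self._parse(out, "nucleotide", self.bundle.nucleotides)


# ---------------------------------------------------------------------------
# internal fallback


def _word_set(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1)}


def bit_score(raw: float, lam: float, k: float) -> float:
    return (lam * raw - math.log(k)) / math.log(2.0)


def evalue(raw: float, m: int, n: int, lam: float, k: float) -> float:
    return k * m * n * math.exp(-lam * raw)


class InternalEngine:
    """Hermetic search fallback: seeded local alignment + K-A statistics.

    A subject is considered only when it shares at least one exact word with
    the query (word sizes 4 aa / 11 nt; 5 aa in fast mode), then scored with
    a full local alignment.  E-values use the gapped Karlin-Altschul
    parameters of the corresponding scoring system with the total database
    residue count as the search-space factor.
    """

    def __init__(self, bundle: DatabaseBundle, fast: bool = False,
                 protein_evalue: float = 1e-3, nucleotide_evalue: float = 1e-10) -> None:
        self.bundle = bundle
        self.protein_evalue = protein_evalue
        self.nucleotide_evalue = nucleotide_evalue
        self.pword = PROTEIN_WORD_SIZE + (1 if fast else 0)
        self.nword = NUCLEOTIDE_WORD_SIZE

        self._prot_aligner = Align.PairwiseAligner()
        self._prot_aligner.mode = "local"
        self._prot_aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        self._prot_aligner.open_gap_score = -11
        self._prot_aligner.extend_gap_score = -1

        self._nucl_aligner = Align.PairwiseAligner()
        self._nucl_aligner.mode = "local"
        self._nucl_aligner.match_score = 2
        self._nucl_aligner.mismatch_score = -3
        self._nucl_aligner.open_gap_score = -5
        self._nucl_aligner.extend_gap_score = -2

        self._prot_words = {sid: _word_set(s, self.pword) for sid, s in bundle.proteins.items()}
        self._nucl_words = {sid: _word_set(s, self.nword) for sid, s in bundle.nucleotides.items()}
        self._prot_space = sum(len(s) for s in bundle.proteins.values())
        self._nucl_space = sum(len(s) for s in bundle.nucleotides.values())

    # -- protein (translated) search

    def search_protein(self, transcripts: list[Transcript]) -> dict[str, list[HomologyHit]]:
        out: dict[str, list[HomologyHit]] = {}
        for t in transcripts:
            hits = self._search_protein_one(t)
            if hits:
                out[t.id] = hits
        return out

    def _search_protein_one(self, t: Transcript) -> list[HomologyHit]:
        frames = [(f, pep) for f, pep in six_frame_translations(t.sequence) if len(pep) >= self.pword]
        best: dict[str, HomologyHit] = {}
        for frame, pep in frames:
            qwords = _word_set(pep, self.pword)
            for sid, swords in self._prot_words.items():
                if qwords.isdisjoint(swords):
                    continue
                subject = self.bundle.proteins[sid]
                score = self._prot_aligner.score(pep, subject)
                e = evalue(score, len(pep), self._prot_space, PROTEIN_LAMBDA, PROTEIN_K)
                if e > self.protein_evalue:
                    continue
                aln = self._prot_aligner.align(pep, subject)[0]
                qa, qb = aln.aligned[0][0][0], aln.aligned[0][-1][-1]
                sa, sb = aln.aligned[1][0][0], aln.aligned[1][-1][-1]
                hsp = self._aa_to_nt_hsp(t, frame, qa, qb, sa, sb, score, e)
                prev = best.get(sid)
                if prev is None:
                    best[sid] = HomologyHit(subject_id=sid, subject_kind="protein",
                                            hsps=[hsp], subject_seq=subject)
                elif hsp.evalue < prev.best_evalue:
                    prev.hsps.insert(0, hsp)
                else:
                    prev.hsps.append(hsp)
        return sort_hits(list(best.values()))

    def _aa_to_nt_hsp(self, t: Transcript, frame: int, qa: int, qb: int,
                      sa: int, sb: int, score: float, e: float) -> Hsp:
        off = abs(frame) - 1
        nt_start0 = off + 3 * qa
        nt_end0 = off + 3 * qb  # half-open on the frame's strand
        if frame < 0:
            length = len(t)
            nt_start0, nt_end0 = length - nt_end0, length - nt_start0
        return Hsp(
            query_start=nt_start0 + 1,
            query_end=nt_end0,
            subject_start=sa + 1,
            subject_end=sb,
            frame=frame,
            evalue=e,
            bit_score=bit_score(score, PROTEIN_LAMBDA, PROTEIN_K),
        )

    # -- nucleotide search

    def search_nucleotide(self, transcripts: list[Transcript]) -> dict[str, list[HomologyHit]]:
        out: dict[str, list[HomologyHit]] = {}
        for t in transcripts:
            hits = self._search_nucleotide_one(t)
            if hits:
                out[t.id] = hits
        return out

    def _search_nucleotide_one(self, t: Transcript) -> list[HomologyHit]:
        plus = t.sequence
        minus = revcomp(plus)
        words_plus = _word_set(plus, self.nword)
        words_minus = _word_set(minus, self.nword)
        hits: list[HomologyHit] = []
        for sid, swords in self._nucl_words.items():
            candidates = []
            if not words_plus.isdisjoint(swords):
                candidates.append((1, plus))
            if not words_minus.isdisjoint(swords):
                candidates.append((-1, minus))
            best_hsp = None
            for strand, qseq in candidates:
                subject = self.bundle.nucleotides[sid]
                score = self._nucl_aligner.score(qseq, subject)
                e = evalue(score, len(qseq), self._nucl_space, NUCLEOTIDE_LAMBDA, NUCLEOTIDE_K)
                if e > self.nucleotide_evalue:
                    continue
                aln = self._nucl_aligner.align(qseq, subject)[0]
                qa, qb = aln.aligned[0][0][0], aln.aligned[0][-1][-1]
                sa, sb = aln.aligned[1][0][0], aln.aligned[1][-1][-1]
                if strand < 0:
                    qa, qb = len(qseq) - qb, len(qseq) - qa
                hsp = Hsp(qa + 1, qb, sa + 1, sb, strand,
                          e, bit_score(score, NUCLEOTIDE_LAMBDA, NUCLEOTIDE_K))
                if best_hsp is None or hsp.evalue < best_hsp.evalue:
                    best_hsp = hsp
            if best_hsp is not None:
                hits.append(HomologyHit(subject_id=sid, subject_kind="nucleotide",
                                        hsps=[best_hsp], subject_seq=self.bundle.nucleotides[sid]))
        return sort_hits(hits)


def export_hits_xml(hits_by_query: dict[str, list[HomologyHit]], path) -> None:
    """Write translated-search results as a BlastOutput-style XML document.

    Schema mirrors the NCBI BlastOutput element names for one-HSP-per-Hit
    content so downstream annotation tools can ingest it.
    """
    import xml.etree.ElementTree as ET

    root = ET.Element("BlastOutput")
    ET.SubElement(root, "BlastOutput_program").text = "blastx"
    ET.SubElement(root, "BlastOutput_version").text = "ALIGNFIX 0.1.0"
    ET.SubElement(root, "BlastOutput_query-ID").text = "Query_1"
    ET.SubElement(root, "BlastOutput_query-def").text = "query"
    ET.SubElement(root, "BlastOutput_query-len").text = "0"
    iterations = ET.SubElement(root, "BlastOutput_iterations")
    for num, (qid, hits) in enumerate(hits_by_query.items(), start=1):
        it = ET.SubElement(iterations, "Iteration")
        ET.SubElement(it, "Iteration_iter-num").text = str(num)
        ET.SubElement(it, "Iteration_query-ID").text = qid
        ET.SubElement(it, "Iteration_query-def").text = qid
        qlen = max((s.query_end for h in hits for s in h.hsps), default=0)
        ET.SubElement(it, "Iteration_query-len").text = str(qlen)
        hits_el = ET.SubElement(it, "Iteration_hits")
        for hnum, hit in enumerate(hits, start=1):
            h = ET.SubElement(hits_el, "Hit")
            ET.SubElement(h, "Hit_num").text = str(hnum)
            ET.SubElement(h, "Hit_id").text = hit.subject_id
            ET.SubElement(h, "Hit_def").text = hit.subject_id
            hsps = ET.SubElement(h, "Hit_hsps")
            for snum, s in enumerate(hit.hsps, start=1):
                e = ET.SubElement(hsps, "Hsp")
                ET.SubElement(e, "Hsp_num").text = str(snum)
                ET.SubElement(e, "Hsp_bit-score").text = f"{s.bit_score:.6g}"
                ET.SubElement(e, "Hsp_evalue").text = f"{s.evalue:.6g}"
                ET.SubElement(e, "Hsp_query-from").text = str(s.query_start)
                ET.SubElement(e, "Hsp_query-to").text = str(s.query_end)
                ET.SubElement(e, "Hsp_hit-from").text = str(s.subject_start)
                ET.SubElement(e, "Hsp_hit-to").text = str(s.subject_end)
                ET.SubElement(e, "Hsp_query-frame").text = str(s.frame)
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="unicode")
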