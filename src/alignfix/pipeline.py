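"""Per-transcript orchestration: homology, gap analysis, wise path, combiner.

For each transcript the pipeline identifies a putative coding region from
the translated search, runs the gap-analysis corrector (with its quality
gates and top-HSP fallback) and the frameshift-aware protein-to-DNA
aligner guided by the same top-hit protein, then keeps whichever candidate
protein aligns better — and more completely — to that top-hit protein.
Full-length coverage of the reference is rewarded so an over-extended
candidate that wanders into non-coding sequence loses to an exact one.
One ORF per transcript, and every input id appears exactly once in the log.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import Align

from . import alignfs as afs
from . import wise as ws
from .homology import (
    DEFAULT_K_HOMOLOGS,
    DEFAULT_NUCLEOTIDE_EVALUE,
    DEFAULT_PROTEIN_EVALUE,
    DatabaseBundle,
    HomologyHit,
    identify_coding_region,
    load_hit_table,
    select_homologs,
)
from .search import export_hits_xml, get_engine
from .seqs import Transcript, read_fasta, translate, write_fasta

log = logging.getLogger(__name__)

DECISION_CODES = ("no_hit", "top_hsp", "no_change", "fsc_alignfs", "fsc_wise", "identical")


@dataclass
class RunConfig:
    mode: str = "combined"  # combined | alignfs_only | wise_only
    threads: int = 1
    fast_search: bool = False
    engine: str = "auto"  # auto | blast | internal
    homolog_table_path: Optional[str] = None
    protein_table_path: Optional[str] = None
    save_xml: Optional[str] = None
    verbose: bool = False
    gates: afs.QualityGates = field(default_factory=afs.QualityGates)
    wise_params: ws.WiseParams = field(default_factory=ws.WiseParams)
    protein_evalue: float = DEFAULT_PROTEIN_EVALUE
    nucleotide_evalue: float = DEFAULT_NUCLEOTIDE_EVALUE
    k_homologs: int = DEFAULT_K_HOMOLOGS

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.mode not in ("combined", "alignfs_only", "wise_only"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class OrfResult:
    transcript_id: str
    orf_sequence: str
    protein: str
    source: str  # alignfs | wise | identical | alignfs_forced | wise_forced | none
    decision_code: str
    corrections_applied: int = 0
    comparison_scores: tuple[float, float] = (0.0, 0.0)
    homolog_ids: list[str] = field(default_factory=list)
    gate_summary: str = ""
    alignfs_outcome: Optional[afs.AlignFsOutcome] = None
    wise_outcome: Optional[ws.WiseOutcome] = None

    @property
    def has_orf(self) -> bool:
        return bool(self.orf_sequence)


import threading

_tls = threading.local()


def _protein_aligner() -> Align.PairwiseAligner:
    a = getattr(_tls, "aligner", None)
    if a is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _tls.aligner = a
    return a


def _coverage_weighted_score(candidate: str, reference: str) -> float:
    """Local alignment score scaled by the fraction of the reference covered."""
    if not candidate or not reference:
        return 0.0
    cand = candidate.rstrip("*")
    if not cand:
        return 0.0
    aln = _protein_aligner().align(cand, reference)[0]
    score = aln.score
    ref_lo, ref_hi = aln.aligned[1][0][0], aln.aligned[1][-1][-1]
    return float(score) * (ref_hi - ref_lo) / len(reference)


# Relative score advantage the wise candidate must show before it displaces
# the gap-analysis candidate.  The gap-analysis corrections are conservative
# by construction, so near-ties (e.g. two extra codons of coverage) should
# not flip the choice to the more aggressive aligner.
WISE_PREFERENCE_MARGIN = 0.05


def compare_candidates(
    alignfs_protein: Optional[str],
    wise_protein: Optional[str],
    reference_protein: str,
) -> tuple[str, tuple[float, float]]:
    """Pick the candidate whose protein best matches the top-hit protein.

    Scores are coverage-weighted local-alignment scores against the
    reference, rewarding full-length agreement; byte-identical candidates
    are ``identical``; the wise candidate wins only when its score exceeds
    the gap-analysis candidate's by more than ``WISE_PREFERENCE_MARGIN``.
    """
    a = _coverage_weighted_score(alignfs_protein or "", reference_protein)
    w = _coverage_weighted_score(wise_protein or "", reference_protein)
    if alignfs_protein and wise_protein and alignfs_protein == wise_protein:
        return "identical", (a, w)
    if not alignfs_protein and not wise_protein:
        return "none", (a, w)
    if not wise_protein:
        return "alignfs", (a, w)
    if not alignfs_protein:
        return "wise", (a, w)
    if w > a * (1.0 + WISE_PREFERENCE_MARGIN):
        return "wise", (a, w)
    return "alignfs", (a, w)


def _wise_has_fsc(outcome: Optional[ws.WiseOutcome]) -> bool:
    return bool(outcome) and any(s.frameshift_ops for s in outcome.segments)


def _no_hit(tid: str) -> OrfResult:
    return OrfResult(tid, "", "", "none", "no_hit")


def process_transcript(
    transcript: Transcript,
    config: RunConfig,
    databases: DatabaseBundle,
    protein_hits: list[HomologyHit],
    nucleotide_hits: list[HomologyHit],
) -> OrfResult:
    """Run the full decision flow for one transcript.

    Any failing step degrades to the next-best outcome (gate failure to the
    top-HSP span, both paths failing to a no-hit record); it never raises.
    """
    region = identify_coding_region(transcript, protein_hits, config.protein_evalue)
    if region is None:
        return _no_hit(transcript.id)

    af_out: Optional[afs.AlignFsOutcome] = None
    wise_out: Optional[ws.WiseOutcome] = None

    if config.mode in ("combined", "alignfs_only"):
        homologs = select_homologs(
            transcript, nucleotide_hits, config.k_homologs,
            config.nucleotide_evalue, working_strand=region.strand)
        af_out = afs.run_alignfs(region, homologs, config.gates,
                                 keep_alignment=config.verbose)

    if config.mode in ("combined", "wise_only"):
        guide = region.top_hit_protein.rstrip("*")
        working = region.working_sequence
        if len(guide) >= 5 and len(working) >= 15:
            try:
                segments = ws.align_protein_dna(guide, working, config.wise_params)
                wise_out = ws.stitch_and_select(segments, working)
            except Exception as exc:
                log.warning("wise path failed for %s: %s", transcript.id, exc)
                wise_out = ws.WiseOutcome("", [], "no_orf")
        else:
            wise_out = ws.WiseOutcome("", [], "no_orf")

    af_orf = af_out.orf_sequence if af_out and af_out.decision != "no_orf" else ""
    wise_orf = wise_out.orf_sequence if wise_out and wise_out.decision == "wise_orf" else ""
    af_prot = translate(af_orf) if af_orf else ""
    wise_prot = translate(wise_orf) if wise_orf else ""

    def af_code() -> str:
        return {"fsc_made": "fsc_alignfs", "no_change": "no_change",
                "top_hsp_fallback": "top_hsp"}.get(af_out.decision, "no_hit")

    def result(source: str, orf: str, prot: str, code: str,
               scores: tuple[float, float] = (0.0, 0.0)) -> OrfResult:
        return OrfResult(
            transcript_id=transcript.id,
            orf_sequence=orf,
            protein=prot,
            source=source,
            decision_code=code,
            corrections_applied=len(af_out.corrections) if (af_out and source != "wise"
                                                            and source != "wise_forced") else 0,
            comparison_scores=scores,
            homolog_ids=af_out.homolog_ids if af_out else [],
            gate_summary=af_out.gate_report.summary() if af_out and af_out.gate_report else "",
            alignfs_outcome=af_out,
            wise_outcome=wise_out,
        )

    if config.mode == "alignfs_only":
        if not af_orf:
            return _no_hit(transcript.id)
        return result("alignfs_forced", af_orf, af_prot, af_code())
    if config.mode == "wise_only":
        if not wise_orf:
            return _no_hit(transcript.id)
        code = "fsc_wise" if _wise_has_fsc(wise_out) else "no_change"
        return result("wise_forced", wise_orf, wise_prot, code)

    winner, scores = compare_candidates(af_prot or None, wise_prot or None,
                                        region.top_hit_protein)
    if winner == "none":
        return _no_hit(transcript.id)
    if winner == "identical":
        code = "identical"
        return result("identical", af_orf, af_prot, code, scores)
    if winner == "alignfs":
        return result("alignfs", af_orf, af_prot, af_code(), scores)
    code = "fsc_wise" if _wise_has_fsc(wise_out) else "no_change"
    return result("wise", wise_orf, wise_prot, code, scores)


@dataclass
class BatchResult:
    results: list[OrfResult]
    counts: dict[str, int]

    def log_lines(self) -> list[str]:
        lines = []
        for r in self.results:
            lines.append("\t".join([
                r.transcript_id, r.decision_code, r.source,
                str(r.corrections_applied), r.gate_summary,
                ",".join(r.homolog_ids),
            ]))
        return lines


def run_batch(
    transcripts,
    config: RunConfig,
    databases: DatabaseBundle,
    out_prefix: Optional[str] = None,
) -> BatchResult:
    """Process a FASTA file or a list of transcripts.

    Homology searches run once, batched, up front; transcripts are then
    processed independently across ``config.threads`` workers.  Output
    order always matches input order, so results are byte-identical
    whatever the thread count.
    """
    if isinstance(transcripts, (str, Path)):
        transcripts = read_fasta(transcripts)
    transcripts = list(transcripts)

    engine = get_engine(databases, config.engine, config.fast_search,
                        config.threads, config.protein_evalue, config.nucleotide_evalue)

    if config.protein_table_path:
        prot_hits = load_hit_table(config.protein_table_path, subject_kind="protein")
        for hits in prot_hits.values():
            for h in hits:
                h.subject_seq = databases.proteins.get(h.subject_id)
    else:
        if config.save_xml and hasattr(engine, "save_xml_to"):
            engine.save_xml_to = Path(config.save_xml)
        prot_hits = engine.search_protein(transcripts)
        if config.save_xml and not hasattr(engine, "save_xml_to"):
            export_hits_xml(prot_hits, config.save_xml)

    coding = [t for t in transcripts if prot_hits.get(t.id)]
    if config.homolog_table_path:
        nucl_hits = load_hit_table(config.homolog_table_path, subject_kind="nucleotide")
        for hits in nucl_hits.values():
            for h in hits:
                h.subject_seq = databases.nucleotides.get(h.subject_id)
    else:
        nucl_hits = engine.search_nucleotide(coding) if coding else {}

    def work(t: Transcript) -> OrfResult:
        try:
            return process_transcript(t, config, databases,
                                      prot_hits.get(t.id, []), nucl_hits.get(t.id, []))
        except Exception as exc:
            log.error("transcript %s failed: %s", t.id, exc)
            return _no_hit(t.id)

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(work, transcripts))
    else:
        results = [work(t) for t in transcripts]

    counts: dict[str, int] = {c: 0 for c in DECISION_CODES}
    counts["orfs_found"] = 0
    counts["fsc_made"] = 0
    for r in results:
        counts[r.decision_code] = counts.get(r.decision_code, 0) + 1
        if r.has_orf:
            counts["orfs_found"] += 1
        if r.decision_code in ("fsc_alignfs", "fsc_wise"):
            counts["fsc_made"] += 1
        elif r.decision_code == "identical" and r.corrections_applied:
            counts["fsc_made"] += 1

    batch = BatchResult(results=results, counts=counts)
    if out_prefix is not None:
        _write_outputs(batch, out_prefix)
    return batch


def _write_outputs(batch: BatchResult, prefix: str) -> None:
    prefix = str(prefix)
    with_orf = [(r.transcript_id, r.orf_sequence) for r in batch.results if r.has_orf]
    write_fasta(f"{prefix}.orfs.fasta", with_orf)
    write_fasta(f"{prefix}.proteins.fasta",
                [(r.transcript_id, r.protein) for r in batch.results if r.has_orf])
    with open(f"{prefix}.log.tsv", "w") as fh:
        fh.write("transcript_id\tdecision\tsource\tn_corrections\tgates\thomologs\n")
        for line in batch.log_lines():
            fh.write(line + "\n")
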