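"""Multiple-alignment gap analysis and frame-shift correction.

The corrector aligns the working transcript with in-frame coding-sequence
homologs and inspects gap runs whose length is not divisible by three:

* a gap in the transcript row opposite homolog residues marks a deletion in
  the transcript — placeholder ``N`` bases are inserted to restore frame;
* a gap conserved across *all* homolog rows opposite transcript residues
  marks an insertion in the transcript — bases are removed;
* runs where only some homolog rows carry residues are decided by majority,
  which lets a frame-shifted homolog be ignored;
* runs of length 1, 2 and 4 get 1, 2 and 1 ``N`` respectively (a 4-base gap
  is a single gap followed by an in-frame 3-base deletion); longer runs are
  processed per end against the codon frame of a trusted homolog row, so an
  edit can land at either or both ends;
* runs divisible by three, and runs closer than 3 bases to the boundary of
  the putative coding region, are left alone.

If no homologs are found, or the alignment fails the quality gates, no
correction is attempted and the single top-HSP span is returned instead —
a truncated but trustworthy in-frame sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from .homology import CodingRegion, Homolog
from .seqs import translate

log = logging.getLogger(__name__)

LONG_GAP_MIN = 5  # lengths 1, 2, 4 are enumerated cases; 3 and 6 are in frame
BOUNDARY_SKIP_BP = 3  # corrections this close to the region edge are skipped


import threading

_tls = threading.local()


def _pairwise_aligner() -> Align.PairwiseAligner:
    """Per-thread aligner (PairwiseAligner instances are not shared safely)."""
    a = getattr(_tls, "aligner", None)
    if a is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 2
        a.mismatch_score = -3
        a.open_gap_score = -7
        a.extend_gap_score = -2
        a.end_gap_score = 0  # terminal overhangs (UTRs, length differences) are free
        _tls.aligner = a
    return a


@dataclass
class MultipleAlignment:
    """Transcript-anchored multiple alignment; row 0 is the transcript."""

    rows: list[tuple[str, str]]
    transcript_row_index: int = 0

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    @property
    def transcript_row(self) -> str:
        return self.rows[self.transcript_row_index][1]

    @property
    def homolog_rows(self) -> list[tuple[str, str]]:
        return [r for i, r in enumerate(self.rows) if i != self.transcript_row_index]

    def ungapped_transcript(self) -> str:
        return self.transcript_row.replace("-", "")

    def to_fasta_text(self) -> str:
        return "".join(f">{rid}\n{seq}\n" for rid, seq in self.rows)


@dataclass
class GapEvent:
    """A maximal gap run relevant to frame analysis.

    ``col_start``/``col_end`` are 0-based half-open alignment columns;
    ``transcript_pos`` anchors the event in ungapped working-sequence
    coordinates (the insertion point for transcript gaps, the first run
    base for conserved homolog gaps).
    """

    col_start: int
    col_end: int
    carrier: str  # transcript_only | all_homologs | mixed
    transcript_pos: int
    rows_with_residue: int = 0
    n_homologs: int = 0

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


@dataclass
class Correction:
    """A frame-restoring edit on the working sequence."""

    kind: str  # insert_n | delete_bases
    transcript_pos: int  # 0-based, working-sequence coordinates
    count: int  # always 1 or 2: an in-frame remainder is never edited
    source_gap: Optional[GapEvent] = None
    end_tag: str = "whole"  # whole | gap_start | gap_end


@dataclass
class QualityGates:
    """Alignment-quality thresholds below which no correction is attempted."""

    min_identity: float = 0.70
    max_gap_length: int = 30
    max_gap_fraction: float = 0.20
    min_homologs: int = 1


@dataclass
class GateReport:
    passed: bool
    n_homologs: int
    mean_identity: float
    max_gap_run: int
    gap_fraction: float
    failures: list[str] = field(default_factory=list)

    def summary(self) -> str:
        state = "pass" if self.passed else "fail(" + ",".join(self.failures) + ")"
        return (f"{state};id={self.mean_identity:.3f};maxgap={self.max_gap_run};"
                f"gapfrac={self.gap_fraction:.3f};homologs={self.n_homologs}")


@dataclass
class AlignFsOutcome:
    orf_sequence: str
    decision: str  # fsc_made | no_change | top_hsp_fallback | no_orf
    corrections: list[Correction]
    gate_report: Optional[GateReport]
    homolog_ids: list[str] = field(default_factory=list)
    note: str = ""
    alignment: Optional[MultipleAlignment] = None


# ---------------------------------------------------------------------------
# alignment construction


def _pairwise_columns(target: str, query: str) -> tuple[str, str]:
    aln = _pairwise_aligner().align(target, query)[0]
    return str(aln[0]), str(aln[1])


def build_alignment(working_seq: str, homologs: Sequence[Homolog]) -> MultipleAlignment:
    """Globally align the transcript with its homologs (transcript-anchored).

    Each homolog is globally aligned to the transcript with free end gaps,
    then the pairwise alignments are merged on the shared transcript
    coordinate (center-star): homolog residues falling between transcript
    positions open an insertion slot whose width is the longest insert any
    homolog needs there.  The transcript row ungaps back to ``working_seq``
    exactly.
    """
    if not homologs:
        raise ValueError("at least one homolog is required")
    L = len(working_seq)
    inserts: list[dict[int, str]] = []  # per homolog: slot index -> inserted residues
    aligned: list[list[str]] = []  # per homolog: residue/('-') at each transcript pos

    for hom in homologs:
        trow, hrow = _pairwise_columns(working_seq, hom.sequence)
        ins: dict[int, str] = {}
        res = ["-"] * L
        tpos = 0
        for tc, hc in zip(trow, hrow):
            if tc == "-":
                ins[tpos] = ins.get(tpos, "") + hc
            else:
                res[tpos] = hc
                tpos += 1
        inserts.append(ins)
        aligned.append(res)

    slot_width = [0] * (L + 1)
    for ins in inserts:
        for slot, chars in ins.items():
            slot_width[slot] = max(slot_width[slot], len(chars))

    t_parts: list[str] = []
    h_parts: list[list[str]] = [[] for _ in homologs]
    for i in range(L + 1):
        w = slot_width[i]
        if w:
            t_parts.append("-" * w)
            for k, ins in enumerate(inserts):
                chars = ins.get(i, "")
                h_parts[k].append(chars + "-" * (w - len(chars)))
        if i < L:
            t_parts.append(working_seq[i])
            for k in range(len(homologs)):
                h_parts[k].append(aligned[k][i])

    rows = [("transcript", "".join(t_parts))]
    rows += [(hom.id, "".join(parts)) for hom, parts in zip(homologs, h_parts)]
    return MultipleAlignment(rows=rows, transcript_row_index=0)


def _transcript_pos_index(trow: str) -> list[int]:
    """Number of transcript residues strictly left of each column (len = cols+1)."""
    idx = [0]
    for c in trow:
        idx.append(idx[-1] + (c != "-"))
    return idx


def _window_columns(aln: MultipleAlignment, region_start0: int, region_end0: int) -> tuple[int, int]:
    """Columns spanning transcript positions [region_start0, region_end0)."""
    trow = aln.transcript_row
    tpos = 0
    col_start = col_end = len(trow)
    for col, c in enumerate(trow):
        if c != "-":
            if tpos == region_start0:
                col_start = col
            tpos += 1
            if tpos == region_end0:
                col_end = col + 1
                break
    return min(col_start, col_end), col_end


# ---------------------------------------------------------------------------
# gap scanning


def scan_gaps(aln: MultipleAlignment, window: Optional[tuple[int, int]] = None) -> list[GapEvent]:
    """Find maximal gap runs relevant to frame-shift analysis.

    Returns transcript-row gap runs (``transcript_only`` when every homolog
    row has residues there, ``mixed`` otherwise) and runs gapped in *all*
    homolog rows opposite transcript residues (``all_homologs``), ordered by
    column.  Scanning is restricted to ``window`` columns when given.
    """
    trow = aln.transcript_row
    hrows = [seq for _, seq in aln.homolog_rows]
    n_hom = len(hrows)
    cols = aln.column_count
    lo, hi = window if window is not None else (0, cols)
    tindex = _transcript_pos_index(trow)

    events: list[GapEvent] = []

    # transcript-row gap runs
    col = lo
    while col < hi:
        if trow[col] == "-":
            run_start = col
            while col < hi and trow[col] == "-":
                col += 1
            rows_with = sum(1 for h in hrows if any(c != "-" for c in h[run_start:col]))
            carrier = "transcript_only" if rows_with == n_hom else "mixed"
            events.append(GapEvent(run_start, col, carrier, tindex[run_start],
                                   rows_with_residue=rows_with, n_homologs=n_hom))
        else:
            col += 1

    # runs gapped in all homolog rows, transcript residues present
    col = lo
    while col < hi:
        if trow[col] != "-" and all(h[col] == "-" for h in hrows):
            run_start = col
            while col < hi and trow[col] != "-" and all(h[col] == "-" for h in hrows):
                col += 1
            events.append(GapEvent(run_start, col, "all_homologs", tindex[run_start],
                                   rows_with_residue=0, n_homologs=n_hom))
        else:
            col += 1

    events.sort(key=lambda e: e.col_start)
    return events


# ---------------------------------------------------------------------------
# correction rules


def _ref_row_for_event(gap: GapEvent, aln: MultipleAlignment,
                       homolog_rank: Optional[Sequence[int]] = None) -> Optional[str]:
    """Best-ranked homolog row with no gap across the event, or None."""
    hrows = [seq for _, seq in aln.homolog_rows]
    order = homolog_rank if homolog_rank is not None else range(len(hrows))
    for k in order:
        row = hrows[k]
        if "-" not in row[gap.col_start : gap.col_end]:
            return row
    return None


def _phase_at(row: str, col: int) -> int:
    """Codon phase of an in-frame homolog row at an alignment column.

    Reference sequences are in-frame CDS, so the phase at any column is the
    count of the row's residues left of it, mod 3 (this survives reverse
    complementing because the sequence length is a codon multiple).
    """
    return sum(1 for c in row[:col] if c != "-") % 3


def classify_and_correct_gap(
    gap: GapEvent,
    aln: MultipleAlignment,
    region_start0: int = 0,
    region_end0: Optional[int] = None,
    homolog_rank: Optional[Sequence[int]] = None,
) -> list[Correction]:
    """Turn one gap event into frame-restoring edits (possibly none).

    Gap runs divisible by three need no edit.  Runs of length 1, 2 and 4
    receive the enumerated treatment; length >= 5 transcript gaps are
    processed per end against the codon frame of the best homolog row that
    spans the event without gaps: the start end completes the codon broken
    at the gap start, the far end completes the codon straddling the gap
    end, so an edit can occur at either or both ends.  Conserved homolog
    gaps (insertions in the transcript) mirror the logic with deletions;
    both their ends see the same reference phase, so a single deletion of
    ``length mod 3`` bases suffices.
    """
    L = gap.length
    if L % 3 == 0:
        return []
    if region_end0 is None:
        region_end0 = len(aln.ungapped_transcript())

    is_deletion = gap.carrier == "transcript_only" or (
        gap.carrier == "mixed" and gap.rows_with_residue * 2 > gap.n_homologs
    )
    if gap.carrier == "mixed" and not is_deletion:
        return []
    if gap.carrier == "all_homologs":
        is_deletion = False

    p = gap.transcript_pos
    if is_deletion:
        # insertion point: skip when too close to the region boundary
        if p - region_start0 < BOUNDARY_SKIP_BP or region_end0 - p < BOUNDARY_SKIP_BP:
            return []
        if L in (1, 2):
            return [Correction("insert_n", p, L, gap, "whole")]
        if L == 4:
            return [Correction("insert_n", p, 1, gap, "whole")]
        ref = _ref_row_for_event(gap, aln, homolog_rank)
        if ref is None:
            log.debug("gap at cols %d-%d: no gap-free reference row; skipped",
                      gap.col_start, gap.col_end)
            return []
        phase_start = _phase_at(ref, gap.col_start)
        n_ref_inside = sum(1 for c in ref[gap.col_start : gap.col_end] if c != "-")
        phase_end = (phase_start + n_ref_inside) % 3
        out: list[Correction] = []
        a = (3 - phase_start) % 3  # complete the codon broken at the gap start
        if a:
            out.append(Correction("insert_n", p, a, gap, "gap_start"))
        if phase_end:  # complete the codon straddling the gap end
            out.append(Correction("insert_n", p, phase_end, gap, "gap_end"))
        return out

    # insertion in the transcript: remove bases, same enumeration
    run_end = p + L
    if p - region_start0 < BOUNDARY_SKIP_BP or region_end0 - run_end < BOUNDARY_SKIP_BP:
        return []
    if L in (1, 2):
        return [Correction("delete_bases", p, L, gap, "whole")]
    if L == 4:
        return [Correction("delete_bases", p, 1, gap, "whole")]
    count = L % 3  # both ends share the reference phase; one edit restores frame
    return [Correction("delete_bases", p, count, gap, "gap_start")]


# ---------------------------------------------------------------------------
# gates


def apply_gates(aln: MultipleAlignment, gates: QualityGates,
                window: Optional[tuple[int, int]] = None) -> GateReport:
    """Measure alignment quality against the configured thresholds.

    Identity is the mean, over homologs, of transcript-vs-homolog identity
    across mutually ungapped columns; the gap-run and gap-fraction measures
    cover every row.  Measurement is restricted to ``window`` when given so
    terminal overhangs from length differences are not penalised.
    """
    lo, hi = window if window is not None else (0, aln.column_count)
    trow = aln.transcript_row[lo:hi]
    hrows = [seq[lo:hi] for _, seq in aln.homolog_rows]
    n_hom = len(hrows)

    identities = []
    for h in hrows:
        match = both = 0
        for tc, hc in zip(trow, h):
            if tc != "-" and hc != "-":
                both += 1
                match += tc == hc
        identities.append(match / both if both else 0.0)
    mean_identity = sum(identities) / n_hom if n_hom else 0.0

    max_run = 0
    total = gapped = 0
    for row in [trow] + hrows:
        run = 0
        for c in row:
            total += 1
            if c == "-":
                gapped += 1
                run += 1
                max_run = max(max_run, run)
            else:
                run = 0
    gap_fraction = gapped / total if total else 0.0

    failures = []
    if n_hom < gates.min_homologs:
        failures.append("min_homologs")
    if mean_identity < gates.min_identity:
        failures.append("min_identity")
    if max_run > gates.max_gap_length:
        failures.append("max_gap_length")
    if gap_fraction > gates.max_gap_fraction:
        failures.append("max_gap_fraction")
    return GateReport(not failures, n_hom, mean_identity, max_run, gap_fraction, failures)


# ---------------------------------------------------------------------------
# applying edits


def apply_corrections(working_seq: str, corrections: list[Correction]) -> str:
    """Apply edits right-to-left so earlier coordinates stay valid.

    Insertions at the same position are allowed (both ends of one long gap
    anchor at one insertion point); overlapping deletions indicate a
    scanning bug and raise.
    """
    ordered = sorted(corrections, key=lambda c: (c.transcript_pos, c.end_tag != "gap_start"))
    for c in ordered:
        if c.kind == "delete_bases" and c.transcript_pos + c.count > len(working_seq):
            raise ValueError("deletion extends past end of sequence")
    for a, b in zip(ordered, ordered[1:]):
        if a.kind == "delete_bases" and a.transcript_pos + a.count > b.transcript_pos:
            raise ValueError("overlapping corrections")
    seq = working_seq
    for c in reversed(ordered):
        p = c.transcript_pos
        if c.kind == "insert_n":
            seq = seq[:p] + "N" * c.count + seq[p:]
        elif c.kind == "delete_bases":
            seq = seq[:p] + seq[p + c.count :]
        else:
            raise ValueError(f"unknown correction kind {c.kind!r}")
    return seq


def _trim_to_codon(seq: str) -> str:
    return seq[: len(seq) - len(seq) % 3]


def _has_internal_stop(orf: str) -> bool:
    prot = translate(orf)
    return "*" in prot[:-1] if prot else False


# ---------------------------------------------------------------------------
# driver


def run_alignfs(
    region: CodingRegion,
    homologs: Sequence[Homolog],
    gates: Optional[QualityGates] = None,
    keep_alignment: bool = False,
) -> AlignFsOutcome:
    """Full gap-analysis pass for one putative coding region.

    Falls back to the single top-HSP span (uncorrected, in frame) when no
    usable homolog alignment exists, when the quality gates fail, or when a
    corrected ORF still contains an internal stop codon.
    """
    gates = gates or QualityGates()
    working = region.working_sequence
    hom_ids = [h.id for h in homologs]

    def fallback(note: str, report: Optional[GateReport]) -> AlignFsOutcome:
        orf = _trim_to_codon(region.top_hsp_sequence())
        return AlignFsOutcome(orf, "top_hsp_fallback", [], report, hom_ids, note)

    if len(homologs) < max(1, gates.min_homologs):
        return fallback("insufficient_homologs", None)

    try:
        aln = build_alignment(working, list(homologs))
    except Exception as exc:  # aligner failure degrades, never crashes the batch
        log.warning("alignment failed for %s: %s", region.transcript_id, exc)
        return AlignFsOutcome("", "no_orf", [], None, hom_ids, "alignment_failed")

    window = _window_columns(aln, region.start0, region.end0)
    report = apply_gates(aln, gates, window)
    if not report.passed:
        out = fallback("gates_failed", report)
        if keep_alignment:
            out.alignment = aln
        return out

    events = scan_gaps(aln, window)
    corrections: list[Correction] = []
    for ev in events:
        corrections.extend(
            classify_and_correct_gap(ev, aln, region.start0, region.end0)
        )

    if not corrections:
        orf = _trim_to_codon(region.region_sequence())
        out = AlignFsOutcome(orf, "no_change", [], report, hom_ids)
        if keep_alignment:
            out.alignment = aln
        return out

    edited = apply_corrections(working, corrections)
    net = sum(c.count if c.kind == "insert_n" else -c.count for c in corrections)
    orf = _trim_to_codon(edited[region.start0 : region.end0 + net])
    if _has_internal_stop(orf):
        out = fallback("internal_stop", report)
        if keep_alignment:
            out.alignment = aln
        return out
    out = AlignFsOutcome(orf, "fsc_made", corrections, report, hom_ids)
    if keep_alignment:
        out.alignment = aln
    return out
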