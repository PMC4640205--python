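"""Synthetic benchmark: indel-injected coding sequences with known truth.

The generator emulates the evaluation design used for frameshift
correctors: draw a stop-free coding sequence, derive diverged in-frame
homologs (substitution-only, biased 3:1 toward third codon positions so
protein similarity stays realistic for a given nucleotide divergence), and
inject a single frame-disrupting indel at a random interior position.  The
pipeline runs against databases built from the homologs, and each output
ORF is scored against the known coding sequence: *accurate* (aligns with
no frame discontinuity, inserted ``N`` treated as a wildcard), *inaccurate*
(frame discontinuity or mismatch), *truncated-in-frame* (clean but stops
short of the indel without attempting a correction) or *not found*.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .homology import prepare_reference_db, translated_protein_db
from .pipeline import OrfResult, RunConfig, run_batch
from .seqs import Transcript, translate

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = {"TAA", "TAG", "TGA"}

INDEL_KINDS = ("del1", "ins1", "del2", "ins2", "del4")


@dataclass
class BenchmarkSpec:
    """Study conditions for one benchmark run."""

    n_transcripts: int = 1000
    cds_length_range: tuple[int, int] = (300, 3000)
    homolog_divergence: float = 0.05  # per-site substitution probability
    n_homologs: int = 3
    indel_kind_probs: dict[str, float] = field(
        default_factory=lambda: {"del1": 0.5, "ins1": 0.5})
    edge_margin: int = 9  # bp excluded at each CDS end for indel placement
    utr_length_range: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cds_length_range
        if lo < 90 or lo % 3 or hi % 3 or hi < lo:
            raise ValueError("cds_length_range must be multiples of 3, min >= 90")
        if self.edge_margin < 3:
            raise ValueError("edge_margin must be >= 3")
        if self.edge_margin >= lo // 2:
            raise ValueError("edge_margin too large for the shortest CDS")
        total = sum(self.indel_kind_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("indel_kind_probs must sum to 1")
        for k in self.indel_kind_probs:
            if k not in INDEL_KINDS:
                raise ValueError(f"unknown indel kind {k!r}")
        if not 0.0 <= self.homolog_divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")


@dataclass
class BenchmarkCase:
    case_id: str
    true_cds: str
    homologs: list[str]
    mutant_transcript: str
    indel_pos: int  # CDS coordinate of the event (0-based)
    indel_kind: str
    utr5: int = 0
    utr3: int = 0


@dataclass
class OutcomeRecord:
    case_id: str
    fsc_attempted: bool
    category: str  # accurate | inaccurate | truncated_in_frame | not_found
    cds_coverage: float  # percent; may exceed 100 for over-extended ORFs
    source: str
    indel_relative_pos: float
    divergence: float = float("nan")


# ---------------------------------------------------------------------------
# generation


def _random_cds(rng: np.random.Generator, length: int) -> str:
    n_inner = length // 3 - 2
    inner = rng.choice(len(_SENSE_CODONS), size=n_inner)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in inner) + "TAA"


def _diverge(rng: np.random.Generator, cds: str, p: float) -> str:
    """Substitution-only divergence, 3:1 biased to third codon positions.

    Start and stop codons are preserved; a substitution that would create
    an internal stop codon is redrawn so homologs stay translatable.
    """
    if p <= 0:
        return cds
    site_p = np.tile([0.6 * p, 0.6 * p, 1.8 * p], len(cds) // 3)
    site_p = np.minimum(site_p, 0.95)
    site_p[:3] = 0.0
    site_p[-3:] = 0.0
    hits = rng.random(len(cds)) < site_p
    seq = list(cds)
    bases = "ACGT"
    for i in np.flatnonzero(hits):
        choices = [b for b in bases if b != seq[i]]
        seq[i] = choices[rng.integers(3)]
        c0 = 3 * (i // 3)
        codon = "".join(seq[c0 : c0 + 3])
        tries = 0
        while codon in _STOPS and tries < 10:
            seq[i] = choices[rng.integers(3)]
            codon = "".join(seq[c0 : c0 + 3])
            tries += 1
        if codon in _STOPS:
            seq[i] = cds[i]  # give up on this site
    return "".join(seq)


def _inject_indel(rng: np.random.Generator, cds: str, kind: str, pos: int) -> str:
    if kind == "del1":
        return cds[:pos] + cds[pos + 1 :]
    if kind == "del2":
        return cds[:pos] + cds[pos + 2 :]
    if kind == "del4":
        return cds[:pos] + cds[pos + 4 :]
    if kind == "ins1":
        return cds[:pos] + "ACGT"[rng.integers(4)] + cds[pos:]
    if kind == "ins2":
        ins = "ACGT"[rng.integers(4)] + "ACGT"[rng.integers(4)]
        return cds[:pos] + ins + cds[pos:]
    raise ValueError(f"unknown indel kind {kind!r}")


def generate_cases(spec: BenchmarkSpec) -> list[BenchmarkCase]:
    """Seeded, reproducible benchmark cases satisfying the type invariants."""
    rng = np.random.default_rng(spec.seed)
    kinds = sorted(spec.indel_kind_probs)
    kind_p = np.array([spec.indel_kind_probs[k] for k in kinds])
    lo, hi = spec.cds_length_range
    cases: list[BenchmarkCase] = []
    width = len(str(max(spec.n_transcripts, 1)))
    for i in range(spec.n_transcripts):
        length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        cds = _random_cds(rng, length)
        homologs = [_diverge(rng, cds, spec.homolog_divergence)
                    for _ in range(spec.n_homologs)]
        kind = kinds[int(rng.choice(len(kinds), p=kind_p))]
        pos = int(rng.integers(spec.edge_margin, length - spec.edge_margin))
        mutant = _inject_indel(rng, cds, kind, pos)
        u5, u3 = 0, 0
        if spec.utr_length_range[1] > 0:
            u5 = int(rng.integers(spec.utr_length_range[0], spec.utr_length_range[1] + 1))
            u3 = int(rng.integers(spec.utr_length_range[0], spec.utr_length_range[1] + 1))
            mutant = ("".join("ACGT"[b] for b in rng.integers(0, 4, u5)) + mutant
                      + "".join("ACGT"[b] for b in rng.integers(0, 4, u3)))
        cases.append(BenchmarkCase(
            case_id=f"case{i:0{width}d}", true_cds=cds, homologs=homologs,
            mutant_transcript=mutant, indel_pos=pos, indel_kind=kind,
            utr5=u5, utr3=u3))
    return cases


# ---------------------------------------------------------------------------
# running the pipeline over a case set


def build_case_databases(cases: list[BenchmarkCase], out_dir):
    """Reference databases from the diverged homologs (never the true CDS)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nucl = {}
    for case in cases:
        for k, hom in enumerate(case.homologs):
            nucl[f"{case.case_id}h{k}"] = hom
    prots = translated_protein_db(nucl)
    from .seqs import write_fasta

    cds_path = out_dir / "bench_cds.fasta"
    prot_path = out_dir / "bench_prot.fasta"
    write_fasta(cds_path, nucl.items())
    write_fasta(prot_path, prots.items())
    return prepare_reference_db(cds_path, prot_path, out_dir / "db")


def run_cases(cases: list[BenchmarkCase], config: Optional[RunConfig] = None,
              workdir=None):
    """Run the pipeline over the mutant transcripts; returns the BatchResult."""
    config = config or RunConfig()
    transcripts = [Transcript.from_raw(c.case_id, c.mutant_transcript) for c in cases]
    if workdir is None:
        with tempfile.TemporaryDirectory(prefix="alignfix_bench_") as tmp:
            bundle = build_case_databases(cases, tmp)
            return run_batch(transcripts, config, bundle)
    bundle = build_case_databases(cases, workdir)
    return run_batch(transcripts, config, bundle)


# ---------------------------------------------------------------------------
# outcome classification


def _make_cds_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.end_gap_score = 0
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if x == "N" or y == "N":
                m[x, y] = 1.0  # placeholder base: wildcard
            else:
                m[x, y] = 2.0 if x == y else -4.0
    a.substitution_matrix = m
    a.open_gap_score = -8
    a.extend_gap_score = -2
    return a


_CDS_ALIGNER = _make_cds_aligner()


def _frame_and_mismatch(orf: str, cds: str) -> tuple[bool, int, int, int]:
    """(frame_clean, mismatches, cds_span_start, cds_span_end) vs the truth.

    Frame-clean means every internal gap run in the pairwise alignment has
    a length divisible by three.  ``N`` matches anything.
    """
    aln = _CDS_ALIGNER.align(orf, cds)[0]
    rows = (str(aln[0]), str(aln[1]))
    cols = len(rows[0])
    # trim terminal overhangs
    lead = 0
    while lead < cols and ("-" in (rows[0][lead], rows[1][lead])):
        lead += 1
    tail = cols
    while tail > lead and ("-" in (rows[0][tail - 1], rows[1][tail - 1])):
        tail -= 1
    frame_clean = True
    mismatches = 0
    for row in rows:
        run = 0
        for c in row[lead:tail]:
            if c == "-":
                run += 1
            else:
                if run % 3:
                    frame_clean = False
                run = 0
        if run % 3:
            frame_clean = False
    for a, b in zip(rows[0][lead:tail], rows[1][lead:tail]):
        if a != "-" and b != "-" and a != b and a != "N" and b != "N":
            mismatches += 1
    cds_start = len(rows[1][:lead].replace("-", ""))
    cds_end = len(rows[1][:tail].replace("-", ""))
    return frame_clean, mismatches, cds_start, cds_end


def is_frame_restored(orf: str, true_cds: str) -> bool:
    """True when the ORF translates without internal stop and aligns to the
    true coding sequence with no frame discontinuity (N as wildcard)."""
    if not orf:
        return False
    if "*" in translate(orf)[:-1]:
        return False
    frame_clean, _, _, _ = _frame_and_mismatch(orf, true_cds)
    return frame_clean


def classify_outcome(result: Optional[OrfResult], case: BenchmarkCase,
                     source: str = "combined",
                     orf: Optional[str] = None,
                     fsc_attempted: Optional[bool] = None,
                     divergence: float = float("nan")) -> OutcomeRecord:
    """Score one ORF against the known coding sequence.

    By default the combined result is scored; pass ``orf``/``fsc_attempted``
    explicitly to score a single path's candidate from the same run.
    """
    if orf is None:
        orf = result.orf_sequence if result is not None else ""
    if fsc_attempted is None:
        fsc_attempted = bool(result) and (
            result.decision_code in ("fsc_alignfs", "fsc_wise")
            or (result.decision_code == "identical" and result.corrections_applied > 0))
    rel = case.indel_pos / len(case.true_cds)
    if not orf:
        return OutcomeRecord(case.case_id, fsc_attempted, "not_found", 0.0,
                             source, rel, divergence)
    coverage = 100.0 * len(orf) / len(case.true_cds)
    frame_clean, mismatches, cds_lo, cds_hi = _frame_and_mismatch(orf, case.true_cds)
    covers_indel = cds_lo <= case.indel_pos < cds_hi
    if not frame_clean or mismatches:
        category = "inaccurate"
    elif covers_indel or fsc_attempted:
        category = "accurate"
    else:
        category = "truncated_in_frame"
    return OutcomeRecord(case.case_id, fsc_attempted, category, coverage,
                         source, rel, divergence)


def classify_batch(batch, cases: list[BenchmarkCase],
                   divergence: float = float("nan"),
                   per_path: bool = False) -> list[OutcomeRecord]:
    """Classify combined results and, optionally, each path's own candidate."""
    by_id = {r.transcript_id: r for r in batch.results}
    records: list[OutcomeRecord] = []
    for case in cases:
        r = by_id.get(case.case_id)
        records.append(classify_outcome(r, case, source="combined", divergence=divergence))
        if not per_path:
            continue
        af = r.alignfs_outcome if r else None
        af_orf = af.orf_sequence if af and af.decision != "no_orf" else ""
        records.append(classify_outcome(
            r, case, source="alignfs", orf=af_orf,
            fsc_attempted=bool(af and af.decision == "fsc_made"),
            divergence=divergence))
        wo = r.wise_outcome if r else None
        wo_orf = wo.orf_sequence if wo and wo.decision == "wise_orf" else ""
        records.append(classify_outcome(
            r, case, source="wise", orf=wo_orf,
            fsc_attempted=bool(wo and any(s.frameshift_ops for s in wo.segments)),
            divergence=divergence))
    return records


# ---------------------------------------------------------------------------
# summaries


def records_frame(records: list[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summarize(records: list[OutcomeRecord], group_by: str = "none") -> pd.DataFrame:
    """Counts and rates: totals, accuracy, coverage, perfect-FSC rate.

    ``group_by`` is ``none``, ``divergence``, ``position_bin`` (terciles of
    relative indel position) or ``source``.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = records_frame(records)
    if group_by == "none":
        df["_g"] = "all"
        key = "_g"
    elif group_by == "divergence":
        key = "divergence"
    elif group_by == "source":
        key = "source"
    elif group_by == "position_bin":
        df["position_bin"] = pd.cut(df["indel_relative_pos"], [0, 1 / 3, 2 / 3, 1],
                                    labels=["start", "middle", "end"])
        key = "position_bin"
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    rows = []
    for g, sub in df.groupby(key, observed=True, sort=True):
        with_orf = sub[sub["category"] != "not_found"]
        attempted = sub[sub["fsc_attempted"]]
        rows.append({
            group_by if group_by != "none" else "group": g,
            "total_orfs": len(with_orf),
            "accurate": int((with_orf["category"] == "accurate").sum()),
            "inaccurate": int((with_orf["category"] == "inaccurate").sum()),
            "truncated_in_frame": int((with_orf["category"] == "truncated_in_frame").sum()),
            "not_found": int((sub["category"] == "not_found").sum()),
            "mean_cds_coverage": float(with_orf["cds_coverage"].mean()) if len(with_orf) else 0.0,
            "fsc_attempted": len(attempted),
            "perfect_fsc_rate": (float((attempted["category"] == "accurate").mean())
                                 if len(attempted) else float("nan")),
        })
    return pd.DataFrame(rows)
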