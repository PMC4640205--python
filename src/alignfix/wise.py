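"""Frameshift-aware protein-to-DNA local alignment (spliced-transcript mode).

A guide protein is aligned against a nucleotide sequence by dynamic
programming over codon-level states: a match state consuming 3 bases,
frameshift states consuming 1, 2, 4 or 5 bases (penalised), a codon-sized
gap in the protein (extra DNA codons, kept in the ORF) and a gap in the
DNA (protein residues skipped).  There are no intron states: input is
assumed to be spliced transcript sequence.

Frameshift codons are scored completion-aware: a 2-base codon is scored by
the best completion over the three possible positions of the lost base, a
4(5)-base codon by the best choice of surplus base(s) to drop.  The
traceback emits the arg-max variant — ``N`` placed where the lost base
most plausibly sat, surplus bases actually removed — so the emitted ORF
stays in frame and the placeholder lands at the damaged position.

High-scoring segments are found best-first (the DP re-runs on the flanking
subproblems, which keeps segments colinear), stitched in order, and the
longest resulting ORF is returned with all frameshift edits applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Optional

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_ALPHABET = _BLOSUM62.alphabet  # includes X and *
_AA_INDEX = {aa: i for i, aa in enumerate(_AA_ALPHABET)}
_SUBMAT = np.asarray(_BLOSUM62, dtype=np.float64)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"


def _codon_aa(codon: str) -> str:
    if "N" in codon:
        return "X"
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table.get(codon, "X")


# codon -> amino-acid index over base-5 codon codes (N-containing -> X)
_CODON_AA = np.empty(125, dtype=np.int32)
for _b0 in range(5):
    for _b1 in range(5):
        for _b2 in range(5):
            _codon = "ACGTN"[_b0] + "ACGTN"[_b1] + "ACGTN"[_b2]
            _CODON_AA[25 * _b0 + 5 * _b1 + _b2] = _AA_INDEX[_codon_aa(_codon)]

_MAX_VARIANTS = 20  # distinct amino acids reachable from a partial codon


@lru_cache(maxsize=None)
def _fs2_variants(pair: str) -> tuple[tuple[int, str], ...]:
    """(aa index, emitted codon) for each lost-base position of a 2-base codon."""
    out: dict[tuple[int, str], None] = {}
    for npos in range(3):
        emitted = pair[:npos] + "N" + pair[npos:]
        for b in _BASES:
            codon = pair[:npos] + b + pair[npos:]
            out[(_AA_INDEX[_codon_aa(codon)], emitted)] = None
    return tuple(out)


@lru_cache(maxsize=None)
def _fs1_variants(base: str) -> tuple[tuple[int, str], ...]:
    """(aa index, emitted codon) for each position of the single kept base."""
    out: dict[tuple[int, str], None] = {}
    for kpos in range(3):
        emitted = "N" * kpos + base + "N" * (2 - kpos)
        for b1 in _BASES:
            for b2 in _BASES:
                pads = b1 + b2
                codon = pads[:kpos] + base + pads[kpos:]
                out[(_AA_INDEX[_codon_aa(codon)], emitted)] = None
    return tuple(out)


@lru_cache(maxsize=None)
def _fsn_variants(bases: str) -> tuple[tuple[int, str], ...]:
    """(aa index, emitted codon) for each way to drop surplus bases to 3."""
    out: dict[tuple[int, str], None] = {}
    for keep in combinations(range(len(bases)), 3):
        codon = "".join(bases[k] for k in keep)
        out[(_AA_INDEX[_codon_aa(codon)], codon)] = None
    return tuple(out)


def _variants_for(chunk: str, consume: int) -> tuple[tuple[int, str], ...]:
    if "N" in chunk:
        emitted = ("N" + chunk) if consume == 2 else ("NN" + chunk if consume == 1
                                                      else chunk[-3:])
        return ((_AA_INDEX["X"], emitted),)
    if consume == 1:
        return _fs1_variants(chunk)
    if consume == 2:
        return _fs2_variants(chunk)
    return _fsn_variants(chunk)


def _fill_variants(dna: str, consume: int) -> np.ndarray:
    nd = len(dna)
    arr = np.full((nd + 1, _MAX_VARIANTS), -1, dtype=np.int32)
    for j in range(consume, nd + 1):
        aas = sorted({aa for aa, _ in _variants_for(dna[j - consume : j], consume)})
        arr[j, : len(aas)] = aas
    return arr


def _variant_arrays(dna: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """aa-index variant tables for 1-, 2-, 4- and 5-base codons ending at j."""
    return (_fill_variants(dna, 1), _fill_variants(dna, 2),
            _fill_variants(dna, 4), _fill_variants(dna, 5))


# traceback op codes for the main state
_OP_START, _OP_MATCH3, _OP_FS1, _OP_FS2, _OP_FS4, _OP_FS5, _OP_DNAGAP, _OP_PROTGAP = range(8)


@dataclass
class WiseParams:
    """Scoring parameters for the protein-to-DNA aligner.

    Scores are in BLOSUM62 half-bit units.  ``frameshift_penalty`` is the
    cost of entering a 1/2/4/5-base codon; gap penalties apply per codon
    (DNA side) or per residue (protein side).  ``gap_open <= gap_extend``
    is required (opening is never cheaper than extending).
    """

    gap_open: float = -12.0
    gap_extend: float = -2.0
    frameshift_penalty: float = -15.0
    segment_score_threshold: float = 25.0

    def __post_init__(self) -> None:
        if self.frameshift_penalty >= 0:
            raise ValueError("frameshift_penalty must be negative")
        if self.gap_open > self.gap_extend or self.gap_extend >= 0:
            raise ValueError("require gap_open <= gap_extend < 0")


@dataclass
class WiseSegment:
    """One locally aligned protein/DNA block with its frameshift edits."""

    dna_start: int  # 0-based half-open on the input dna
    dna_end: int
    protein_start: int
    protein_end: int
    score: float
    frameshift_ops: list[tuple[int, str]] = field(default_factory=list)  # (dna_pos, kind)
    emitted: str = ""  # in-frame DNA with pads inserted / skips removed


@dataclass
class WiseOutcome:
    orf_sequence: str
    segments: list[WiseSegment]
    decision: str  # wise_orf | no_orf


def encode_protein(protein: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(aa, _AA_INDEX["X"]) for aa in protein.upper()],
                    dtype=np.int32)


def encode_dna_codons(dna: str) -> np.ndarray:
    """aa index of the codon *ending* at position j (j >= 3), else -1."""
    codes = np.array([_BASE_INDEX.get(b, 4) for b in dna.upper()], dtype=np.int32)
    out = np.full(len(dna) + 1, -1, dtype=np.int32)
    for j in range(3, len(dna) + 1):
        out[j] = _CODON_AA[25 * codes[j - 3] + 5 * codes[j - 2] + codes[j - 1]]
    return out


@njit(cache=True)
def _dp_kernel(prot, aa_at, var1, var2, var4, var5, submat,
               gap_open, gap_extend, fs_pen):  # pragma: no cover
    npr = prot.shape[0]
    nd = aa_at.shape[0] - 1
    NEG = -1e18
    H = np.zeros((npr + 1, nd + 1), dtype=np.float64)
    Ix = np.full((npr + 1, nd + 1), NEG, dtype=np.float64)
    Iy = np.full((npr + 1, nd + 1), NEG, dtype=np.float64)
    ptrH = np.zeros((npr + 1, nd + 1), dtype=np.int8)
    ptrIx = np.zeros((npr + 1, nd + 1), dtype=np.int8)  # 0 open, 1 extend
    ptrIy = np.zeros((npr + 1, nd + 1), dtype=np.int8)
    nvar = var2.shape[1]

    for i in range(1, npr + 1):
        ai = prot[i - 1]
        for j in range(1, nd + 1):
            best = 0.0
            op = 0
            if j >= 3 and aa_at[j] >= 0:
                s = H[i - 1, j - 3] + submat[ai, aa_at[j]]
                if s > best:
                    best = s
                    op = 1
            vbest = NEG
            for k in range(nvar):
                v = var1[j, k]
                if v < 0:
                    break
                if submat[ai, v] > vbest:
                    vbest = submat[ai, v]
            s = H[i - 1, j - 1] + fs_pen + vbest
            if s > best:
                best = s
                op = 2
            if j >= 2:
                vbest = NEG
                for k in range(nvar):
                    v = var2[j, k]
                    if v < 0:
                        break
                    if submat[ai, v] > vbest:
                        vbest = submat[ai, v]
                s = H[i - 1, j - 2] + fs_pen + vbest
                if s > best:
                    best = s
                    op = 3
            if j >= 4:
                vbest = NEG
                for k in range(nvar):
                    v = var4[j, k]
                    if v < 0:
                        break
                    if submat[ai, v] > vbest:
                        vbest = submat[ai, v]
                s = H[i - 1, j - 4] + fs_pen + vbest
                if s > best:
                    best = s
                    op = 4
            if j >= 5:
                vbest = NEG
                for k in range(nvar):
                    v = var5[j, k]
                    if v < 0:
                        break
                    if submat[ai, v] > vbest:
                        vbest = submat[ai, v]
                s = H[i - 1, j - 5] + fs_pen + vbest
                if s > best:
                    best = s
                    op = 5
            # codon-sized gap in the protein (extra DNA codon)
            if j >= 3:
                o = H[i, j - 3] + gap_open
                e = Ix[i, j - 3] + gap_extend
                if o >= e:
                    Ix[i, j] = o
                    ptrIx[i, j] = 0
                else:
                    Ix[i, j] = e
                    ptrIx[i, j] = 1
                if Ix[i, j] > best:
                    best = Ix[i, j]
                    op = 6
            # gap in the DNA (protein residue skipped)
            o = H[i - 1, j] + gap_open
            e = Iy[i - 1, j] + gap_extend
            if o >= e:
                Iy[i, j] = o
                ptrIy[i, j] = 0
            else:
                Iy[i, j] = e
                ptrIy[i, j] = 1
            if Iy[i, j] > best:
                best = Iy[i, j]
                op = 7
            H[i, j] = best
            ptrH[i, j] = op
    return H, Ix, Iy, ptrH, ptrIx, ptrIy


def _best_fs_emission(dna_chunk: str, ai: int, n_consumed: int) -> str:
    """Arg-max emitted codon for a frameshift state (stable over ties)."""
    variants = _variants_for(dna_chunk, n_consumed)
    best = max(enumerate(variants), key=lambda kv: (_SUBMAT[ai, kv[1][0]], -kv[0]))
    return best[1][1]


def _traceback(dna: str, prot: np.ndarray, H, ptrH, ptrIx, ptrIy, i: int, j: int,
               dna_offset: int, prot_offset: int) -> WiseSegment:
    score = H[i, j]
    emitted_rev: list[str] = []
    fs_ops: list[tuple[int, str]] = []
    end_i, end_j = i, j
    state = "H"
    while True:
        if state == "H":
            op = ptrH[i, j]
            if op == _OP_START or H[i, j] <= 0:
                break
            ai = prot[i - 1]
            if op == _OP_MATCH3:
                emitted_rev.append(dna[j - 3 : j])
                i, j = i - 1, j - 3
            elif op == _OP_FS1:
                emitted_rev.append(_best_fs_emission(dna[j - 1], ai, 1))
                fs_ops.append((dna_offset + j - 1, "pad2"))
                i, j = i - 1, j - 1
            elif op == _OP_FS2:
                emitted_rev.append(_best_fs_emission(dna[j - 2 : j], ai, 2))
                fs_ops.append((dna_offset + j - 2, "pad1"))
                i, j = i - 1, j - 2
            elif op == _OP_FS4:
                emitted_rev.append(_best_fs_emission(dna[j - 4 : j], ai, 4))
                fs_ops.append((dna_offset + j - 4, "skip1"))
                i, j = i - 1, j - 4
            elif op == _OP_FS5:
                emitted_rev.append(_best_fs_emission(dna[j - 5 : j], ai, 5))
                fs_ops.append((dna_offset + j - 5, "skip2"))
                i, j = i - 1, j - 5
            elif op == _OP_DNAGAP:
                state = "Ix"
            elif op == _OP_PROTGAP:
                state = "Iy"
        elif state == "Ix":
            emitted_rev.append(dna[j - 3 : j])
            nxt = ptrIx[i, j]
            j -= 3
            if nxt == 0:
                state = "H"
        else:  # Iy
            nxt = ptrIy[i, j]
            i -= 1
            if nxt == 0:
                state = "H"
    fs_ops.reverse()
    emitted_rev.reverse()
    return WiseSegment(
        dna_start=dna_offset + j,
        dna_end=dna_offset + end_j,
        protein_start=prot_offset + i,
        protein_end=prot_offset + end_i,
        score=float(score),
        frameshift_ops=fs_ops,
        emitted="".join(emitted_rev),
    )


def _run_dp(protein: str, dna: str, params: WiseParams):
    prot = encode_protein(protein)
    aa_at = encode_dna_codons(dna)
    var1, var2, var4, var5 = _variant_arrays(dna)
    return prot, _dp_kernel(prot, aa_at, var1, var2, var4, var5, _SUBMAT,
                            params.gap_open, params.gap_extend,
                            params.frameshift_penalty)


def align_protein_dna(protein: str, dna: str,
                      params: Optional[WiseParams] = None) -> list[WiseSegment]:
    """All non-overlapping local segments above the score threshold, best first.

    The best segment is found by the DP; the search then recurses on the
    protein/DNA regions before and after it, so returned segments are
    mutually colinear.  Ties in the DP prefer a codon match over a
    frameshift over a gap, and the earlier DNA position.
    """
    params = params or WiseParams()
    segments: list[WiseSegment] = []

    def solve(p_lo: int, p_hi: int, d_lo: int, d_hi: int) -> None:
        if p_hi - p_lo < 2 or d_hi - d_lo < 3:
            return
        sub_dna = dna[d_lo:d_hi]
        prot, (H, Ix, Iy, ptrH, ptrIx, ptrIy) = _run_dp(
            protein[p_lo:p_hi], sub_dna, params)
        flat = int(np.argmax(H))
        i, j = divmod(flat, H.shape[1])
        if H[i, j] < params.segment_score_threshold:
            return
        seg = _traceback(sub_dna, prot, H, ptrH, ptrIx, ptrIy, i, j, d_lo, p_lo)
        segments.append(seg)
        solve(p_lo, seg.protein_start, d_lo, seg.dna_start)
        solve(seg.protein_end, p_hi, seg.dna_end, d_hi)

    solve(0, len(protein), 0, len(dna))
    segments.sort(key=lambda s: -s.score)
    return segments


def best_local_score(protein: str, dna: str, params: Optional[WiseParams] = None) -> float:
    """Optimal local alignment score only (no traceback)."""
    params = params or WiseParams()
    _, (H, *_rest) = _run_dp(protein, dna, params)
    return float(H.max())


def stitch_and_select(segments: list[WiseSegment], dna: str) -> WiseOutcome:
    """Chain colinear segments and return the longest stitched ORF.

    Mutually overlapping segments compete: chains are valued by total
    emitted length ("the longest ORF"), summed score breaking ties; the
    emitted DNA of the winning chain (frameshift edits already applied per
    segment) is concatenated in order.
    """
    if not segments:
        return WiseOutcome("", [], "no_orf")
    segs = sorted(segments, key=lambda s: (s.dna_start, s.protein_start))
    n = len(segs)
    best_val = [(len(s.emitted), s.score) for s in segs]
    prev = [-1] * n
    for i in range(n):
        for k in range(i):
            if (segs[k].dna_end <= segs[i].dna_start
                    and segs[k].protein_end <= segs[i].protein_start):
                cand = (best_val[k][0] + len(segs[i].emitted),
                        best_val[k][1] + segs[i].score)
                if cand > best_val[i]:
                    best_val[i] = cand
                    prev[i] = k
    end = max(range(n), key=lambda i: best_val[i])
    chain: list[WiseSegment] = []
    while end != -1:
        chain.append(segs[end])
        end = prev[end]
    chain.reverse()
    orf = "".join(s.emitted for s in chain)
    return WiseOutcome(orf, chain, "wise_orf" if orf else "no_orf")


# ---------------------------------------------------------------------------
# independent oracle (tests only, tiny inputs): memoised recursion over the
# same scoring objective with an explicit cap on the number of frameshift ops


def brute_force_best_score(protein: str, dna: str, params: Optional[WiseParams] = None,
                           max_frameshifts: int = 2) -> float:
    params = params or WiseParams()
    prot = protein.upper()
    pidx = [_AA_INDEX.get(a, _AA_INDEX["X"]) for a in prot]
    NEG = float("-inf")

    def fs_score(ai: int, j: int, consume: int) -> float:
        chunk = dna[j - consume : j]
        return max(float(_SUBMAT[ai, v]) for v, _ in _variants_for(chunk, consume))

    def match_score(ai: int, j: int) -> float:
        codon = dna[j - 3 : j]
        return float(_SUBMAT[ai, _AA_INDEX[_codon_aa(codon)]])

    @lru_cache(maxsize=None)
    def ending_at(i: int, j: int, state: str, fs: int) -> float:
        # best score of a local alignment ending at protein[:i], dna[:j] in `state`
        if state == "H":
            best = 0.0
            if i >= 1:
                if j >= 3:
                    best = max(best, ending_at(i - 1, j - 3, "H", fs)
                               + match_score(pidx[i - 1], j))
                if fs >= 1:
                    for consume in (1, 2, 4, 5):
                        if j >= consume:
                            best = max(best,
                                       ending_at(i - 1, j - consume, "H", fs - 1)
                                       + params.frameshift_penalty
                                       + fs_score(pidx[i - 1], j, consume))
            best = max(best, ending_at(i, j, "Ix", fs), ending_at(i, j, "Iy", fs))
            return best
        if state == "Ix":
            if j < 3:
                return NEG
            return max(ending_at(i, j - 3, "H", fs) + params.gap_open,
                       ending_at(i, j - 3, "Ix", fs) + params.gap_extend)
        if i < 1:
            return NEG
        return max(ending_at(i - 1, j, "H", fs) + params.gap_open,
                   ending_at(i - 1, j, "Iy", fs) + params.gap_extend)

    best = 0.0
    for i in range(len(prot) + 1):
        for j in range(len(dna) + 1):
            best = max(best, ending_at(i, j, "H", max_frameshifts))
    return best
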