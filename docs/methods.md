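# Methods

`alignfix` identifies protein-coding regions in assembled transcripts (ESTs,
de-novo RNA-seq contigs) by homology, corrects erroneous frame-shifts caused
by insertion/deletion sequencing errors, and reports one in-frame DNA
sequence per transcript.  In-frame DNA is the input that codon substitution
models require, so the tool is aimed at phylogenetic pipelines working on
species without a reference genome.  This note records the model, the
tunable parameters, the numerical choices, and what the synthetic benchmark
does and does not demonstrate.

## Pipeline model

For each transcript:

1. **Coding test.**  A translated (six-frame) search against a protein
   database.  The transcript is protein-coding if the top hit's e-value is
   ≤ 1e-3; everything else is discarded.  The putative ORF spans from the
   earliest start to the furthest end over all HSPs of the top hit, even
   when the HSPs do not overlap — a frame-shift splits one protein hit into
   two HSPs in different frames, and the merged span recovers the full
   region.  Minus-strand hits flip the working sequence to the reverse
   complement.  HSPs on the opposite strand from the best-scoring HSP are
   ignored during merging; ties on e-value break by summed bit score, then
   subject id, so runs are reproducible.
2. **Gap-analysis correction** (the conservative path).  The whole
   transcript is searched against a nucleotide database of *in-frame* coding
   sequences (e ≤ 1e-10); up to `k` homologs (default 3) are globally
   aligned with the transcript, and gap runs whose length is not divisible
   by three are interpreted as frame-shifts.  Gaps in the transcript row are
   deletions, repaired by inserting placeholder `N`s; gaps conserved across
   all homolog rows are insertions, repaired by removing bases.  Run length
   1, 2 and 4 get 1, 2 and 1 edits respectively (a 4-base gap is one lost
   base plus an in-frame 3-base deletion).  Runs of ≥ 5 are processed per
   end against the codon frame of the best homolog row that spans the run
   without gaps: the start end completes the codon broken at the gap start
   (`(3 − phase) mod 3` Ns), the far end completes the codon straddling the
   gap end (`(phase_start + run_length) mod 3` Ns); the two edits together
   always restore frame.  For conserved-homolog (insertion) runs both ends
   see the same reference phase, so a single deletion of `length mod 3`
   bases is emitted.  Gaps within 3 bases of the region boundary, and runs
   carried by only a minority of homolog rows (a frame-shifted homolog),
   are skipped.
3. **Quality gates.**  If fewer than `min_homologs` homologs are found, or
   mean transcript-homolog identity < 0.70, or any gap run exceeds 30
   columns, or gaps exceed 20 % of the alignment, no correction is
   attempted; the single top-HSP span is returned instead — truncated but
   very unlikely to contain an unnoticed frame-shift.
4. **Frameshift-aware protein-to-DNA alignment** (the liberal path).  The
   top-hit protein guides a local codon-level dynamic program over the
   working sequence with states for a 3-base codon match, 1/2/4/5-base
   frameshift codons, codon-sized DNA gaps and protein gaps — the
   spliced-transcript (no-intron) variant of the Genewise/ESTwise algorithm
   family.  Non-overlapping segments above a score threshold are chained
   colinearly and the longest stitched ORF is emitted with pads/skips
   applied, so the output is always in frame.
5. **Combiner.**  Both candidate proteins are aligned to the top-hit
   protein; the comparison score is the local alignment score weighted by
   the fraction of the reference covered, which rewards full-length
   agreement and rejects candidates that extend into non-coding sequence.
   The wise candidate replaces the gap-analysis candidate only when its
   score is more than 5 % higher (`WISE_PREFERENCE_MARGIN`): the
   gap-analysis corrections are conservative by construction, and a few
   extra codons of coverage should not flip the choice to the more
   aggressive aligner.  Identical proteins are reported as such.  Each
   transcript yields exactly one ORF (or a logged `no_hit`).

## Scoring and numerical choices

* Protein alignments use BLOSUM62 throughout (open −11 / extend −1 for
  search and candidate comparison, in half-bit units).
* The protein-to-DNA DP uses gap open −12 / extend −2 per codon and a
  frameshift penalty of −15, so one frameshift is preferred over breaking a
  long alignment; segments must score ≥ 25.  Frameshift codons are scored
  *completion-aware*: a 2-base codon scores the best completion over the
  three possible positions of the lost base; 4/5-base codons score the best
  choice of surplus bases to drop; the traceback emits that arg-max variant,
  so the `N` placeholder (or the removed base) lands at the most plausible
  in-codon position.  Ties prefer match over frameshift over gap and the
  earlier DNA coordinate; the whole DP is deterministic.
* The multiple alignment is built center-star around the transcript:
  each homolog is aligned to the transcript pairwise (global, match 2 /
  mismatch −3 / open −7 / extend −2, free end gaps) and the pairwise
  alignments are merged on transcript coordinates.  With the transcript as
  the natural anchor this reproduces exactly the row structure the gap
  scanner needs and is deterministic; an external multiple aligner is not
  required.
* Gate measurement and gap scanning are restricted to the alignment columns
  spanning the putative coding region, so terminal overhangs — UTRs, or
  homologs longer/shorter than the transcript — are not mistaken for
  alignment quality problems.
* ORF ends are trimmed (never extended) to a codon boundary.  A corrected
  ORF that still contains an internal stop is demoted to the top-HSP
  fallback (`internal_stop` in the log): an in-frame truncation is more
  useful downstream than a dubious correction.
* Homolog codon phase at an alignment column is the count of that row's
  residues left of the column, mod 3.  This is valid because the reference
  database keeps only ATG-initial, length-divisible-by-3 coding sequences
  (`prepdb` enforces both), and survives reverse complementing.
* Search runs through NCBI BLAST+ when the binaries are on `PATH`
  (blastx/blastn, tabular output, `-parse_seqids` indexing) and otherwise
  through an internal engine: six-frame translation, exact-word seeding
  (4 aa / 11 nt; 5 aa in `--fast` mode), local alignment, and
  Karlin–Altschul e-values from the total database residue count using the
  published gapped parameters for each scoring system.  Both engines
  return identical structures, and results always flow through the same
  downstream decisions.

## Synthetic benchmark

The generator draws a stop-free coding sequence (uniform sense codons, ATG
prepended, stop appended; lengths 300–3000 by default), derives `k = 3`
in-frame homologs by substitution-only divergence with a 3:1 bias toward
third codon positions (so protein similarity degrades realistically as
nucleotide divergence grows), and injects exactly one frame-disrupting
indel — by default a one-base insertion or deletion with equal probability;
2- and 4-base events are available — at a uniform position at least 9 bp
from either end.  Reference databases for the run are built from the
homologs, never from the true sequence.

Each output ORF is aligned to the known coding sequence with `N` as a
wildcard and classified: **accurate** (no mismatch, every internal gap a
multiple of three), **inaccurate** (a frame discontinuity or a mismatch),
**truncated-in-frame** (clean but stops short of the indel with no
correction attempted), or **not found**.  CDS coverage is
`100 × ORF length / CDS length` and can exceed 100 for over-extended ORFs.
The *perfect-FSC rate* is the fraction of accurate outcomes among
transcripts where the reported sequence contains a frame-shift correction.

What the generator does **not** emulate: real error processes
(homopolymer-biased indels), UTR base composition, paralogy, homolog
length variation, or alignment-confounding indels between true homologs
(divergence is substitution-only by design, to isolate evolutionary
distance as the swept variable).  Passing benchmarks therefore demonstrate
correctness of the decision logic and frame arithmetic under controlled
conditions, not end-to-end accuracy on real transcriptomes.

Scale choices: the shipped analyses run 500 cases per condition with CDS
lengths 300–1500 and a mixed indel-kind distribution
(del1/ins1/del2/ins2/del4 = 0.30/0.30/0.15/0.15/0.10), and a four-point
homolog-divergence grid {0.01, 0.05, 0.15, 0.30}.  These sizes give
binomial standard errors of ~1–2 percentage points on the reported rates.

## Observed behaviour and limitations

* The gap-analysis path is highly accurate where it acts: its corrections
  are near-perfect at low divergence, and its attempt count (not its
  per-attempt accuracy) falls as divergence grows, because the identity
  gate pushes noisy alignments to the conservative top-HSP fallback.
* The protein-to-DNA path attempts a correction almost always, and its
  placement accuracy declines with guide-protein divergence: a guide
  mismatch adjacent to the frameshift can relocate the DP's frameshift
  state by a codon, which shows up as a one-base placement error against
  the true sequence.  This is intrinsic to single-guide homology placement
  under a substitution-only divergence model.
* The combined mode consequently attempts more corrections than the
  gap-analysis path alone and recovers more accurate ORFs overall at every
  divergence level than either path individually, while its per-attempt
  rate sits between the two paths'.
* Only indel-class errors are corrected; substitutions are left alone.
  Homolog/reference sequences are trusted to be in frame; frame-shifts
  inside them are not corrected (a majority rule ignores a single
  frame-shifted homolog).
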