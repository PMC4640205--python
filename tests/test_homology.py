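"""Hit modelling, coding-region identification and database preparation."""

import pytest

from alignfix.homology import (
    HitTableError,
    HomologyHit,
    Hsp,
    identify_coding_region,
    load_hit_table,
    prepare_reference_db,
    select_homologs,
)
from alignfix.seqs import Transcript, revcomp, write_fasta


def hit(sid, *hsps, kind="protein", seq=None):
    return HomologyHit(subject_id=sid, subject_kind=kind,
                       hsps=list(hsps), subject_seq=seq)


def hsp(qs, qe, frame=1, evalue=1e-20, bits=100.0, ss=1, se=50):
    return Hsp(qs, qe, ss, se, frame, evalue, bits)


@pytest.fixture
def transcript():
    return Transcript.from_raw("t1", "ACGT" * 100)


class TestIdentifyCodingRegion:
    def test_above_threshold_is_not_coding(self, transcript):
        hits = [hit("p1", hsp(10, 100, evalue=1e-2))]
        assert identify_coding_region(transcript, hits, 1e-3) is None

    def test_nonoverlapping_hsps_merge_to_full_span(self, transcript):
        hits = [hit("p1", hsp(10, 100), hsp(150, 300, evalue=1e-10), seq="M" * 97)]
        region = identify_coding_region(transcript, hits)
        assert (region.start, region.end) == (10, 300)
        assert region.origin == "merged_hsps"
        assert region.top_hit_protein == "M" * 97

    def test_minus_strand_hit_flips_working_sequence(self, transcript):
        L = len(transcript)
        hits = [hit("p1", hsp(25, 250, frame=-2))]
        region = identify_coding_region(transcript, hits)
        assert region.strand == "-"
        assert region.working_sequence == revcomp(transcript.sequence)
        assert (region.start, region.end) == (L - 250 + 1, L - 25 + 1)

    def test_strand_normalization_idempotent(self, transcript):
        """Searching the reverse complement finds the same working sequence."""
        L = len(transcript)
        fwd = identify_coding_region(transcript, [hit("p1", hsp(25, 250, frame=2))])
        rc = Transcript.from_raw("t1rc", revcomp(transcript.sequence))
        # the same biological hit seen from the flipped query
        back = identify_coding_region(
            rc, [hit("p1", hsp(L - 250 + 1, L - 25 + 1, frame=-2))])
        assert back.working_sequence == fwd.working_sequence
        assert (back.start, back.end) == (fwd.start, fwd.end)

    def test_merged_region_contains_every_hsp_span(self, transcript):
        spans = [(10, 60), (80, 130), (200, 260)]
        hits = [hit("p1", *[hsp(a, b) for a, b in spans])]
        region = identify_coding_region(transcript, hits)
        for a, b in spans:
            assert region.start <= a and b <= region.end

    def test_opposite_strand_hsps_ignored_in_merge(self, transcript):
        hits = [hit("p1", hsp(10, 100, frame=1, evalue=1e-30),
                    hsp(200, 300, frame=-1, evalue=1e-5))]
        region = identify_coding_region(transcript, hits)
        assert (region.start, region.end) == (10, 100)

    def test_malformed_hit_rejected_next_considered(self, transcript):
        bad = HomologyHit("p0", "protein",
                          [Hsp(100, 10, 1, 30, 1, 1e-40, 200.0)])
        good = hit("p1", hsp(10, 100, evalue=1e-10))
        region = identify_coding_region(transcript, [bad, good])
        assert region.top_hit_id == "p1"

    def test_threshold_monotonicity(self, transcript):
        """Raising the e-value threshold never loses a coding call."""
        hits = [hit("p1", hsp(10, 100, evalue=1e-4))]
        strict = identify_coding_region(transcript, hits, 1e-5)
        loose = identify_coding_region(transcript, hits, 1e-3)
        assert strict is None and loose is not None


class TestSelectHomologs:
    def make_hits(self, evalues):
        return [hit(f"s{i}", hsp(1, 100, evalue=e), kind="nucleotide",
                    seq="ATG" + "AAA" * 20)
                for i, e in enumerate(evalues)]

    def test_threshold_and_k(self, transcript):
        hits = self.make_hits([1e-50, 1e-20, 1e-12, 1e-8])
        out = select_homologs(transcript, hits, k=3, evalue_threshold=1e-10)
        assert [h.id for h in out] == ["s0", "s1", "s2"]

    def test_zero_passing_hits(self, transcript):
        assert select_homologs(transcript, self.make_hits([1e-5]), k=3) == []

    def test_k_configurable(self, transcript):
        hits = self.make_hits([1e-50, 1e-40, 1e-30, 1e-20, 1e-15])
        assert len(select_homologs(transcript, hits, k=4)) == 4

    def test_minus_hit_reverse_complemented(self, transcript):
        seq = "ATGCCCGGGTTTAAACCC"
        h = hit("s0", hsp(1, 18, frame=-1), kind="nucleotide", seq=seq)
        out = select_homologs(transcript, [h], k=1)
        assert out[0].sequence == revcomp(seq)

    def test_unretrievable_subject_skipped(self, transcript):
        hits = [hit("gone", hsp(1, 100, evalue=1e-50), kind="nucleotide", seq=None),
                hit("here", hsp(1, 100, evalue=1e-20), kind="nucleotide", seq="ATGAAATAA")]
        out = select_homologs(transcript, hits, k=1)
        assert [h.id for h in out] == ["here"]


class TestHitTable:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert load_hit_table(p) == {}

    def test_round_trip_row(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("t1\ts1\t98.5\t100\t1\t0\t5\t304\t1\t100\t1e-30\t180.3\t2\n")
        hits = load_hit_table(p, subject_kind="protein")
        (h,) = hits["t1"]
        assert h.best_evalue == pytest.approx(1e-30)
        assert h.hsps[0].query_start == 5 and h.hsps[0].query_end == 304
        assert h.hsps[0].frame == 2

    def test_reversed_coords_on_plus_frame_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("t1\ts1\t98.5\t100\t1\t0\t304\t5\t1\t100\t1e-30\t180.3\t1\n")
        with pytest.raises(HitTableError, match="line 1"):
            load_hit_table(p)

    def test_xml_dialect_round_trip(self, tmp_path):
        from alignfix.search import export_hits_xml

        hits = {"t1": [hit("s1", hsp(5, 304, frame=2, evalue=1e-30, bits=180.0))]}
        p = tmp_path / "hits.xml"
        export_hits_xml(hits, p)
        loaded = load_hit_table(p, dialect="xml", subject_kind="protein")
        (h,) = loaded["t1"]
        assert h.hsps[0].query_start == 5
        assert h.hsps[0].query_end == 304
        assert h.hsps[0].frame == 2


class TestPrepareReferenceDb:
    def test_atg_and_frame_filters(self, tmp_path):
        write_fasta(tmp_path / "cds.fasta", [
            ("ok", "ATGAAATGA"),
            ("noatg", "CTGAAATGA"),
            ("offframe", "ATGAAATGAG"),
        ])
        write_fasta(tmp_path / "prot.fasta", [("p1", "MKWVLF")])
        bundle = prepare_reference_db(tmp_path / "cds.fasta", tmp_path / "prot.fasta",
                                      tmp_path / "db", run_makeblastdb=False)
        assert set(bundle.nucleotides) == {"ok"}
        assert bundle.report["cds_dropped"] == 2
        assert bundle.report["cds_drop_reasons"]["offframe"] == "not in frame"

    def test_kept_translations_never_truncate_mid_codon(self, tmp_path, rng):
        from tests.conftest import random_cds

        entries = [(f"c{i}", random_cds(rng, 20)) for i in range(5)]
        write_fasta(tmp_path / "cds.fasta", entries)
        write_fasta(tmp_path / "prot.fasta", [("p1", "MKWVLF")])
        bundle = prepare_reference_db(tmp_path / "cds.fasta", tmp_path / "prot.fasta",
                                      tmp_path / "db", run_makeblastdb=False)
        for seq in bundle.nucleotides.values():
            assert len(seq) % 3 == 0

    def test_empty_output_is_an_error(self, tmp_path):
        write_fasta(tmp_path / "cds.fasta", [("bad", "CTGAAATGA")])
        write_fasta(tmp_path / "prot.fasta", [("p1", "MKWVLF")])
        with pytest.raises(ValueError, match="empty"):
            prepare_reference_db(tmp_path / "cds.fasta", tmp_path / "prot.fasta",
                                 tmp_path / "db", run_makeblastdb=False)
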