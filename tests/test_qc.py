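"""Translation screen, compliance flags and Folmer-space indel detection."""

import numpy as np
import pytest
from Bio.Data import CodonTable

from barcaudit.qc import (
    anchor_align,
    compliance_check,
    detect_indels,
    translate_codon,
    translate_screen,
)
from conftest import make_record

TABLE5 = CodonTable.unambiguous_dna_by_id[5]
BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


class TestTranslateScreen:
    def test_no_stops(self):
        assert translate_screen("ATGTTT", frame=1).n_stops == 0

    def test_forced_stop_position(self):
        s = translate_screen("ATGTAAATT", frame=1)
        assert s.stop_positions == [4]

    def test_aga_agg_are_serine_not_stop(self):
        # the invertebrate mitochondrial code reassigns AGA/AGG to serine
        s = translate_screen("AGAAGG", frame=1)
        assert s.n_stops == 0
        assert s.protein == "SS"

    def test_all_64_codons_match_translation_table_5(self):
        for codon in ALL_CODONS:
            expected = "*" if codon in TABLE5.stop_codons else TABLE5.forward_table[codon]
            assert translate_codon(codon) == expected

    def test_concatenated_non_stop_codons_have_zero_stops(self):
        non_stop = [c for c in ALL_CODONS if c not in TABLE5.stop_codons]
        assert translate_screen("".join(non_stop), frame=1).n_stops == 0

    def test_ambiguity_codons_never_count_as_stops(self):
        # TAN could resolve to TAA/TAG; ambiguity must translate to X
        s = translate_screen("TANTAR", frame=1)
        assert s.n_stops == 0
        assert s.protein == "XX"

    def test_best_frame_selection_prefers_fewest_stops(self):
        # TAA at frame 1; shifting one base removes it
        seq = "TAA" + "ATG" * 20
        s = translate_screen(seq)
        assert s.n_stops == 0
        assert s.frame > 1

    def test_frame_tie_breaks_to_lowest(self):
        assert translate_screen("ATGATGATG").frame == 1

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            translate_screen("AT")


class TestCompliance:
    def test_clean_full_length_passes(self, base_seq):
        rec = make_record("ok", base_seq)
        assert compliance_check(rec).passed

    def test_short_sequence_flagged(self, base_seq):
        rec = make_record("short", base_seq[:480])
        res = compliance_check(rec)
        assert res.flags == {"too_short"}

    def test_excess_ambiguity_at_1_52_percent(self, base_seq):
        seq = "N" * 10 + base_seq[10:]
        res = compliance_check(make_record("amb", seq))
        assert "excess_ambiguity" in res.flags
        assert res.details["excess_ambiguity"]["fraction"] == pytest.approx(10 / 658)

    def test_ambiguity_below_threshold_passes(self, base_seq):
        seq = "N" * 6 + base_seq[6:]  # 0.91% < 1%
        assert "excess_ambiguity" not in compliance_check(make_record("a", seq)).flags

    def test_stop_codon_flag(self, base_seq):
        seq = base_seq[:300] + "TAA" + base_seq[303:]
        res = compliance_check(make_record("st", seq), frame=1)
        assert "stop_codon" in res.flags

    def test_frameshift_from_non_triplet_indel(self, base_seq):
        from barcaudit.qc import IndelEvent

        ev = IndelEvent("fs", "deletion", 100, 101)  # 2 bp
        res = compliance_check(make_record("fs", base_seq), indel_events=[ev])
        assert "frameshift" in res.flags
        assert not ev.frame_preserving

    def test_passed_iff_flags_empty(self, base_seq):
        res = compliance_check(make_record("ok", base_seq))
        assert res.passed == (not res.flags)


class TestAnchorAlign:
    def test_self_alignment(self, base_seq):
        a = anchor_align(base_seq, base_seq)
        assert a.identity == 1.0
        assert "-" not in a.ref_row + a.query_row
        assert detect_indels(a) == []

    def test_deletion_at_358_360(self, base_seq):
        query = base_seq[:357] + base_seq[360:]
        a = anchor_align(query, base_seq, query_id="del")
        events = detect_indels(a)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "deletion"
        assert ev.frame_preserving
        # coordinates match the canonical (leftmost) placement of a 3-bp cut
        assert (ev.start, ev.end) == _oracle_leftmost_deletion(base_seq, query, 3)

    def test_ttg_insertion_reported_at_94_96(self, base_seq):
        # choose context so the canonical placement is exactly 94-96
        ref = list(base_seq)
        ref[92] = "A"  # position 93: not G, so no left shift of ...TTG
        ref = "".join(ref)
        query = ref[:93] + "TTG" + ref[93:]
        a = anchor_align(query, ref, query_id="ins")
        events = detect_indels(a)
        assert len(events) == 1
        ev = events[0]
        assert (ev.kind, ev.start, ev.end) == ("insertion", 94, 96)
        assert ev.inserted_motif == "TTG"
        assert ev.frame_preserving

    def test_partial_sequence_maps_into_folmer_coordinates(self, base_seq):
        a = anchor_align(base_seq[99:600], base_seq, query_id="part")
        cmap = a.coordinate_map()
        assert cmap[1] == 100
        assert cmap[len(base_seq[99:600])] == 600
        assert detect_indels(a) == []  # end gaps are not indels

    def test_non_homologous_raises(self, base_seq):
        with pytest.raises(ValueError, match="not homologous"):
            anchor_align("A" * 658, base_seq)

    def test_projection_has_reference_length(self, base_seq):
        query = base_seq[:93] + "TTG" + base_seq[93:]
        a = anchor_align(query, base_seq)
        assert len(a.project_to_reference()) == len(base_seq)


def _oracle_leftmost_insertion(ref, modified, length):
    """Brute-force canonical placement: smallest p with ref[:p]+m+ref[p:] == modified."""
    for p in range(len(ref) + 1):
        m = modified[p : p + length]
        if ref[:p] + m + ref[p:] == modified:
            return p + 1, p + length, m
    raise AssertionError("not a single insertion")


def _oracle_leftmost_deletion(ref, modified, length):
    for p in range(len(ref)):
        if ref[:p] + ref[p + length :] == modified:
            return p + 1, p + length
    raise AssertionError("not a single deletion")


def test_single_indel_recovered_exactly_over_random_positions(base_seq):
    """Any single in-frame 3k indel away from the ends is recovered with
    exact left-normalized coordinates."""
    rng = np.random.default_rng(11)
    for _ in range(40):
        length = 3 * int(rng.integers(1, 3))  # 3 or 6 bp
        if rng.random() < 0.5:
            pos = int(rng.integers(10, len(base_seq) - 10))
            motif = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
            query = base_seq[:pos] + motif + base_seq[pos:]
            want = _oracle_leftmost_insertion(base_seq, query, length)
            kind = "insertion"
        else:
            pos = int(rng.integers(10, len(base_seq) - 10 - length))
            query = base_seq[:pos] + base_seq[pos + length :]
            want = _oracle_leftmost_deletion(base_seq, query, length)
            kind = "deletion"
        events = detect_indels(anchor_align(query, base_seq, query_id="r"))
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == kind
        assert (ev.start, ev.end) == want[:2]
        if kind == "insertion":
            assert ev.inserted_motif == want[2]
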