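"""MOTU concordance classification, synonym review, reference matching and
barcode-based identification of open-nomenclature specimens."""

import pytest

from barcaudit.concordance import (
    classify_motus,
    match_reference,
    propagate_id,
    review,
    summarize_classes,
    summarize_counts,
)
from barcaudit.io import BarcodeLibrary, SynonymTable
from barcaudit.motu import MOTUAssignment
from conftest import make_record, mutate


def _assignment(mapping):
    return MOTUAssignment(
        mapping=mapping, threshold=0.022, n_motus=len(set(mapping.values()))
    )


def _library(*records):
    return BarcodeLibrary(list(records))


SEQ = "ACGT" * 10


class TestClassify:
    def test_uniform_motu_is_concordant(self):
        lib = _library(*[make_record(f"s{i}", SEQ, "Aa aa") for i in range(4)])
        a = _assignment({f"s{i}": 1 for i in range(4)})
        (c,) = classify_motus(a, lib)
        assert (c.status, c.discordance_rank) == ("concordant", "none")

    def test_two_names_discordant_at_species_rank(self):
        lib = _library(
            make_record("o1", SEQ, "Littorina obtusata"),
            make_record("o2", SEQ, "Littorina obtusata"),
            make_record("f1", SEQ, "Littorina fabalis"),
        )
        a = _assignment({"o1": 1, "o2": 1, "f1": 1})
        (c,) = classify_motus(a, lib)
        assert (c.status, c.discordance_rank) == ("discordant", "species")

    def test_different_genera_discordant_at_genus_rank(self):
        lib = _library(
            make_record("p1", SEQ, "Phorcus lineatus"),
            make_record("o1", SEQ, "Osilinus lineatus"),
        )
        a = _assignment({"p1": 1, "o1": 1})
        (c,) = classify_motus(a, lib)
        assert (c.status, c.discordance_rank) == ("discordant", "genus")

    def test_single_member_is_singleton(self):
        lib = _library(make_record("s1", SEQ, "Aa aa"))
        (c,) = classify_motus(_assignment({"s1": 1}), lib)
        assert c.status == "singleton"

    def test_open_nomenclature_does_not_cause_discordance(self):
        lib = _library(
            make_record("n1", SEQ, "Nassarius incrassatus"),
            make_record("n2", SEQ, "Nassarius incrassatus"),
            make_record("q1", SEQ, "", qualifier="sp", genus="Nassarius"),
        )
        (c,) = classify_motus(_assignment({"n1": 1, "n2": 1, "q1": 1}), lib)
        assert c.status == "concordant"
        assert c.n_members == 3

    def test_status_counts_partition_motus(self, graded_library):
        lib, _ = graded_library
        from barcaudit.distances import distance_matrix
        from barcaudit.motu import cluster

        a = cluster(distance_matrix(lib))
        classes = classify_motus(a, lib)
        by_status = {
            s: sum(c.status == s for c in classes)
            for s in ("concordant", "discordant", "singleton")
        }
        assert sum(by_status.values()) == a.n_motus


class TestReview:
    def _discordant(self, names):
        lib = _library(
            *[make_record(f"s{i}", SEQ, n) for i, n in enumerate(names)]
        )
        a = _assignment({f"s{i}": 1 for i in range(len(names))})
        return classify_motus(a, lib)

    def test_synonym_collapse_reclassifies(self):
        classes = self._discordant(["Osilinus lineatus", "Phorcus lineatus"])
        table = SynonymTable(
            {"Osilinus lineatus": "Phorcus lineatus"}, notes={"Osilinus lineatus": "WoRMS"}
        )
        (c,) = review(classes, table)
        assert c.review_status == "reclassified_concordant"
        assert "Osilinus lineatus = Phorcus lineatus" in c.review_reason
        assert "WoRMS" in c.review_reason

    def test_true_conflict_confirmed_discordant(self):
        classes = self._discordant(
            ["Littorina saxatilis", "Littorina compressa", "Littorina arcana"]
        )
        (c,) = review(classes, SynonymTable())
        assert c.review_status == "confirmed_discordant"

    def test_review_never_touches_concordant_or_singletons(self, graded_library):
        lib, _ = graded_library
        from barcaudit.distances import distance_matrix
        from barcaudit.motu import cluster

        classes = classify_motus(cluster(distance_matrix(lib)), lib)
        reviewed = review(classes, SynonymTable({"Zeta zeta": "Eta eta"}))
        for before, after in zip(classes, reviewed):
            if before.status in ("concordant", "singleton"):
                assert after.review_status == "as_reported"
                assert after.status == before.status


class TestSummaries:
    def test_counts_arithmetic(self):
        s = summarize_counts(23, 11, 1, 8, singletons_as_concordant=True)
        assert s.n_motus == 35
        assert s.n_concordant_after_review == 32
        assert s.pct_concordant == pytest.approx(100 * 32 / 35)
        assert s.pct_concordant_display == 91.4

    def test_singleton_switch(self):
        s = summarize_counts(23, 11, 1, 8, singletons_as_concordant=False)
        assert s.n_concordant_after_review == 31

    def test_over_reclassification_rejected(self):
        with pytest.raises(ValueError):
            summarize_counts(1, 2, 0, 3)

    def test_class_summary_matches_counts(self, graded_library):
        lib, _ = graded_library
        from barcaudit.distances import distance_matrix
        from barcaudit.motu import cluster

        classes = review(classify_motus(cluster(distance_matrix(lib)), lib), SynonymTable())
        s = summarize_classes(classes)
        assert s.n_motus == len(classes)
        assert s.n_concordant + s.n_discordant + s.n_singleton == s.n_motus


class TestMatchReference:
    def test_self_sequence_scores_100(self, base_seq):
        ref = _library(
            make_record("r1", base_seq, "Aa aa", source="external"),
            make_record("r2", mutate(base_seq, range(0, 30)), "Bb bb", source="external"),
        )
        hits = match_reference(base_seq, "q", ref)
        assert hits[0].hit_id == "r1"
        assert hits[0].identity == pytest.approx(100.0)

    def test_identity_over_usable_overlap(self, base_seq):
        # 8 N's in the query leave 650 usable sites; 3 differences among them
        query = "N" * 8 + base_seq[8:]
        query = mutate(query, [100, 200, 300])
        ref = _library(make_record("r1", base_seq, "Gibbula pennanti", source="external"))
        (hit,) = match_reference(query, "q", ref)
        assert hit.overlap == 650
        assert hit.identity == pytest.approx(100 * (1 - 3 / 650))

    def test_min_overlap_drops_short_hits(self, base_seq):
        short = base_seq[:300] + "-" * 358
        ref = _library(make_record("r1", short, "Aa aa", source="external"))
        assert match_reference(base_seq, "q", ref, min_overlap=400) == []

    def test_ties_sorted_by_hit_id(self, base_seq):
        ref = _library(
            make_record("zz", base_seq, "Aa aa", source="external"),
            make_record("aa", base_seq, "Aa aa", source="external"),
        )
        hits = match_reference(base_seq, "q", ref)
        assert [h.hit_id for h in hits] == ["aa", "zz"]


class TestPropagate:
    def _setup(self, motu_members, query_genus="Nassarius"):
        recs = [make_record("q1", SEQ, "", qualifier="sp", genus=query_genus)]
        mapping = {"q1": 1}
        for i, name in enumerate(motu_members):
            recs.append(make_record(f"m{i}", SEQ, name))
            mapping[f"m{i}"] = 1
        lib = _library(*recs)
        a = _assignment(mapping)
        classes = review(classify_motus(a, lib), SynonymTable())
        return lib.by_id("q1"), a, classes, lib

    def test_pure_motu_proposes_name(self):
        q, a, classes, lib = self._setup(["Nassarius incrassatus"] * 3)
        assert propagate_id(q, a, classes, lib) == "Nassarius incrassatus"

    def test_discordant_motu_blocks(self):
        q, a, classes, lib = self._setup(["Nassarius incrassatus", "Nassarius reticulatus"])
        assert propagate_id(q, a, classes, lib) is None

    def test_singleton_blocks(self):
        lib = _library(make_record("q1", SEQ, "", qualifier="sp", genus="Gibbula"))
        a = _assignment({"q1": 1})
        classes = review(classify_motus(a, lib), SynonymTable())
        assert propagate_id(lib.by_id("q1"), a, classes, lib) is None

    def test_genus_conflict_blocks(self):
        q, a, classes, lib = self._setup(["Gibbula pennanti"] * 2, query_genus="Nassarius")
        assert propagate_id(q, a, classes, lib) is None

    def test_proposed_name_matches_stated_genus(self):
        q, a, classes, lib = self._setup(["Gibbula pennanti"] * 2, query_genus="Gibbula")
        assert propagate_id(q, a, classes, lib) == "Gibbula pennanti"
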