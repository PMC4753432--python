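"""K2P distances, exclusions, rank summaries and nearest neighbours."""

import math

import numpy as np
import pytest

from barcaudit.distances import (
    distance_matrix,
    exclusion_filter,
    k2p,
    k2p_with_sites,
    nearest_neighbor,
    summarize,
)
from barcaudit.io import BarcodeLibrary
from conftest import make_record

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_oracle(a, b):
    """Independent closed-form evaluation, plain Python."""
    pairs = [(x, y) for x, y in zip(a.upper(), b.upper()) if x in "ACGT" and y in "ACGT"]
    if not pairs:
        return math.nan
    n = len(pairs)
    P = sum((x, y) in TRANSITIONS for x, y in pairs) / n
    Q = sum(x != y and (x, y) not in TRANSITIONS for x, y in pairs) / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return math.nan
    arg = (1 - 2 * P - Q) * math.sqrt(1 - 2 * Q)
    return -0.5 * math.log(arg)


class TestK2P:
    def test_identical_sequences(self, base_seq):
        assert k2p(base_seq, base_seq) == 0.0

    def test_single_transition_closed_form(self):
        assert k2p("AAAA", "AAAG") == pytest.approx(-0.5 * math.log(0.5))

    def test_pairwise_deletion_of_ambiguity(self):
        d, sites = k2p_with_sites("AAAA", "AAAN")
        assert d == 0.0
        assert sites == 3

    def test_saturated_pair_is_undefined(self):
        assert math.isnan(k2p("AAAA", "GGGG"))

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            k2p("AAA", "AAAA")

    def test_matches_independent_k80_implementation(self):
        # frozen from ape::dist.dna(model="K80", pairwise.deletion=TRUE)
        a = "ACGTACGTACGTACGTACGTTTTTCCCCGGGGAAAATTTT"
        b = "ACGTACGTATGTACGAACGTTTTCCCCCGGGTAAAATTAT"
        assert k2p(a, b) == pytest.approx(0.136815678698, abs=1e-10)

    def test_reduces_to_p_distance_at_low_divergence(self):
        # with Q=0 and P -> 0, d ~ P to first order
        a = "A" * 1000
        b = "G" + "A" * 999  # P = 0.001
        assert k2p(a, b) == pytest.approx(0.001, abs=1e-5)

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(5)
        alphabet = np.array(list("ACGTN-"))
        for _ in range(200):
            L = int(rng.integers(30, 120))
            a = "".join(rng.choice(alphabet, p=[0.23, 0.23, 0.23, 0.23, 0.05, 0.03], size=L))
            b = "".join(rng.choice(alphabet, p=[0.23, 0.23, 0.23, 0.23, 0.05, 0.03], size=L))
            got, want = k2p(a, b), k2p_oracle(a, b)
            assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)


def _random_library(n, L, seed):
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGTN"))
    recs = [
        make_record(
            f"R{i}",
            "".join(rng.choice(alphabet, p=[0.24, 0.24, 0.24, 0.24, 0.04], size=L)),
            f"Gen sp{i % 5}",
        )
        for i in range(n)
    ]
    return BarcodeLibrary(recs)


class TestMatrix:
    def test_identical_sequences_all_zero(self, base_seq):
        lib = BarcodeLibrary([make_record(f"S{i}", base_seq, "Sp a") for i in range(3)])
        m = distance_matrix(lib)
        assert np.allclose(m.d, 0.0)

    def test_matrix_equals_per_pair_oracle(self):
        lib = _random_library(20, 80, seed=9)
        with pytest.warns(UserWarning):
            m = distance_matrix(lib)
        rows = {r.specimen_id: r.sequence for r in lib}
        for i, a in enumerate(m.ids):
            for j, b in enumerate(m.ids):
                if i >= j:
                    continue
                want = k2p_oracle(rows[a], rows[b])
                got = m.d[i, j]
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)
        assert np.allclose(m.d, m.d.T, equal_nan=True)

    def test_invariant_to_record_order(self, graded_library):
        lib, _ = graded_library
        m1 = distance_matrix(lib)
        reversed_lib = BarcodeLibrary(list(lib.records[::-1]))
        m2 = distance_matrix(reversed_lib)
        for a in lib.ids:
            for b in lib.ids:
                if a != b:
                    assert m1.get(a, b) == pytest.approx(m2.get(a, b))


class TestExclusions:
    def test_open_nomenclature_and_invalid_names_removed(self, base_seq):
        lib = BarcodeLibrary(
            [
                make_record("q1", base_seq, "", qualifier="sp", genus="Gibbula"),
                make_record("q2", base_seq, "Ocinebrina edwardsii", qualifier="cf"),
                make_record("q3", base_seq, "Osilinus lineatus"),
                make_record("q4", base_seq, "Phorcus lineatus"),
            ]
        )
        kept = exclusion_filter(lib, invalid_names=["Osilinus lineatus"])
        assert kept.ids == ["q4"]


def _three_species_library(base_seq):
    # hand-buildable distances: within species ~2 sites, across ~30/60 sites
    from conftest import mutate

    s1 = base_seq
    s2 = mutate(base_seq, range(100, 130))
    s3 = mutate(base_seq, range(200, 260))
    recs = [
        make_record("a1", s1, "Aa aa", family="F1"),
        make_record("a2", mutate(s1, [400]), "Aa aa", family="F1"),
        make_record("b1", s2, "Aa bb", family="F1"),
        make_record("b2", mutate(s2, [403]), "Aa bb", family="F1"),
        make_record("c1", s3, "Cc cc", genus="Cc", family="F1"),
    ]
    return BarcodeLibrary(recs)


class TestSummaries:
    def test_single_identical_pair(self, base_seq):
        lib = BarcodeLibrary([make_record(f"s{i}", base_seq, "Aa aa") for i in range(2)])
        s = summarize(distance_matrix(lib), lib, "species")
        assert s.n_comparisons == 1
        assert (s.min, s.mean, s.max) == (0.0, 0.0, 0.0)

    def test_hand_enumerated_aggregation(self, base_seq):
        lib = _three_species_library(base_seq)
        m = distance_matrix(lib)
        rows = {r.specimen_id: r.sequence for r in lib}

        # species rank: within-species pairs (a1,a2), (b1,b2)
        s = summarize(m, lib, "species")
        want = [k2p_oracle(rows["a1"], rows["a2"]), k2p_oracle(rows["b1"], rows["b2"])]
        assert s.n_comparisons == 2
        assert s.n_groups == 2
        assert s.mean == pytest.approx(100 * np.mean(want))
        assert s.min == pytest.approx(100 * min(want))
        assert s.max == pytest.approx(100 * max(want))

        # genus rank: cross-species pairs within genus Aa (2x2 = 4 pairs)
        g = summarize(m, lib, "genus")
        cross = [
            k2p_oracle(rows[x], rows[y])
            for x in ("a1", "a2")
            for y in ("b1", "b2")
        ]
        assert g.n_comparisons == 4
        assert g.mean == pytest.approx(100 * np.mean(cross))

        # family rank: between genera Aa and Cc (4 pairs)
        f = summarize(m, lib, "family")
        fam = [k2p_oracle(rows[x], rows["c1"]) for x in ("a1", "a2", "b1", "b2")]
        assert f.n_comparisons == 4
        assert f.mean == pytest.approx(100 * np.mean(fam))

    def test_mean_agrees_with_matrix_mask_route(self, graded_library):
        lib, _ = graded_library
        m = distance_matrix(lib)
        s = summarize(m, lib, "species")
        # independent route: boolean mask over the matrix
        labels = [lib.by_id(i).morpho_species for i in m.ids]
        vals = []
        for i in range(len(m.ids)):
            for j in range(i + 1, len(m.ids)):
                if labels[i] == labels[j] and labels[i]:
                    vals.append(m.d[i, j] * 100)
        assert s.mean == pytest.approx(float(np.mean(vals)))
        assert s.n_comparisons == len(vals)

    def test_rank_with_no_pairs(self, base_seq):
        lib = BarcodeLibrary([make_record("x", base_seq, "Aa aa")])
        s = summarize(distance_matrix(lib), lib, "species")
        assert s.n_comparisons == 0
        assert math.isnan(s.mean)


class TestNearestNeighbor:
    def test_two_species_symmetric(self, base_seq):
        from conftest import mutate

        other = mutate(base_seq, range(100, 160))
        lib = BarcodeLibrary(
            [
                make_record("a1", base_seq, "Aa aa"),
                make_record("a2", base_seq, "Aa aa"),
                make_record("b1", other, "Bb bb"),
                make_record("b2", other, "Bb bb"),
            ]
        )
        m = distance_matrix(lib)
        nn = nearest_neighbor(m, {r.specimen_id: r.morpho_species for r in lib})
        assert nn["Aa aa"].nn_species == ["Bb bb"]
        assert nn["Bb bb"].nn_species == ["Aa aa"]
        assert nn["Aa aa"].distance == pytest.approx(nn["Bb bb"].distance)

    def test_matches_exhaustive_search(self, graded_library):
        lib, _ = graded_library
        m = distance_matrix(lib)
        labels = {r.specimen_id: r.morpho_species for r in lib}
        nn = nearest_neighbor(m, labels)
        for sp, res in nn.items():
            best = math.inf
            for i, a in enumerate(m.ids):
                for j, b in enumerate(m.ids):
                    if labels[a] == sp and labels[b] not in ("", sp):
                        best = min(best, m.d[i, j])
            assert res.distance == pytest.approx(best)

    def test_single_species_raises(self, base_seq):
        lib = BarcodeLibrary([make_record(f"s{i}", base_seq, "Aa aa") for i in range(3)])
        m = distance_matrix(lib)
        with pytest.raises(ValueError):
            nearest_neighbor(m, {i: "Aa aa" for i in m.ids})
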