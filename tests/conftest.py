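"""Shared fixtures: deterministic sequences and an engineered library in
which every reliability grade fires exactly once."""

from __future__ import annotations

import numpy as np
import pytest

from barcaudit.io import BarcodeLibrary, SpecimenRecord
from barcaudit.qc import translate_codon

BASES = "ACGT"


def random_coding_sequence(length: int = 658, seed: int = 7) -> str:
    """Random DNA with no in-frame (frame 1) stop codons, independent of the
    package's simulator."""
    rng = np.random.default_rng(seed)
    seq = list("".join(BASES[i] for i in rng.integers(0, 4, size=length)))
    for start in range(0, 3 * (length // 3), 3):
        while translate_codon("".join(seq[start : start + 3])) == "*":
            for k in range(3):
                seq[start + k] = BASES[rng.integers(0, 4)]
    return "".join(seq)


def mutate(seq: str, positions) -> str:
    """Substitute each 0-based position by the next base in the ACGT cycle,
    avoiding the creation of frame-1 stop codons."""
    s = list(seq)
    for pos in positions:
        codon_start = 3 * (pos // 3)
        for _ in range(3):
            s[pos] = BASES[(BASES.index(s[pos]) + 1) % 4]
            if translate_codon("".join(s[codon_start : codon_start + 3])) != "*":
                break
    out = "".join(s)
    assert out != seq
    return out


@pytest.fixture(scope="session")
def base_seq() -> str:
    return random_coding_sequence(658, seed=7)


def _cluster_positions(i: int) -> range:
    # disjoint 40-site blocks per cluster: cross-cluster divergence >= ~12%
    return range(60 + 40 * i, 60 + 40 * i + 40)


@pytest.fixture(scope="session")
def graded_library(base_seq) -> tuple[BarcodeLibrary, dict]:
    """Library engineered so the A-E decision rules each fire exactly once.

    Six sequence clusters separated far beyond the 2.2% threshold; within a
    cluster records differ at <=2 private sites (~0.3%).
    """
    specs = [
        # id, species, source, published, cluster, private_site_index
        ("A1", "Alpha alpha", "own", False, 0, 0),
        ("A2", "Alpha alpha", "own", False, 0, 1),
        ("AX", "Alpha alpha", "external", True, 0, 2),
        ("B1", "Beta beta", "own", False, 1, 3),
        ("B2", "Beta beta", "own", False, 1, 4),
        ("B3", "Beta beta", "own", False, 1, 5),
        ("C1", "Gamma gamma", "own", False, 2, 6),
        ("C2", "Gamma gamma", "own", False, 2, 7),
        ("C3", "Gamma gamma", "own", False, 3, 8),
        ("D1", "Delta delta", "own", False, 4, 9),
        ("E1", "Epsilon epsilon", "own", False, 5, 10),
        ("E2", "Epsilon epsilon", "own", False, 5, 11),
        ("X1", "Zeta zeta", "external", True, 5, 12),
    ]
    records = []
    for sid, species, source, published, cluster_i, private in specs:
        seq = mutate(base_seq, _cluster_positions(cluster_i))
        seq = mutate(seq, [400 + 3 * private])
        genus = species.split()[0]
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                sequence=seq,
                morpho_species=species,
                genus=genus,
                family="Testidae",
                qualifier="none",
                locality="here",
                source=source,
                published=published,
            )
        )
    expected = {
        "Alpha alpha": "A",
        "Beta beta": "B",
        "Gamma gamma": "C",
        "Delta delta": "D",
        "Epsilon epsilon": "E",
    }
    return BarcodeLibrary(records), expected


def make_record(sid: str, seq: str, species: str = "", **kwargs) -> SpecimenRecord:
    genus = kwargs.pop("genus", species.split()[0] if species else "")
    return SpecimenRecord(
        specimen_id=sid,
        sequence=seq,
        morpho_species=species,
        genus=genus,
        family=kwargs.pop("family", "Famidae"),
        **kwargs,
    )
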