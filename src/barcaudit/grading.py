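"""Species-level reliability grading of barcode records (grades A-E).

Each morpho-species with own-project records receives a single grade:

* **A** — external concordance: own records share a MOTU with same-named
  records from other projects/published sequences, and every same-named
  record lands in that one MOTU.
* **B** — internal concordance: a single MOTU, at least 3 own specimens,
  and no external records of the species to compare against.
* **C** — sub-optimal concordance: at least 3 own specimens split over more
  than one MOTU (possible genetic structure within the species).
* **D** — insufficient data: 1-2 specimens and no matching external record.
* **E** — discordant: own records co-cluster with differently named
  records, or fail to co-cluster with the same-named external records.

The rules are evaluated in the fixed precedence E > C > A > B > D, which
resolves combinations the grade definitions alone leave open: discordance is
always fatal, and a species split over several MOTUs reads as possible
genetic structure (C) even when some external records match. External
concordance outranks sample size, so a 1-2 specimen species whose records
co-cluster with same-named external records still earns an A.
"""

from __future__ import annotations

from dataclasses import dataclass

from .concordance import MOTUClass
from .io import BarcodeLibrary
from .motu import MOTUAssignment

GRADES = ("A", "B", "C", "D", "E")


@dataclass
class Grade:
    """Grade of one morpho-species with a machine-readable rationale."""

    species_name: str
    grade: str
    n_specimens_own: int
    n_motus_occupied: int
    has_external_match: bool
    rationale: str


@dataclass
class GradeTable:
    grades: list[Grade]
    counts: dict
    pct_ab: float                 # percent of graded species scoring A or B

    @property
    def pct_ab_display(self) -> float:
        return round(self.pct_ab, 1)

    def rows(self) -> list[dict]:
        return [
            {
                "species": g.species_name,
                "grade": g.grade,
                "n_specimens": g.n_specimens_own,
                "n_motus": g.n_motus_occupied,
                "external_match": g.has_external_match,
                "rationale": g.rationale,
            }
            for g in self.grades
        ]


def _accepted_name(record, synonyms=None) -> str:
    if synonyms is not None:
        return synonyms.resolve(record.morpho_species)
    return record.morpho_species


def grade_species(
    species: str,
    library: BarcodeLibrary,
    assignment: MOTUAssignment,
    classes: list[MOTUClass],
    synonyms=None,
) -> Grade:
    """Grade one morpho-species by the A-E decision rules.

    ``classes`` must be the reviewed MOTU classification; ``synonyms``
    resolves names so nomenclatural conflicts do not masquerade as
    discordance. Raises for a species with no own records.
    """
    resolve = synonyms.resolve if synonyms else (lambda n: n)
    accepted = resolve(species)

    own = [
        r
        for r in library
        if r.source == "own" and r.qualifier == "none" and resolve(r.morpho_species) == accepted
    ]
    if not own:
        raise ValueError(f"species {species!r} has no own records to grade")
    ext_same = [
        r
        for r in library
        if r.source == "external"
        and r.qualifier == "none"
        and resolve(r.morpho_species) == accepted
    ]

    own_motus = sorted({assignment.mapping[r.specimen_id] for r in own})
    ext_motus = sorted({assignment.mapping[r.specimen_id] for r in ext_same})
    n_own = len(own)

    # E(1): an own record shares a MOTU with a differently named record.
    conflicting = set()
    own_ids = {r.specimen_id for r in own}
    for m in own_motus:
        cls = next(c for c in classes if c.motu_id == m)
        for sid in cls.member_ids:
            if sid in own_ids:
                continue
            other = library.by_id(sid)
            if other.qualifier != "none" or not other.morpho_species:
                continue
            other_name = resolve(other.morpho_species)
            if other_name != accepted:
                conflicting.add(other_name)
    if conflicting:
        return Grade(
            species_name=species,
            grade="E",
            n_specimens_own=n_own,
            n_motus_occupied=len(own_motus),
            has_external_match=bool(set(ext_motus) & set(own_motus)),
            rationale="co-clusters with differently named records: "
            + ", ".join(sorted(conflicting)),
        )
    # E(2): same-named external records exist but none co-cluster with ours.
    if ext_same and not set(ext_motus) & set(own_motus):
        return Grade(
            species_name=species,
            grade="E",
            n_specimens_own=n_own,
            n_motus_occupied=len(own_motus),
            has_external_match=False,
            rationale="own records do not co-cluster with same-named external records",
        )
    # C: possible genetic structure.
    if n_own >= 3 and len(own_motus) > 1:
        return Grade(
            species_name=species,
            grade="C",
            n_specimens_own=n_own,
            n_motus_occupied=len(own_motus),
            has_external_match=bool(set(ext_motus) & set(own_motus)),
            rationale=f"{n_own} specimens split over {len(own_motus)} MOTUs",
        )
    # A: external concordance, all same-named records in one shared MOTU.
    if (
        ext_same
        and set(ext_motus) & set(own_motus)
        and len(set(own_motus) | set(ext_motus)) == 1
    ):
        return Grade(
            species_name=species,
            grade="A",
            n_specimens_own=n_own,
            n_motus_occupied=len(own_motus),
            has_external_match=True,
            rationale=f"unambiguous MOTU match with {len(ext_same)} external record(s)",
        )
    # B: internal concordance only.
    if not ext_same and len(own_motus) == 1 and n_own >= 3:
        return Grade(
            species_name=species,
            grade="B",
            n_specimens_own=n_own,
            n_motus_occupied=1,
            has_external_match=False,
            rationale=f"single MOTU, {n_own} own specimens, no external records",
        )
    # D: insufficient data (and any residual ambiguous combination).
    return Grade(
        species_name=species,
        grade="D",
        n_specimens_own=n_own,
        n_motus_occupied=len(own_motus),
        has_external_match=bool(set(ext_motus) & set(own_motus)),
        rationale=f"insufficient data ({n_own} specimen(s), no unambiguous external match)",
    )


def grade_table(
    library: BarcodeLibrary,
    assignment: MOTUAssignment,
    classes: list[MOTUClass],
    synonyms=None,
) -> GradeTable:
    """Grade every morpho-species with own records; summarize counts.

    The headline statistic is the percentage of graded species scoring A or
    B, carried at full precision (display rounding is separate).
    """
    resolve = synonyms.resolve if synonyms else (lambda n: n)
    species = sorted(
        {
            resolve(r.morpho_species)
            for r in library
            if r.source == "own" and r.qualifier == "none" and r.morpho_species
        }
    )
    grades = [
        grade_species(sp, library, assignment, classes, synonyms=synonyms)
        for sp in species
    ]
    counts = {g: 0 for g in GRADES}
    for g in grades:
        counts[g.grade] += 1
    n = len(grades)
    pct_ab = 100.0 * (counts["A"] + counts["B"]) / n if n else float("nan")
    return GradeTable(grades=grades, counts=counts, pct_ab=pct_ab)


def ab_percentage(counts: dict) -> float:
    """A+B percentage over graded species from a counts mapping."""
    total = sum(counts.get(g, 0) for g in GRADES)
    if total == 0:
        return float("nan")
    return 100.0 * (counts.get("A", 0) + counts.get("B", 0)) / total
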