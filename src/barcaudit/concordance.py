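"""Concordance review of MOTUs against morphology-based identifications.

Mirrors the semantics of a barcode-database "BIN report": each MOTU is
classed as *concordant* (all species-level identifications agree),
*discordant* (more than one species name among its members) or *singleton*
(exactly one member). Discordant MOTUs are then re-examined with a synonym
table — many apparent conflicts are nomenclatural, not biological — and
either reclassified concordant or confirmed discordant.

Open-nomenclature specimens (qualifier sp/cf/aff) never make a MOTU
discordant by themselves: such specimens are candidates for barcode-based
identification (``propagate_id``) rather than evidence of conflict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .distances import p_distance_with_sites
from .io import BarcodeLibrary, SynonymTable
from .motu import MOTUAssignment


@dataclass
class MOTUClass:
    """Classification of one MOTU before and after expert review."""

    motu_id: int
    status: str                     # "concordant" | "discordant" | "singleton"
    discordance_rank: str           # "none" | "species" | "genus"
    member_ids: list[str]
    member_species: list[str]       # species-level names, one per counted member
    review_status: str = "as_reported"
    review_reason: str = ""

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def concordant_after_review(self, singletons_as_concordant: bool = True) -> bool:
        if self.status == "singleton":
            return singletons_as_concordant
        if self.status == "concordant":
            return True
        return self.review_status == "reclassified_concordant"


def _counted_names(records) -> list[tuple[str, str]]:
    """(species, genus) pairs for members that count toward discordance."""
    out = []
    for r in records:
        if r.qualifier == "none" and r.morpho_species:
            genus = r.genus or r.morpho_species.split()[0]
            out.append((r.morpho_species, genus))
    return out


def classify_motus(assignment: MOTUAssignment, library: BarcodeLibrary) -> list[MOTUClass]:
    """Classify every MOTU as concordant, discordant or singleton."""
    classes = []
    for motu_id, member_ids in sorted(assignment.motus().items()):
        records = [library.by_id(sid) for sid in member_ids]
        counted = _counted_names(records)
        names = sorted({sp for sp, _ in counted})
        genera = sorted({g for _, g in counted})
        if len(member_ids) == 1:
            status, rank = "singleton", "none"
        elif len(names) > 1:
            status = "discordant"
            rank = "genus" if len(genera) > 1 else "species"
        else:
            status, rank = "concordant", "none"
        classes.append(
            MOTUClass(
                motu_id=motu_id,
                status=status,
                discordance_rank=rank,
                member_ids=list(member_ids),
                member_species=[sp for sp, _ in counted],
            )
        )
    return classes


def review(classes: list[MOTUClass], synonyms: SynonymTable) -> list[MOTUClass]:
    """Re-evaluate discordant MOTUs after synonym resolution.

    A discordant MOTU whose member names collapse to a single accepted name
    becomes ``reclassified_concordant``, recording the triggering synonyms;
    the rest are ``confirmed_discordant``. Concordant and singleton MOTUs
    pass through untouched.
    """
    out = []
    for c in classes:
        new = MOTUClass(
            motu_id=c.motu_id,
            status=c.status,
            discordance_rank=c.discordance_rank,
            member_ids=list(c.member_ids),
            member_species=list(c.member_species),
            review_status=c.review_status,
            review_reason=c.review_reason,
        )
        if c.status == "discordant":
            accepted = {}
            for name in c.member_species:
                accepted[name] = synonyms.resolve(name)
            if len(set(accepted.values())) <= 1:
                applied = sorted(
                    f"{old} = {new_name}" + (f" ({synonyms.note(old)})" if synonyms.note(old) else "")
                    for old, new_name in accepted.items()
                    if old != new_name
                )
                new.review_status = "reclassified_concordant"
                new.review_reason = "; ".join(applied) or "names agree after review"
            else:
                new.review_status = "confirmed_discordant"
                new.review_reason = (
                    "distinct accepted names remain: "
                    + ", ".join(sorted(set(accepted.values())))
                )
        out.append(new)
    return out


@dataclass
class ConcordanceSummary:
    """Counts over a MOTU report, before and after review."""

    n_motus: int
    n_concordant: int
    n_discordant: int
    n_singleton: int
    n_reclassified: int
    n_concordant_after_review: int
    pct_concordant: float           # full precision, percent
    singletons_as_concordant: bool

    @property
    def pct_concordant_display(self) -> float:
        return round(self.pct_concordant, 1)


def summarize_counts(
    n_concordant: int,
    n_discordant: int,
    n_singleton: int,
    n_reclassified: int,
    singletons_as_concordant: bool = True,
) -> ConcordanceSummary:
    """Concordance arithmetic from report counts.

    Total MOTUs = concordant + discordant + singleton; after review the
    concordant tally gains the reclassified MOTUs, plus the singletons when
    ``singletons_as_concordant`` (a one-member MOTU cannot conflict with
    morphology, so reports typically count it as concordant).
    """
    if n_reclassified > n_discordant:
        raise ValueError("cannot reclassify more MOTUs than were discordant")
    total = n_concordant + n_discordant + n_singleton
    after = n_concordant + n_reclassified + (n_singleton if singletons_as_concordant else 0)
    pct = 100.0 * after / total if total else math.nan
    return ConcordanceSummary(
        n_motus=total,
        n_concordant=n_concordant,
        n_discordant=n_discordant,
        n_singleton=n_singleton,
        n_reclassified=n_reclassified,
        n_concordant_after_review=after,
        pct_concordant=pct,
        singletons_as_concordant=singletons_as_concordant,
    )


def summarize_classes(
    classes: list[MOTUClass], singletons_as_concordant: bool = True
) -> ConcordanceSummary:
    """Concordance summary computed from classified (and reviewed) MOTUs."""
    return summarize_counts(
        n_concordant=sum(c.status == "concordant" for c in classes),
        n_discordant=sum(c.status == "discordant" for c in classes),
        n_singleton=sum(c.status == "singleton" for c in classes),
        n_reclassified=sum(
            c.review_status == "reclassified_concordant" for c in classes
        ),
        singletons_as_concordant=singletons_as_concordant,
    )


@dataclass
class ReferenceMatch:
    """One hit of a local reference-similarity search."""

    query_id: str
    hit_id: str
    hit_species: str
    identity: float                 # percent over the aligned overlap
    overlap: int                    # usable overlapping sites
    same_motu: bool | None = None


def match_reference(
    query_row: str,
    query_id: str,
    reference_library: BarcodeLibrary,
    min_overlap: int = 400,
    assignment: MOTUAssignment | None = None,
) -> list[ReferenceMatch]:
    """Rank reference records by percent identity to an anchored query.

    A local, reproducible stand-in for web similarity searches: identity is
    100*(1 - p-distance) over sites where both rows carry an unambiguous
    base; hits overlapping fewer than ``min_overlap`` sites are dropped.
    Sorted by identity (descending), ties broken by hit id.
    """
    if reference_library.alignment is None:
        rows = {r.specimen_id: r.sequence for r in reference_library}
        lengths = {len(s) for s in rows.values()} | {len(query_row)}
        if len(lengths) > 1:
            raise ValueError("reference library and query must share an anchor alignment")
    else:
        rows = reference_library.alignment

    q_motu = assignment.mapping.get(query_id) if assignment else None
    hits = []
    for rec in reference_library:
        if rec.specimen_id == query_id:
            continue
        p, n = p_distance_with_sites(query_row, rows[rec.specimen_id])
        if n < min_overlap or math.isnan(p):
            continue
        same = None
        if assignment is not None:
            same = assignment.mapping.get(rec.specimen_id) == q_motu
        hits.append(
            ReferenceMatch(
                query_id=query_id,
                hit_id=rec.specimen_id,
                hit_species=rec.morpho_species,
                identity=100.0 * (1.0 - p),
                overlap=n,
                same_motu=same,
            )
        )
    hits.sort(key=lambda h: (-h.identity, h.hit_id))
    return hits


def propagate_id(
    specimen,
    assignment: MOTUAssignment,
    classes: list[MOTUClass],
    library: BarcodeLibrary,
    synonyms: SynonymTable | None = None,
) -> str | None:
    """Propose a species name for an open-nomenclature specimen.

    A genus-level (sp) or tentative (cf/aff) specimen inherits the species
    name of its MOTU iff, after review, the MOTU's other members carry
    exactly one accepted name and that name's genus is consistent with the
    specimen's stated genus. Discordant or singleton MOTUs block propagation.
    """
    motu_id = assignment.mapping.get(specimen.specimen_id)
    if motu_id is None:
        return None
    cls = next((c for c in classes if c.motu_id == motu_id), None)
    if cls is None or cls.status == "singleton":
        return None
    if cls.status == "discordant" and cls.review_status != "reclassified_concordant":
        return None
    resolve = synonyms.resolve if synonyms else (lambda n: n)
    others = [
        library.by_id(sid)
        for sid in cls.member_ids
        if sid != specimen.specimen_id
    ]
    names = {
        resolve(r.morpho_species)
        for r in others
        if r.qualifier == "none" and r.morpho_species
    }
    if len(names) != 1:
        return None
    name = names.pop()
    if specimen.genus and name.split()[0] != resolve(specimen.genus):
        return None
    return name


def report_rows(classes: list[MOTUClass]) -> list[dict]:
    return [
        {
            "motu_id": c.motu_id,
            "status": c.status,
            "discordance_rank": c.discordance_rank,
            "n_members": c.n_members,
            "member_species": ";".join(sorted(set(c.member_species))),
            "review_status": c.review_status,
            "review_reason": c.review_reason,
        }
        for c in classes
    ]
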