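"""Reading, writing and validation of barcode reference libraries.

A *library* couples a FASTA file of COI-5P sequences with a tab-separated
specimen metadata table. Records are kept in file order; the pair of files is
the on-disk interchange format throughout the package. Metadata follows a
fixed required header (extra columns are passed through untouched, mirroring
the loose TSV dialect of common barcode-database exports).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN-")
QUALIFIERS = ("none", "sp", "cf", "aff")

REQUIRED_COLUMNS = [
    "specimen_id",
    "morpho_species",
    "genus",
    "family",
    "qualifier",
    "locality",
    "source",
    "published",
]

_GENUS_SP_RE = re.compile(r"^([A-Za-z]+)\s+sp\.?$")


class LibraryError(ValueError):
    """Raised for malformed or inconsistent library inputs."""


@dataclass
class SpecimenRecord:
    """One sequence plus its taxonomy and provenance; the atom of a library.

    ``qualifier`` captures open-nomenclature identifications: ``sp`` for
    genus-only identifications (e.g. *Gibbula* sp.), ``cf``/``aff`` for
    tentative species assignments. ``source`` distinguishes records produced
    by the library's own project (``own``) from records mined from public
    repositories (``external``).
    """

    specimen_id: str
    sequence: str
    morpho_species: str = ""
    genus: str = ""
    family: str = ""
    qualifier: str = "none"
    locality: str = ""
    source: str = "own"
    published: bool = False
    extra: dict = field(default_factory=dict)

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass
class BarcodeLibrary:
    """Ordered collection of specimen records with an optional alignment.

    ``alignment`` maps specimen_id to an aligned row (all rows equal length).
    ``anchor`` optionally holds the gap-free 658-site Folmer-region reference
    that defines barcode coordinates 1..658.
    """

    records: list[SpecimenRecord]
    alignment: dict[str, str] | None = None
    anchor: str | None = None

    def __post_init__(self):
        ids = [r.specimen_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LibraryError(f"duplicate specimen ids: {', '.join(dupes)}")
        if self.alignment is not None:
            missing = [i for i in ids if i not in self.alignment]
            if missing:
                raise LibraryError(f"alignment missing rows for: {missing}")
            lengths = {len(v) for v in self.alignment.values()}
            if len(lengths) > 1:
                raise LibraryError("alignment rows have unequal lengths")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def by_id(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def subset(self, ids) -> "BarcodeLibrary":
        keep = set(ids)
        recs = [r for r in self.records if r.specimen_id in keep]
        aln = None
        if self.alignment is not None:
            aln = {r.specimen_id: self.alignment[r.specimen_id] for r in recs}
        return BarcodeLibrary(recs, alignment=aln, anchor=self.anchor)

    def species_of(self, specimen_id: str) -> str:
        return self.by_id(specimen_id).morpho_species


@dataclass
class SynonymTable:
    """Mapping from a taxon name to its currently accepted name.

    Chains are collapsed at construction so one application reaches the
    accepted name (idempotency); cycles are rejected. Each entry carries a
    free-text authority note (e.g. the database consulted).
    """

    mapping: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        resolved = {}
        for name in self.mapping:
            seen = [name]
            cur = name
            while cur in self.mapping and self.mapping[cur] != cur:
                cur = self.mapping[cur]
                if cur in seen:
                    raise LibraryError(
                        f"cyclic synonym mapping: {' -> '.join(seen + [cur])}"
                    )
                seen.append(cur)
            resolved[name] = cur
        self.mapping = resolved

    def resolve(self, name: str) -> str:
        return self.mapping.get(name, name)

    def note(self, name: str) -> str:
        return self.notes.get(name, "")

    def __len__(self) -> int:
        return len(self.mapping)


def _normalize_qualifier(raw: str) -> str:
    q = raw.strip().rstrip(".").lower()
    if q in ("", "none"):
        return "none"
    if q not in QUALIFIERS:
        raise LibraryError(f"unknown identification qualifier: {raw!r}")
    return q


def _parse_bool(raw: str) -> bool:
    v = str(raw).strip().lower()
    if v in ("true", "1", "yes", "t", "y"):
        return True
    if v in ("false", "0", "no", "f", "n", ""):
        return False
    raise LibraryError(f"cannot parse boolean flag: {raw!r}")


def validate_sequence(specimen_id: str, sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise LibraryError(f"{specimen_id}: empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_DNA:
            raise LibraryError(
                f"{specimen_id}: non-IUPAC character {ch!r} at position {pos}"
            )
    return seq


def _record_from_row(row: dict, sequence: str) -> SpecimenRecord:
    sid = row["specimen_id"]
    morpho = row.get("morpho_species", "").strip()
    genus = row.get("genus", "").strip()
    qualifier = _normalize_qualifier(row.get("qualifier", "none"))
    # "Gibbula sp." style names are genus-level identifications: recover the
    # genus and leave the species hypothesis empty.
    m = _GENUS_SP_RE.match(morpho)
    if m:
        qualifier = "sp" if qualifier == "none" else qualifier
        if not genus:
            genus = m.group(1)
        morpho = ""
    if qualifier == "sp" and morpho and " " in morpho:
        raise LibraryError(
            f"{sid}: qualifier 'sp' requires an empty or genus-only name, "
            f"got {row.get('morpho_species')!r}"
        )
    extra = {
        k: v
        for k, v in row.items()
        if k not in REQUIRED_COLUMNS and not k.startswith("_")
    }
    return SpecimenRecord(
        specimen_id=sid,
        sequence=validate_sequence(sid, sequence),
        morpho_species=morpho,
        genus=genus,
        family=row.get("family", "").strip(),
        qualifier=qualifier,
        locality=row.get("locality", "").strip(),
        source=row.get("source", "own").strip() or "own",
        published=_parse_bool(row.get("published", "false")),
        extra=extra,
    )


def read_library(fasta_path, metadata_path) -> BarcodeLibrary:
    """Read and cross-validate a FASTA + metadata TSV pair.

    Record order follows the FASTA file. Every FASTA id must have exactly one
    metadata row and vice versa; offenders are listed in the error.
    """
    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise LibraryError(f"duplicate specimen id in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq)
        order.append(rec.id)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise LibraryError(f"metadata missing required columns: {missing_cols}")
    if meta["specimen_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["specimen_id"].duplicated(), "specimen_id"])
        raise LibraryError(f"duplicate specimen ids in metadata: {dupes}")

    rows = {r["specimen_id"]: dict(r) for _, r in meta.iterrows()}
    only_fasta = sorted(set(order) - set(rows))
    only_meta = sorted(set(rows) - set(order))
    if only_fasta or only_meta:
        parts = []
        if only_fasta:
            parts.append(f"FASTA ids without metadata: {', '.join(only_fasta)}")
        if only_meta:
            parts.append(f"metadata rows without FASTA: {', '.join(only_meta)}")
        raise LibraryError("; ".join(parts))

    records = [_record_from_row(rows[sid], seqs[sid]) for sid in order]
    return BarcodeLibrary(records)


def write_library(library: BarcodeLibrary, fasta_path, metadata_path) -> None:
    """Write a library back to a FASTA + metadata TSV pair (round-trippable)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in library
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")

    extra_cols: list[str] = []
    for r in library:
        for k in r.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    rows = []
    for r in library:
        morpho = r.morpho_species
        if r.qualifier == "sp" and not morpho:
            morpho = f"{r.genus} sp." if r.genus else ""
        row = {
            "specimen_id": r.specimen_id,
            "morpho_species": morpho,
            "genus": r.genus,
            "family": r.family,
            "qualifier": r.qualifier,
            "locality": r.locality,
            "source": r.source,
            "published": "true" if r.published else "false",
        }
        for k in extra_cols:
            row[k] = r.extra.get(k, "")
        rows.append(row)
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS + extra_cols).to_csv(
        metadata_path, sep="\t", index=False
    )


def read_synonyms(path) -> SynonymTable:
    """Read a synonym TSV with columns ``name  accepted_name  note``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("name", "accepted_name"):
        if col not in df.columns:
            raise LibraryError(f"synonym table missing column {col!r}")
    mapping = dict(zip(df["name"], df["accepted_name"]))
    notes = dict(zip(df["name"], df.get("note", pd.Series("", index=df.index))))
    return SynonymTable(mapping=mapping, notes=notes)


def apply_synonyms(
    library: BarcodeLibrary, table: SynonymTable
) -> tuple[BarcodeLibrary, list[dict]]:
    """Replace every taxon name by its accepted name.

    Returns the renamed library plus an audit trail of replacements, one dict
    per changed field with the triggering synonym's authority note. Genus
    fields follow the accepted binomial's genus; genus-level synonyms (e.g.
    *Lunatia* -> *Euspira*) also rewrite the leading word of binomials.
    """
    audit: list[dict] = []
    new_records = []
    for r in library:
        new = replace(r, extra=dict(r.extra))
        name = new.morpho_species
        if name:
            accepted = table.resolve(name)
            if accepted == name and new.genus and new.genus in table.mapping:
                new_genus = table.resolve(new.genus)
                parts = name.split()
                if parts[0] == new.genus:
                    accepted = " ".join([new_genus] + parts[1:])
            if accepted != name:
                audit.append(
                    {
                        "specimen_id": r.specimen_id,
                        "field": "morpho_species",
                        "old": name,
                        "new": accepted,
                        "note": table.note(name) or table.note(new.genus),
                    }
                )
                new.morpho_species = accepted
                new.genus = accepted.split()[0]
        if new.genus in table.mapping:
            accepted_genus = table.resolve(new.genus)
            if accepted_genus != new.genus:
                audit.append(
                    {
                        "specimen_id": r.specimen_id,
                        "field": "genus",
                        "old": new.genus,
                        "new": accepted_genus,
                        "note": table.note(new.genus),
                    }
                )
                new.genus = accepted_genus
        new_records.append(new)
    out = BarcodeLibrary(
        new_records,
        alignment=dict(library.alignment) if library.alignment else None,
        anchor=library.anchor,
    )
    return out, audit
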