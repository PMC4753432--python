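"""End-to-end library audit: orchestration, artifacts and the audit report.

Stages run in a fixed order — QC, anchoring/alignment, distances, MOTU
delimitation, concordance classification and review, grading, and an
optional NJ tree — and every number in the report is traceable to the
module that produced it. Percentages are carried at full precision; display
rounding (round-half-even, one decimal) is applied only at formatting time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .concordance import (
    classify_motus,
    propagate_id,
    report_rows,
    review,
    summarize_classes,
)
from .distances import distance_matrix, exclusion_filter, nearest_neighbor, summarize
from .grading import grade_table
from .io import BarcodeLibrary, SynonymTable, apply_synonyms
from .motu import DEFAULT_THRESHOLD, cluster, splitter_report
from .qc import compliance_check, locate_library_indels
from .trees import bootstrap, nj, to_newick

log = logging.getLogger("barcaudit")


class AuditError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AuditConfig:
    threshold: float = DEFAULT_THRESHOLD
    min_len: int = 500
    max_ambig_frac: float = 0.01
    invalid_names: list = field(default_factory=list)
    singletons_as_concordant: bool = True
    build_tree: bool = False
    bootstrap_reps: int = 0
    seed: int = 0
    min_identity: float = 0.5


@dataclass
class AuditReport:
    n_records: int
    qc: list                               # QCResult per record
    n_qc_failed: int
    indels: list                           # IndelEvent list
    distance_summaries: dict               # rank -> DistanceSummary
    nearest_neighbors: dict
    n_motus: int
    assignment: object
    classes: list                          # reviewed MOTUClass list
    concordance: object                    # ConcordanceSummary
    splitters: list
    propagated_ids: dict                   # specimen_id -> proposed name
    grades: object                         # GradeTable
    synonym_audit: list
    tree_newick: str | None
    ari: float | None
    provenance: dict

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        summaries = {
            rank: {k: clean(v) for k, v in s.as_row().items()}
            for rank, s in self.distance_summaries.items()
        }
        conc = dataclasses.asdict(self.concordance)
        return {
            "n_records": self.n_records,
            "qc": {
                "n_failed": self.n_qc_failed,
                "failed_ids": [r.specimen_id for r in self.qc if not r.passed],
            },
            "indels": [
                {
                    "specimen_id": e.specimen_id,
                    "kind": e.kind,
                    "start": e.start,
                    "end": e.end,
                    "motif": e.inserted_motif,
                    "frame_preserving": e.frame_preserving,
                }
                for e in self.indels
            ],
            "distance_summaries": summaries,
            "motu": {"n_motus": self.n_motus, "threshold": self.assignment.threshold},
            "concordance": conc,
            "concordance_pct_display": self.concordance.pct_concordant_display,
            "splitters": [
                {
                    "species": s.species,
                    "n_motus": s.n_motus,
                    "max_intra_distance": clean(s.max_intra_distance),
                }
                for s in self.splitters
            ],
            "propagated_ids": self.propagated_ids,
            "grades": {
                "counts": self.grades.counts,
                "pct_ab": self.grades.pct_ab,
                "pct_ab_display": self.grades.pct_ab_display,
                "table": self.grades.rows(),
            },
            "ari": clean(self.ari) if self.ari is not None else None,
            "tree_newick": self.tree_newick,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AuditError:
                raise
            except Exception as exc:
                raise AuditError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("qc")
def _run_qc(library: BarcodeLibrary, config: AuditConfig):
    events_by_id: dict = {}
    aligned_rows: dict = {}
    if library.anchor:
        events_by_id, aligned_rows = locate_library_indels(
            library, min_identity=config.min_identity
        )
        dropped = set(library.ids) - set(aligned_rows)
        for sid in sorted(dropped):
            log.warning("%s: not homologous to anchor, dropped", sid)
    results = []
    indel_events = []
    for rec in library:
        events = events_by_id.get(rec.specimen_id) if library.anchor else None
        if events:
            indel_events.extend(events)
        results.append(
            compliance_check(
                rec,
                min_len=config.min_len,
                max_ambig_frac=config.max_ambig_frac,
                indel_events=events,
            )
        )
    return results, indel_events, aligned_rows


def run_audit(
    library: BarcodeLibrary,
    synonyms: SynonymTable | None = None,
    config: AuditConfig | None = None,
    truth=None,
    outdir=None,
) -> AuditReport:
    """Run the full audit over a validated library.

    If the library carries a Folmer anchor, every record is anchor-aligned
    (records failing the homology check are dropped with a warning) and
    indels are detected; otherwise sequences must already be of equal
    length. ``truth`` (from the simulator) adds an adjusted-Rand-index
    check of the MOTU assignment against true species. Artifacts are written
    under ``outdir`` when given.
    """
    config = config or AuditConfig()
    synonyms = synonyms or SynonymTable()
    log.info("audit: %d records, threshold %.3f", len(library), config.threshold)

    qc_results, indel_events, aligned_rows = _run_qc(library, config)
    passed_ids = [r.specimen_id for r in qc_results if r.passed]
    n_failed = len(library) - len(passed_ids)
    if n_failed:
        log.info("qc: %d record(s) failed compliance", n_failed)
    if not passed_ids:
        raise AuditError("stage 'qc' failed: no records passed compliance")

    working = library.subset(passed_ids)
    if library.anchor:
        working.alignment = {
            sid: aligned_rows[sid] for sid in passed_ids if sid in aligned_rows
        }
        working.records = [r for r in working.records if r.specimen_id in working.alignment]

    try:
        matrix = distance_matrix(working)
    except Exception as exc:
        raise AuditError(f"stage 'distances' failed: {exc}") from exc

    excluded = exclusion_filter(working, invalid_names=config.invalid_names)
    sub_matrix = matrix.subset(excluded.ids) if len(excluded) else matrix
    summaries = {}
    for rank in ("species", "genus", "family"):
        try:
            summaries[rank] = summarize(sub_matrix, excluded, rank)
        except Exception as exc:
            raise AuditError(f"stage 'distances' failed at rank {rank}: {exc}") from exc

    species_labels = {
        r.specimen_id: r.morpho_species for r in excluded if r.morpho_species
    }
    nn = {}
    if len(set(species_labels.values())) >= 2:
        nn = nearest_neighbor(sub_matrix, species_labels)

    try:
        assignment = cluster(matrix, threshold=config.threshold)
    except Exception as exc:
        raise AuditError(f"stage 'motu' failed: {exc}") from exc

    try:
        classes = review(classify_motus(assignment, working), synonyms)
        conc = summarize_classes(
            classes, singletons_as_concordant=config.singletons_as_concordant
        )
    except Exception as exc:
        raise AuditError(f"stage 'concordance' failed: {exc}") from exc

    all_species = {r.specimen_id: r.morpho_species for r in working if r.morpho_species}
    splitters = splitter_report(assignment, all_species, matrix)

    propagated = {}
    for rec in working:
        if rec.qualifier in ("sp", "cf", "aff"):
            name = propagate_id(rec, assignment, classes, working, synonyms=synonyms)
            if name:
                propagated[rec.specimen_id] = name

    try:
        renamed, synonym_audit = apply_synonyms(working, synonyms)
        grades = grade_table(renamed, assignment, classes, synonyms=synonyms)
    except Exception as exc:
        raise AuditError(f"stage 'grading' failed: {exc}") from exc

    tree_newick = None
    if config.build_tree and len(working) >= 3:
        try:
            if config.bootstrap_reps > 0 and working.alignment is not None:
                result = bootstrap(
                    working.alignment,
                    n_reps=config.bootstrap_reps,
                    seed=config.seed,
                )
                tree_newick = to_newick(result.tree)
            elif config.bootstrap_reps > 0:
                rows = {r.specimen_id: r.sequence for r in working}
                result = bootstrap(rows, n_reps=config.bootstrap_reps, seed=config.seed)
                tree_newick = to_newick(result.tree)
            else:
                tree_newick = to_newick(nj(matrix))
        except Exception as exc:
            raise AuditError(f"stage 'trees' failed: {exc}") from exc

    ari = None
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        ids = [sid for sid in assignment.mapping if sid in truth.entries]
        ari = float(
            adjusted_rand_score(
                [truth.entries[i].true_species for i in ids],
                [assignment.mapping[i] for i in ids],
            )
        )

    report = AuditReport(
        n_records=len(library),
        qc=qc_results,
        n_qc_failed=n_failed,
        indels=indel_events,
        distance_summaries=summaries,
        nearest_neighbors=nn,
        n_motus=assignment.n_motus,
        assignment=assignment,
        classes=classes,
        concordance=conc,
        splitters=splitters,
        propagated_ids=propagated,
        grades=grades,
        synonym_audit=synonym_audit,
        tree_newick=tree_newick,
        ari=ari,
        provenance={
            "package": "barcaudit",
            "version": __version__,
            "n_input_records": len(library),
            "threshold": config.threshold,
            "min_len": config.min_len,
            "max_ambig_frac": config.max_ambig_frac,
            "seed": config.seed,
            "singletons_as_concordant": config.singletons_as_concordant,
        },
    )
    if outdir is not None:
        write_artifacts(report, outdir)
    return report


def write_artifacts(report: AuditReport, outdir) -> None:
    """Write TSV/JSON/newick artifacts for every stage."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    from .qc import qc_report_rows

    pd.DataFrame(qc_report_rows(report.qc)).to_csv(
        out / "qc_report.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [s.as_row() for s in report.distance_summaries.values()]
    ).to_csv(out / "distance_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"specimen_id": sid, "motu_id": m}
            for sid, m in report.assignment.mapping.items()
        ]
    ).to_csv(out / "motu_assignment.tsv", sep="\t", index=False)
    pd.DataFrame(report_rows(report.classes)).to_csv(
        out / "motu_report.tsv", sep="\t", index=False
    )
    pd.DataFrame(report.grades.rows()).to_csv(
        out / "grade_table.tsv", sep="\t", index=False
    )
    (out / "audit_report.json").write_text(report.to_json())
    if report.tree_newick:
        (out / "phenogram.nwk").write_text(report.tree_newick + "\n")
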