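"""Sequence vetting for barcode libraries.

Three screens are applied to candidate barcodes before any distance-based
analysis:

* a translation screen under the invertebrate mitochondrial genetic code
  (NCBI table 5), flagging in-frame stop codons — the classic symptom of a
  nuclear mitochondrial pseudogene (NUMT) or sequencing artefact;
* barcode-compliance checks on ungapped length and ambiguity content,
  mirroring the minimum standards used by reference-library databases;
* indel detection against a gap-free 658-site reference for the barcode
  region amplified by the Folmer primers, distinguishing reading-frame
  preserving (3k bp) length variants — which occur naturally in some
  gastropod families — from frameshifts.

Coordinates are 1-based and inclusive in reference (Folmer) space. An
insertion between reference positions p and p+1 of length L is reported as
occupying p+1..p+L in the expanded coordinate frame, so a TTG insert right
after position 93 reads as "insertion at 94-96".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Data import CodonTable

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
_ACGT = set("ACGT")

QC_FLAGS = ("too_short", "excess_ambiguity", "stop_codon", "frameshift", "not_translatable")


def translate_codon(codon: str) -> str:
    """Translate one codon under table 5; ambiguity codes give 'X', stops '*'."""
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= _ACGT:
        return "X"
    if codon in _TABLE5.stop_codons:
        return "*"
    return _TABLE5.forward_table[codon]


@dataclass
class TranslationScreen:
    frame: int                      # 1, 2 or 3
    protein: str
    stop_positions: list[int]       # 1-based nucleotide position of each stop codon start

    @property
    def n_stops(self) -> int:
        return len(self.stop_positions)


@dataclass
class QCResult:
    specimen_id: str
    passed: bool
    flags: set = field(default_factory=set)
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        self.passed = not self.flags


@dataclass
class IndelEvent:
    """A maximal gap run relative to the Folmer reference.

    ``start``/``end`` are 1-based inclusive reference-space coordinates (for
    insertions, in the expanded frame; see module docstring).
    """

    specimen_id: str
    kind: str                # "insertion" | "deletion"
    start: int
    end: int
    inserted_motif: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def frame_preserving(self) -> bool:
        return self.length % 3 == 0


def _screen_frame(seq: str, frame: int) -> TranslationScreen:
    protein = []
    stops = []
    for i in range(frame - 1, len(seq) - 2, 3):
        aa = translate_codon(seq[i : i + 3])
        protein.append(aa)
        if aa == "*":
            stops.append(i + 1)
    return TranslationScreen(frame=frame, protein="".join(protein), stop_positions=stops)


def translate_screen(sequence: str, frame: int | None = None) -> TranslationScreen:
    """Translate a sequence and report every in-frame stop codon.

    Gaps are removed first. With ``frame=None`` the reading frame with the
    fewest stops is selected (ties broken by the lowest frame number) —
    appropriate for barcodes whose amplicon frame is unknown. Codons
    containing ambiguity codes translate to X and never count as stops.
    """
    seq = sequence.replace("-", "").upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if frame is not None:
        if frame not in (1, 2, 3):
            raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
        return _screen_frame(seq, frame)
    screens = [_screen_frame(seq, f) for f in (1, 2, 3)]
    return min(screens, key=lambda s: (s.n_stops, s.frame))


def amino_acid_divergence(sequence: str, consensus_protein: str, frame: int = 1) -> float:
    """Mean amino-acid p-distance of a sequence's translation to a consensus.

    Reported as a metric only; the package sets no pass/fail threshold on
    amino-acid profiles.
    """
    protein = translate_screen(sequence, frame=frame).protein
    n = min(len(protein), len(consensus_protein))
    if n == 0:
        return float("nan")
    usable = [(a, b) for a, b in zip(protein[:n], consensus_protein[:n]) if "X" not in (a, b)]
    if not usable:
        return float("nan")
    return sum(a != b for a, b in usable) / len(usable)


def compliance_check(
    record,
    min_len: int = 500,
    max_ambig_frac: float = 0.01,
    frame: int | None = None,
    indel_events: list[IndelEvent] | None = None,
) -> QCResult:
    """Flag a record against barcode-compliance criteria.

    ``too_short``: ungapped length < min_len. ``excess_ambiguity``: fraction
    of non-ACGT (ambiguity) symbols >= max_ambig_frac. ``stop_codon``: any
    in-frame stop in the selected reading frame. ``frameshift``: any supplied
    indel event whose length is not a multiple of three. ``passed`` is true
    iff no flag is raised.
    """
    seq = record.ungapped().upper()
    flags: set = set()
    details: dict = {}

    if len(seq) < min_len:
        flags.add("too_short")
        details["too_short"] = {"length": len(seq), "min_len": min_len}

    ambig = [i + 1 for i, ch in enumerate(seq) if ch not in _ACGT]
    frac = len(ambig) / len(seq) if seq else 1.0
    if frac >= max_ambig_frac:
        flags.add("excess_ambiguity")
        details["excess_ambiguity"] = {"positions": ambig, "fraction": frac}

    if len(seq) < 3:
        flags.add("not_translatable")
    else:
        screen = translate_screen(seq, frame=frame)
        if screen.n_stops:
            flags.add("stop_codon")
            details["stop_codon"] = {
                "frame": screen.frame,
                "positions": screen.stop_positions,
            }

    if indel_events:
        shifts = [e for e in indel_events if not e.frame_preserving]
        if shifts:
            flags.add("frameshift")
            details["frameshift"] = {
                "events": [(e.kind, e.start, e.end) for e in shifts]
            }

    return QCResult(specimen_id=record.specimen_id, passed=not flags, flags=flags, details=details)


@dataclass
class AnchoredAlignment:
    """Pairwise alignment of a query onto the Folmer reference."""

    query_id: str
    ref_row: str            # aligned reference, gaps where the query has insertions
    query_row: str          # aligned query, gaps where it lacks reference sites
    identity: float         # fraction identical over columns where both have a base

    def coordinate_map(self) -> dict[int, int]:
        """Map 1-based ungapped query positions to reference positions 1..658."""
        out = {}
        qpos = rpos = 0
        for rch, qch in zip(self.ref_row, self.query_row):
            if rch != "-":
                rpos += 1
            if qch != "-":
                qpos += 1
                if rch != "-":
                    out[qpos] = rpos
        return out

    def project_to_reference(self) -> str:
        """Query re-expressed on the reference's coordinate grid.

        Insertions relative to the reference are dropped; reference sites the
        query lacks become gaps. All projected rows share the reference
        length, giving a ready-made multiple alignment by anchoring.
        """
        out = []
        for rch, qch in zip(self.ref_row, self.query_row):
            if rch != "-":
                out.append(qch)
        return "".join(out)


def _make_aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # Free end gaps: sub-658 bp fragments should anchor without end penalties.
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def anchor_align(
    sequence: str,
    folmer_reference: str,
    query_id: str = "query",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    min_identity: float = 0.5,
) -> AnchoredAlignment:
    """Globally align a query to the gap-free Folmer reference.

    Affine gap costs: a gap of length L scores gap_open + (L-1)*gap_extend.
    Raises if the aligned identity falls below ``min_identity`` (the query is
    then not credibly homologous to the anchor).
    """
    ref = folmer_reference.replace("-", "").upper()
    query = sequence.replace("-", "").upper()
    if not ref:
        raise ValueError("empty Folmer reference")
    if not query:
        raise ValueError(f"{query_id}: empty query sequence")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(ref, query)[0]
    ref_row, query_row = str(aln[0]), str(aln[1])

    # Identity over the shorter sequence, not just aligned columns: with free
    # end gaps a non-homologous query could otherwise score 100% on a tiny
    # chance overlap.
    matches = sum(
        r == q for r, q in zip(ref_row, query_row) if r != "-" and q != "-"
    )
    identity = matches / max(1, min(len(ref), len(query)))
    if identity < min_identity:
        raise ValueError(
            f"{query_id}: not homologous to anchor (identity {identity:.1%})"
        )
    return AnchoredAlignment(
        query_id=query_id, ref_row=ref_row, query_row=query_row, identity=identity
    )


def _left_normalize_insertion(ref: str, pos_after: int, motif: str) -> tuple[int, str]:
    """Shift an insertion leftwards to its canonical (leftmost) placement.

    ``pos_after`` is the 0-based count of reference characters preceding the
    insertion. Rotating right is valid while the last inserted character
    equals the reference character just before the insertion point.
    """
    p, m = pos_after, motif
    while p > 0 and m and ref[p - 1] == m[-1]:
        m = ref[p - 1] + m[:-1]
        p -= 1
    return p, m


def _left_normalize_deletion(ref: str, start0: int, length: int) -> int:
    """Shift a deletion leftwards while the flanking characters permit it."""
    s = start0
    while s > 0 and ref[s - 1] == ref[s + length - 1]:
        s -= 1
    return s


def detect_indels(aligned: AnchoredAlignment) -> list[IndelEvent]:
    """Convert maximal gap runs of an anchored alignment into indel events.

    End gaps (missing sequence at either end of a partial barcode) are not
    indels and are ignored. Events are left-normalized so that placement is
    deterministic in repetitive context.
    """
    ref_row, query_row = aligned.ref_row, aligned.query_row
    ref = ref_row.replace("-", "")

    # Trim end-gap columns of the query (partial sequences).
    first = 0
    while first < len(query_row) and query_row[first] == "-" and ref_row[first] != "-":
        first += 1
    last = len(query_row)
    while last > first and query_row[last - 1] == "-" and ref_row[last - 1] != "-":
        last -= 1

    events: list[IndelEvent] = []
    rpos = ref_row[:first].replace("-", "")
    ref_count = len(rpos)  # reference chars consumed before the window
    col = first
    while col < last:
        rch, qch = ref_row[col], query_row[col]
        if rch == "-":
            run = col
            motif = []
            while run < last and ref_row[run] == "-":
                motif.append(query_row[run])
                run += 1
            p, m = _left_normalize_insertion(ref, ref_count, "".join(motif))
            events.append(
                IndelEvent(
                    specimen_id=aligned.query_id,
                    kind="insertion",
                    start=p + 1,
                    end=p + len(m),
                    inserted_motif=m,
                )
            )
            col = run
        elif qch == "-":
            run = col
            while run < last and query_row[run] == "-" and ref_row[run] != "-":
                run += 1
            length = run - col
            s0 = _left_normalize_deletion(ref, ref_count, length)
            events.append(
                IndelEvent(
                    specimen_id=aligned.query_id,
                    kind="deletion",
                    start=s0 + 1,
                    end=s0 + length,
                )
            )
            ref_count += length
            col = run
        else:
            ref_count += 1
            col += 1
    return events


def _consensus(rows: list[str]) -> str:
    """Per-column majority (ties to the alphabetically first base)."""
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        out.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(out)


def alignment_partner(record, library) -> str:
    """Best available 658-grid row to locate a record's indels against.

    Indel coordinates are only sharply determined when the counterpart is
    close: a gap placed against a ~15% divergent global reference can slide
    to a score-equal position several sites away. Conspecific records that
    already sit gap-free on the anchor grid (length == anchor length) define
    the same Folmer coordinates, so their consensus is preferred; failing
    that, congeneric records; failing that, the global anchor.
    """
    if library.anchor is None:
        raise ValueError("library has no Folmer anchor")
    L = len(library.anchor)

    def rows(pred):
        return [
            r.sequence
            for r in library
            if r.specimen_id != record.specimen_id and len(r.sequence) == L and pred(r)
        ]

    if record.morpho_species:
        same_sp = rows(lambda r: r.morpho_species == record.morpho_species)
        if same_sp:
            return _consensus(same_sp)
    if record.genus:
        same_gen = rows(lambda r: r.genus == record.genus)
        if same_gen:
            return _consensus(same_gen)
    return library.anchor


def locate_library_indels(
    library, min_identity: float = 0.5
) -> tuple[dict, dict]:
    """Anchor every record and detect its indels in Folmer coordinates.

    Returns ``(events_by_id, aligned_rows_by_id)``; the aligned rows are the
    records projected onto the anchor's 658-site grid (insertions dropped).
    Records failing the homology check are absent from both mappings.
    """
    events_by_id: dict[str, list[IndelEvent]] = {}
    rows_by_id: dict[str, str] = {}
    for record in library:
        partner = alignment_partner(record, library)
        try:
            anchored = anchor_align(
                record.sequence,
                partner,
                query_id=record.specimen_id,
                min_identity=min_identity,
            )
        except ValueError:
            continue
        events_by_id[record.specimen_id] = detect_indels(anchored)
        rows_by_id[record.specimen_id] = anchored.project_to_reference()
    return events_by_id, rows_by_id


def qc_report_rows(results: list[QCResult]) -> list[dict]:
    """Flatten QC results for TSV/JSON export."""
    rows = []
    for r in results:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "passed": r.passed,
                "flags": ";".join(sorted(r.flags)),
                "details": repr(r.details) if r.details else "",
            }
        )
    return rows
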