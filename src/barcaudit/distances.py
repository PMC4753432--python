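"""Kimura two-parameter (K2P) distances and rank-level divergence summaries.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T; observed fraction P) from
transversions (fraction Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap or an ambiguity code are excluded
pair by pair (pairwise deletion). When the log argument is non-positive the
pair is saturated and the distance is undefined (NaN); such pairs are
reported, never silently zeroed or capped, since capping would bias maxima
in divergence summaries.

Summaries aggregate unordered pairs at a taxonomic rank the way barcode-gap
tables are usually built: within-species pairs, between congeneric species,
and between confamilial genera, with statistics reported in percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_PURINE = np.array([True, False, True, False])  # A, C, G, T


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as uint8: A=0 C=1 G=2 T=3, anything else 255."""
    return _ENC[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]


def _pq_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    usable = (a != 255) & (b != 255)
    n = int(usable.sum())
    if n == 0:
        return 0, 0, 0
    ai, bi = a[usable], b[usable]
    diff = ai != bi
    transitions = int((diff & (_PURINE[ai] == _PURINE[bi])).sum())
    transversions = int(diff.sum()) - transitions
    return n, transitions, transversions


def k2p_from_counts(n_sites: int, transitions: int, transversions: int) -> float:
    if n_sites == 0:
        return math.nan
    P = transitions / n_sites
    Q = transversions / n_sites
    arg = (1.0 - 2.0 * P - Q) * math.sqrt(max(1.0 - 2.0 * Q, 0.0))
    if arg <= 0.0:
        return math.nan
    return -0.5 * math.log(arg)


def k2p(seq_a: str, seq_b: str) -> float:
    """K2P distance between two rows of an alignment (NaN if undefined)."""
    d, _ = k2p_with_sites(seq_a, seq_b)
    return d


def k2p_with_sites(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance plus the count of usable (pairwise-deleted) sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences must be aligned to equal length ({len(seq_a)} vs {len(seq_b)})"
        )
    n, ts, tv = _pq_counts(encode(seq_a), encode(seq_b))
    return k2p_from_counts(n, ts, tv), n


def p_distance_with_sites(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected p-distance with pairwise deletion (used for identity %)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    n, ts, tv = _pq_counts(encode(seq_a), encode(seq_b))
    if n == 0:
        return math.nan, 0
    return (ts + tv) / n, n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with per-pair usable-site counts.

    Distances are proportions (not %); undefined (saturated or siteless)
    pairs hold NaN.
    """

    ids: list[str]
    d: np.ndarray
    sites: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        assert self.d.shape == (n, n) and self.sites.shape == (n, n)

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.index(id_a), self.index(id_b)])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.d[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.index(i) for i in ids]
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            sites=self.sites[np.ix_(idx, idx)].copy(),
        )

    def to_square_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("specimen_id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(
                    "NA" if math.isnan(v) else f"{v:.8f}" for v in self.d[i]
                )
                fh.write(f"{sid}\t{row}\n")

    def to_phylip_lower(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                vals = " ".join(
                    "NA" if math.isnan(v) else f"{v:.8f}" for v in self.d[i, :i]
                )
                fh.write(f"{sid:<12s} {vals}".rstrip() + "\n")


def _aligned_rows(library) -> tuple[list[str], list[str]]:
    if library.alignment is not None:
        return library.ids, [library.alignment[i] for i in library.ids]
    lengths = {len(r.sequence) for r in library}
    if len(lengths) > 1:
        raise ValueError(
            "library is not aligned: sequences have unequal lengths and no "
            "alignment is attached"
        )
    return library.ids, [r.sequence for r in library]


def distance_matrix(library) -> DistanceMatrix:
    """All-pairs K2P matrix over an aligned library (pairwise deletion)."""
    ids, rows = _aligned_rows(library)
    enc = [encode(s) for s in rows]
    n = len(ids)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    L = len(rows[0]) if rows else 0
    np.fill_diagonal(sites, L)
    for i in range(n):
        for j in range(i + 1, n):
            ns, ts, tv = _pq_counts(enc[i], enc[j])
            dist = k2p_from_counts(ns, ts, tv)
            d[i, j] = d[j, i] = dist
            sites[i, j] = sites[j, i] = ns
    n_undef = int(np.isnan(d[np.triu_indices(n, 1)]).sum()) if n > 1 else 0
    if n_undef:
        warnings.warn(
            f"{n_undef} pair(s) have undefined K2P distance (saturated or no "
            "usable sites); they are excluded from summaries",
            stacklevel=2,
        )
    return DistanceMatrix(ids=ids, d=d, sites=sites)


def exclusion_filter(library, invalid_names=()) -> "object":
    """Drop records that would distort species-level distance estimates.

    Removed: open-nomenclature records (qualifier sp/cf/aff), records without
    a species-level name, and records whose name is on the invalid-name list
    (e.g. unaccepted synonyms still circulating in public repositories).
    """
    invalid = set(invalid_names)
    keep = [
        r.specimen_id
        for r in library
        if r.qualifier == "none"
        and r.morpho_species
        and r.morpho_species not in invalid
    ]
    return library.subset(keep)


@dataclass
class DistanceSummary:
    """Aggregated divergence at one taxonomic rank, in percent."""

    rank: str                     # "species" | "genus" | "family"
    n_groups: int
    n_comparisons: int            # qualifying unordered pairs
    n_usable: int                 # pairs with a defined distance
    min: float = math.nan
    mean: float = math.nan
    max: float = math.nan
    se: float = math.nan

    def as_row(self) -> dict:
        return {
            "rank": self.rank,
            "taxa": self.n_groups,
            "comparisons": self.n_comparisons,
            "min": self.min,
            "mean": self.mean,
            "max": self.max,
            "se": self.se,
        }


def _rank_pairs(records, rank: str):
    """Yield (group_key, i, j) index pairs qualifying at the given rank."""
    n = len(records)
    for i in range(n):
        ri = records[i]
        for j in range(i + 1, n):
            rj = records[j]
            if rank == "species":
                if ri.morpho_species and ri.morpho_species == rj.morpho_species:
                    yield ri.morpho_species, i, j
            elif rank == "genus":
                if (
                    ri.genus
                    and ri.genus == rj.genus
                    and ri.morpho_species != rj.morpho_species
                ):
                    yield ri.genus, i, j
            elif rank == "family":
                if (
                    ri.family
                    and ri.family == rj.family
                    and ri.genus != rj.genus
                ):
                    yield ri.family, i, j
            else:
                raise ValueError(f"unknown rank: {rank}")


def summarize(matrix: DistanceMatrix, library, rank: str) -> DistanceSummary:
    """Divergence summary at a rank: within species, between congeneric
    species, or between confamilial genera.

    The mean is the simple mean over qualifying pairs; SE is the standard
    error of that mean. Undefined pairs count toward ``n_comparisons`` but
    not toward the statistics. All values in percent.
    """
    records = [library.by_id(i) for i in matrix.ids]
    groups = set()
    dists = []
    n_comparisons = 0
    for key, i, j in _rank_pairs(records, rank):
        groups.add(key)
        n_comparisons += 1
        v = matrix.d[i, j]
        if not math.isnan(v):
            dists.append(v * 100.0)
    if not dists:
        return DistanceSummary(
            rank=rank, n_groups=len(groups), n_comparisons=n_comparisons, n_usable=0
        )
    arr = np.asarray(dists)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return DistanceSummary(
        rank=rank,
        n_groups=len(groups),
        n_comparisons=n_comparisons,
        n_usable=len(arr),
        min=float(arr.min()),
        mean=float(arr.mean()),
        max=float(arr.max()),
        se=se,
    )


@dataclass
class NearestNeighbor:
    species: str
    nn_species: list[str]         # all species attaining the minimum (ties)
    distance: float               # proportion, NaN if no defined cross pair
    pair: tuple[str, str] = field(default=("", ""))


def nearest_neighbor(matrix: DistanceMatrix, species_labels: dict) -> dict:
    """Per-species nearest heterospecific neighbour.

    ``species_labels`` maps specimen_id -> species name; unlabeled specimens
    are ignored. For each species the minimum defined distance from any of
    its members to any member of a different species is reported, with every
    species attaining that minimum.
    """
    labeled = [i for i, sid in enumerate(matrix.ids) if species_labels.get(sid)]
    species = sorted({species_labels[matrix.ids[i]] for i in labeled})
    if len(species) < 2:
        raise ValueError("nearest-neighbour distances need at least two species")
    out = {}
    for sp in species:
        own = [i for i in labeled if species_labels[matrix.ids[i]] == sp]
        best = math.inf
        best_species: list[str] = []
        best_pair = ("", "")
        for i in own:
            for j in labeled:
                other = species_labels[matrix.ids[j]]
                if other == sp:
                    continue
                v = matrix.d[i, j]
                if math.isnan(v):
                    continue
                if v < best - 1e-12:
                    best = v
                    best_species = [other]
                    best_pair = (matrix.ids[i], matrix.ids[j])
                elif abs(v - best) <= 1e-12 and other not in best_species:
                    best_species.append(other)
        out[sp] = NearestNeighbor(
            species=sp,
            nn_species=sorted(best_species),
            distance=best if best < math.inf else math.nan,
            pair=best_pair,
        )
    return out


def summary_table(summaries: list[DistanceSummary]) -> list[dict]:
    return [s.as_row() for s in summaries]
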