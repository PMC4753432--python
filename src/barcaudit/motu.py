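"""Threshold-based MOTU delimitation (BIN-style single linkage).

Specimens are clustered into molecular operational taxonomic units (MOTUs)
as the connected components of the graph whose edges join pairs at K2P
distance <= threshold. The default threshold of 2.2% is the maximum
reference divergence for within-species boundaries used by threshold-based
barcode clustering systems.

This is an explicit single-linkage approximation of BIN assignment: the
refinement stage of the full RESL algorithm is not reproduced here, so the
output is labelled "BIN-style", never "BIN".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

DEFAULT_THRESHOLD = 0.022


@dataclass
class MOTUAssignment:
    """Specimen -> MOTU map from threshold clustering.

    MOTU ids are dense integers from 1, numbered by order of each cluster's
    first member in the input, so the labelling is deterministic.
    """

    mapping: dict[str, int]
    threshold: float
    n_motus: int

    def members(self, motu_id: int) -> list[str]:
        return [sid for sid, m in self.mapping.items() if m == motu_id]

    def motus(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, m in self.mapping.items():
            out.setdefault(m, []).append(sid)
        return out

    def labels(self) -> list[int]:
        return list(self.mapping.values())


def cluster(matrix: DistanceMatrix, threshold: float = DEFAULT_THRESHOLD) -> MOTUAssignment:
    """Single-linkage clustering at a divergence threshold (inclusive).

    Undefined (NaN) distances are treated as exceeding the threshold — two
    specimens saturated beyond measurability are certainly not conspecific —
    and a warning notes how many pairs that affected.
    """
    n = len(matrix.ids)
    if n == 0:
        raise ValueError("cannot cluster an empty distance matrix")
    d = matrix.d
    undef = np.isnan(d[np.triu_indices(n, 1)]).sum() if n > 1 else 0
    if undef:
        warnings.warn(
            f"{int(undef)} undefined pair(s) treated as exceeding the "
            f"{threshold:.3%} threshold",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        adj = (d <= threshold) & ~np.isnan(d)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)

    relabel: dict[int, int] = {}
    mapping: dict[str, int] = {}
    for sid, lab in zip(matrix.ids, labels):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        mapping[sid] = relabel[lab]
    return MOTUAssignment(mapping=mapping, threshold=threshold, n_motus=len(relabel))


@dataclass
class SplitterEntry:
    species: str
    n_motus: int
    motu_ids: list[int]
    max_intra_distance: float     # proportion; NaN if no defined pair


def splitter_report(
    assignment: MOTUAssignment,
    species_labels: dict,
    matrix: DistanceMatrix | None = None,
) -> list[SplitterEntry]:
    """Species whose members are split across more than one MOTU.

    A split flags either deep intraspecific structure (cryptic lineages) or
    labelling problems. ``max_intra_distance`` requires the distance matrix;
    without it NaN is reported.
    """
    by_species: dict[str, list[str]] = {}
    for sid, sp in species_labels.items():
        if sp and sid in assignment.mapping:
            by_species.setdefault(sp, []).append(sid)

    out = []
    for sp in sorted(by_species):
        members = by_species[sp]
        motus = sorted({assignment.mapping[s] for s in members})
        if len(motus) < 2:
            continue
        max_d = math.nan
        if matrix is not None and len(members) > 1:
            vals = []
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    v = matrix.get(members[a], members[b])
                    if not math.isnan(v):
                        vals.append(v)
            if vals:
                max_d = max(vals)
        out.append(
            SplitterEntry(
                species=sp, n_motus=len(motus), motu_ids=motus, max_intra_distance=max_d
            )
        )
    return out


def assignment_rows(assignment: MOTUAssignment) -> list[dict]:
    return [
        {"specimen_id": sid, "motu_id": m} for sid, m in assignment.mapping.items()
    ]
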