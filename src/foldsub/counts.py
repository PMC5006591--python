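"""Substitution counting and matrix construction from superposed alignments.

The pipeline implemented here turns one homology-level multi-structure
alignment into a 21×21 (20 amino acids + gap) substitution/gap count table,
normalizes it into a real-valued homology-level matrix, and sums homology
matrices into a topology-level matrix whose 20×20 block is scaled to a
maximum of 1.

The physical substitution criterion is a Cα–Cα distance test: for every
unordered pair of structures and every alignment column where both have a
residue, the pair of residues counts as a substitution only if their Cα
atoms lie within the cutoff distance in the shared superposition frame;
otherwise each residue is counted against the gap class. Columns where
exactly one structure of the pair has a residue count that residue against
the gap class once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .structio import (
    AA20,
    AA_INDEX,
    MatrixFile,
    MultiStructureAlignment,
    read_json_sidecar,
    read_matrix,
    write_json_sidecar,
    write_matrix,
)

logger = logging.getLogger(__name__)

#: Index of the gap class in the 21×21 count table.
GAP_IDX = 20
LABELS21 = tuple(AA20) + ("-",)


class CountsUsageError(ValueError):
    """Invalid arguments to a counting operation."""


@dataclass(frozen=True)
class SubstitutionCounts:
    """Symmetric 21×21 substitution/gap count table for one homology level.

    Event bookkeeping: every processed (structure pair, column) event lands
    either in exactly one symmetric amino-acid cell (distance within cutoff),
    in two aa–gap increments (distance failure), or in one aa–gap increment
    (one-sided gap column). Columns involving an ``'X'`` residue are excluded
    and tallied in ``n_excluded_events``.
    """

    table: np.ndarray
    cutoff: float
    n_pairs_examined: int
    n_events: int
    n_substitution_events: int
    n_distance_gap_events: int
    n_onesided_gap_events: int
    n_excluded_events: int

    labels = LABELS21

    def __post_init__(self):
        table = np.asarray(self.table, dtype=np.int64)
        object.__setattr__(self, "table", table)
        if table.shape != (21, 21):
            raise CountsUsageError(f"count table must be 21×21, got {table.shape}")
        if (table < 0).any():
            raise CountsUsageError("negative counts")
        if not np.array_equal(table, table.T):
            raise CountsUsageError("count table must be symmetric")
        if table[GAP_IDX, GAP_IDX] != 0:
            raise CountsUsageError("gap–gap cell must be zero")


@dataclass(frozen=True)
class NormalizedMatrix:
    """Normalized (and symmetrized) homology-level substitution matrix.

    ``values`` is the 20×20 block after symmetrization; ``gap_row`` carries
    the normalized aa→gap frequencies as metadata.
    """

    values: np.ndarray
    gap_row: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "gap_row", np.asarray(self.gap_row, dtype=float))
        if self.values.shape != (20, 20) or self.gap_row.shape != (20,):
            raise CountsUsageError("normalized matrix must be 20×20 with a 20-gap row")


@dataclass(frozen=True)
class TopologyMatrix:
    """Topology-level substitution matrix: summed homology matrices, max-scaled.

    The 20×20 block has maximum 1 whenever any entry is nonzero; the gap row
    is scaled by the same factor.
    """

    topology_id: str
    values: np.ndarray
    gap_row: np.ndarray
    n_homology_levels: int
    cutoff: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "gap_row", np.asarray(self.gap_row, dtype=float))
        if self.values.shape != (20, 20):
            raise CountsUsageError("topology matrix must be 20×20")
        if (self.values < 0).any() or (self.gap_row < 0).any():
            raise CountsUsageError("topology matrix entries must be nonnegative")


def count_substitutions(msta: MultiStructureAlignment, cutoff: float) -> SubstitutionCounts:
    """Count substitutions and gaps over all structure pairs of an alignment.

    Parameters
    ----------
    msta : MultiStructureAlignment
        ≥2 superposed structures sharing a coordinate frame.
    cutoff : float
        Cα–Cα distance cutoff in Å; aligned residues further apart than this
        are treated as gapped rather than substituted.
    """
    if msta.n_structures < 2:
        raise CountsUsageError("need at least 2 structures to count substitutions")
    if not (cutoff > 0):
        raise CountsUsageError(f"cutoff must be positive, got {cutoff}")

    codes = [
        np.array([AA_INDEX.get(ch, -1) for ch in chain.sequence], dtype=np.int64)
        for chain in msta.chains
    ]
    table = np.zeros((21, 21), dtype=np.int64)
    n_sub = n_gap_dist = n_gap_one = n_excluded = 0
    n_pairs = 0

    for i, j in combinations(range(msta.n_structures), 2):
        n_pairs += 1
        ri, rj = msta.index[i], msta.index[j]
        both = (ri >= 0) & (rj >= 0)
        only_i = (ri >= 0) & (rj < 0)
        only_j = (ri < 0) & (rj >= 0)

        a = codes[i][ri[both]]
        b = codes[j][rj[both]]
        valid = (a >= 0) & (b >= 0)
        n_excluded += int((~valid).sum())
        d = np.linalg.norm(
            msta.chains[i].coords[ri[both]] - msta.chains[j].coords[rj[both]], axis=1
        )
        within = valid & (d <= cutoff)
        fail = valid & (d > cutoff)

        aw, bw = a[within], b[within]
        np.add.at(table, (aw, bw), 1)
        off = aw != bw
        np.add.at(table, (bw[off], aw[off]), 1)
        n_sub += int(within.sum())

        for res in (a[fail], b[fail]):
            np.add.at(table, (res, np.full_like(res, GAP_IDX)), 1)
            np.add.at(table, (np.full_like(res, GAP_IDX), res), 1)
        n_gap_dist += int(fail.sum())

        for codes_row, idx_row, mask in ((codes[i], ri, only_i), (codes[j], rj, only_j)):
            res = codes_row[idx_row[mask]]
            ok = res >= 0
            n_excluded += int((~ok).sum())
            res = res[ok]
            np.add.at(table, (res, np.full_like(res, GAP_IDX)), 1)
            np.add.at(table, (np.full_like(res, GAP_IDX), res), 1)
            n_gap_one += int(ok.sum())

    if n_excluded:
        logger.info("%d pair/column events excluded ('X' residues)", n_excluded)
    return SubstitutionCounts(
        table=table,
        cutoff=float(cutoff),
        n_pairs_examined=n_pairs,
        n_events=n_sub + n_gap_dist + n_gap_one,
        n_substitution_events=n_sub,
        n_distance_gap_events=n_gap_dist,
        n_onesided_gap_events=n_gap_one,
        n_excluded_events=n_excluded,
    )


def normalize_counts(counts: SubstitutionCounts, symmetrize: bool = True) -> NormalizedMatrix:
    """Normalize a count table into a homology-level frequency matrix.

    Each count ``C[a][b]`` is divided by the number of times ``a`` was
    replaced by anything *other than* ``b`` — that is, the row sum over the
    full 21-class row (conserved positions and gaps included) minus
    ``C[a][b]`` itself. A zero denominator yields 0.

    The raw result is asymmetric; by default it is symmetrized over the
    20×20 block as ``(M + Mᵀ) / 2``. The gap column is normalized by the
    same rule and returned as a separate row.
    """
    C = counts.table.astype(float)
    rowsum = C[:20].sum(axis=1, keepdims=True)  # over all 21 targets
    denom = rowsum - C[:20]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(denom > 0, C[:20] / np.where(denom > 0, denom, 1.0), 0.0)
    if np.any((denom <= 0) & (C[:20] > 0)):
        logger.warning("zero normalization denominator for a nonzero count row")
    block = raw[:, :20]
    if symmetrize:
        block = (block + block.T) / 2.0
    return NormalizedMatrix(values=block, gap_row=raw[:, GAP_IDX])


def aggregate_topology(
    hmats, topology_id: str, cutoff: float | None = None
) -> TopologyMatrix:
    """Sum homology-level matrices and scale the topology matrix to max 1.

    The element-wise sum of the normalized homology matrices is divided by
    the maximum of its 20×20 block so that the block maximum is exactly 1;
    the gap row is scaled by the same factor. An all-zero sum is returned
    as-is with a logged warning.
    """
    hmats = list(hmats)
    if not hmats:
        raise CountsUsageError("aggregate_topology requires at least one homology matrix")
    values = np.sum([h.values for h in hmats], axis=0)
    gap_row = np.sum([h.gap_row for h in hmats], axis=0)
    mx = values.max()
    if mx > 0:
        values = values / mx
        gap_row = gap_row / mx
    else:
        logger.warning("topology %s: all-zero summed matrix", topology_id)
    return TopologyMatrix(
        topology_id=topology_id,
        values=values,
        gap_row=gap_row,
        n_homology_levels=len(hmats),
        cutoff=cutoff,
    )


def build_topology_matrix(
    mstas, topology_id: str, cutoff: float
) -> TopologyMatrix:
    """Full per-topology pipeline: count, normalize, aggregate.

    ``mstas`` holds one :class:`MultiStructureAlignment` per homology level.
    """
    hmats = [normalize_counts(count_substitutions(m, cutoff)) for m in mstas]
    return aggregate_topology(hmats, topology_id, cutoff=cutoff)


def save_topology_matrix(tm: TopologyMatrix, path) -> None:
    """Write a topology matrix as an NCBI-format file plus a JSON sidecar."""
    path = Path(path)
    write_matrix(
        MatrixFile(name=f"topology_{tm.topology_id}", alphabet=AA20, values=tm.values),
        path,
        comments=[f"topology {tm.topology_id}", "normalized: max of 20x20 block == 1"],
    )
    write_json_sidecar(
        {
            "topology_id": tm.topology_id,
            "cutoff": tm.cutoff,
            "n_homology_levels": tm.n_homology_levels,
            "normalization": "max1",
            "gap_row": [float(v) for v in tm.gap_row],
        },
        path.with_suffix(path.suffix + ".json"),
    )


def load_topology_matrix(path) -> TopologyMatrix:
    path = Path(path)
    mf = read_matrix(path)
    meta = read_json_sidecar(path.with_suffix(path.suffix + ".json"))
    return TopologyMatrix(
        topology_id=meta["topology_id"],
        values=mf.block(AA20),
        gap_row=np.asarray(meta.get("gap_row", np.zeros(20)), dtype=float),
        n_homology_levels=int(meta["n_homology_levels"]),
        cutoff=meta.get("cutoff"),
    )


#: Default Cα cutoff distances (Å) per structural class.
DEFAULT_CUTOFFS = {
    "mainly-alpha": 3.0,
    "mainly-beta": 3.0,
    "alpha-beta": 4.0,
}
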