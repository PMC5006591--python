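"""Combination of generic anchor matrices with topology-specific matrices.

The final fold-specific matrix is a weighted perturbation of a generic
anchor (BLOSUM62 or a VT-family matrix):

    combined = anchor + x · topology_matrix

with the weight ``x`` swept over 0–30 by default (the useful range in
practice lies between 10 and 30). The working form is real-valued;
integer scaling exists only for export to external tools. Discrimination
z-scores are invariant under any consistent positive rescaling of matrix
and gap penalties, so the export scaling never affects evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import TopologyMatrix
from .structio import AA20, NCBI24, MatrixFile

#: Default weight grid for the anchor/topology combination.
DEFAULT_WEIGHTS = tuple(range(0, 31))


class CombineError(ValueError):
    pass


@dataclass(frozen=True)
class CombinedMatrix:
    """Anchor + weight · topology matrix over the 20-residue alphabet.

    The 20×20 working values are real; the originating anchor is kept so
    that exports can carry its B/Z/X/* rows unchanged.
    """

    anchor: MatrixFile
    topology_id: str
    weight: float
    values: np.ndarray

    alphabet = AA20

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (20, 20):
            raise CombineError(f"combined matrix must be 20×20, got {values.shape}")
        if self.weight < 0:
            raise CombineError("weight must be nonnegative")

    @property
    def name(self) -> str:
        return f"{self.anchor.name}+{self.weight:g}x{self.topology_id}"


def combine_matrices(anchor: MatrixFile, topo: TopologyMatrix, x: float) -> CombinedMatrix:
    """Element-wise ``anchor + x · topology`` over the 20×20 block."""
    if x < 0:
        raise CombineError(f"weight must be nonnegative, got {x}")
    block = anchor.block(AA20)  # raises if a standard residue is missing
    return CombinedMatrix(
        anchor=anchor,
        topology_id=topo.topology_id,
        weight=float(x),
        values=block + float(x) * topo.values,
    )


def export_blast_matrix(
    m: CombinedMatrix,
    scale: int = 100,
    cap: int | None = None,
    name: str | None = None,
) -> MatrixFile:
    """Export a combined matrix as an integer NCBI-alphabet matrix.

    The 20×20 block is multiplied by ``scale`` and rounded to the nearest
    integer; entries above ``cap`` (if given) are clamped. Rows for
    residues outside the standard 20 (B, Z, X, * when present in the
    anchor) inherit the anchor values, passed through the same
    scale/round/clamp pipeline so the file is internally consistent.
    """
    if not np.all(np.isfinite(m.values)):
        raise CombineError("non-finite values in combined matrix")
    alphabet = "".join(c for c in NCBI24 if c in m.anchor.alphabet)
    n = len(alphabet)
    full = np.empty((n, n), dtype=float)
    anchor_idx = {c: m.anchor.index(c) for c in alphabet}
    for i, ci in enumerate(alphabet):
        for j, cj in enumerate(alphabet):
            full[i, j] = m.anchor.values[anchor_idx[ci], anchor_idx[cj]]
    std = [alphabet.index(c) for c in AA20]
    full[np.ix_(std, std)] = m.values
    out = np.round(scale * full).astype(np.int64)
    if cap is not None:
        out = np.minimum(out, cap)
    return MatrixFile(name=name or m.name, alphabet=alphabet, values=out)


def export_profile(m: CombinedMatrix, profile: str = "psiblast",
                   cap: int | None = None, name: str | None = None) -> MatrixFile:
    """Named export profiles.

    ``"scaled100"``: working values × 100, rounded (optionally clamped).
    ``"psiblast"``: working values rounded to integers — the ×100-then-÷100
    round trip that external search tools consume directly.
    """
    if profile == "psiblast":
        return export_blast_matrix(m, scale=1, cap=cap, name=name)
    if profile == "scaled100":
        return export_blast_matrix(m, scale=100, cap=cap, name=name)
    raise CombineError(f"unknown export profile {profile!r}")
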