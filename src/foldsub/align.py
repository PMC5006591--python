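"""Global pairwise alignment with affine gap penalties (Needleman–Wunsch/Gotoh).

Only the optimal score is needed by the evaluation pipeline, but a full
traceback is kept for inspection. Two gap-cost conventions are supported:

* default: a gap of length ``k`` costs ``gap_open + k * gap_extend``
  (the first gapped position pays both the opening and an extension);
* ``open_includes_extend=True``: a gap of length ``k`` costs
  ``gap_open + (k - 1) * gap_extend``.

Terminal gaps are penalized by default (true global alignment); a
semi-global mode with free terminal gaps is available via
``penalize_ends=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG = -1e30  # effective -infinity that stays finite under addition


class AlignmentError(ValueError):
    """Invalid alignment input (e.g. residue outside the matrix alphabet)."""


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal global alignment of two sequences.

    Removing gaps from ``aligned_a``/``aligned_b`` recovers the inputs, and
    ``score`` equals the sum of matrix values over matched columns minus the
    affine cost of every gap run.
    """

    score: float
    aligned_a: str
    aligned_b: str
    gap_open: float
    gap_extend: float


def _matrix_lookup(matrix):
    """Normalize the many matrix-like inputs to ``(char→index, ndarray)``."""
    alphabet = getattr(matrix, "alphabet", None)
    values = getattr(matrix, "values", None)
    if alphabet is not None and values is not None:
        return {c: i for i, c in enumerate(alphabet)}, np.asarray(values, dtype=float)
    if alphabet is not None:  # Bio.Align.substitution_matrices.Array
        return {c: i for i, c in enumerate(alphabet)}, np.asarray(matrix, dtype=float)
    if isinstance(matrix, tuple) and len(matrix) == 2:
        alphabet, values = matrix
        return {c: i for i, c in enumerate(alphabet)}, np.asarray(values, dtype=float)
    raise AlignmentError(f"unsupported matrix object: {type(matrix)!r}")


def _encode(seq: str, index: dict, which: str) -> np.ndarray:
    codes = np.empty(len(seq), dtype=np.int64)
    for pos, ch in enumerate(seq):
        try:
            codes[pos] = index[ch]
        except KeyError:
            raise AlignmentError(
                f"residue {ch!r} at position {pos + 1} of sequence {which} "
                f"is not in the matrix alphabet"
            ) from None
    return codes


def nw_score(
    a: str,
    b: str,
    matrix,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    *,
    open_includes_extend: bool = False,
    penalize_ends: bool = True,
) -> float:
    """Optimal global affine-gap alignment score (no traceback)."""
    M, Ix, Iy = _gotoh(a, b, matrix, gap_open, gap_extend,
                       open_includes_extend, penalize_ends)
    return _final_score(M, Ix, Iy, penalize_ends)


def nw_align(
    a: str,
    b: str,
    matrix,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    *,
    open_includes_extend: bool = False,
    penalize_ends: bool = True,
) -> AlignmentResult:
    """Optimal global affine-gap alignment with traceback.

    Ties in the traceback are broken deterministically: diagonal, then up
    (gap in ``b``), then left (gap in ``a``).
    """
    M, Ix, Iy = _gotoh(a, b, matrix, gap_open, gap_extend,
                       open_includes_extend, penalize_ends)
    if not penalize_ends:
        raise NotImplementedError(
            "traceback is only implemented for end-penalized global alignment; "
            "use nw_score(..., penalize_ends=False) for semi-global scores"
        )
    fc = gap_open + gap_extend if not open_includes_extend else gap_open
    aligned_a, aligned_b = _traceback(a, b, M, Ix, Iy, fc, gap_extend)
    return AlignmentResult(
        score=float(_final_score(M, Ix, Iy, True)),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def _gotoh(a, b, matrix, gap_open, gap_extend, open_includes_extend, penalize_ends):
    if gap_open < 0 or gap_extend < 0:
        raise AlignmentError("gap penalties are positive magnitudes")
    index, vals = _matrix_lookup(matrix)
    ca = _encode(a, index, "a")
    cb = _encode(b, index, "b")
    n, m = len(ca), len(cb)
    S = vals[np.ix_(ca, cb)] if n and m else np.zeros((n, m))

    fc = gap_open + gap_extend if not open_includes_extend else gap_open
    ge = gap_extend
    j_arange = np.arange(m)

    # M: both consumed; Ix: gap in b (consume a, "up"); Iy: gap in a ("left").
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    if m:
        if penalize_ends:
            Iy[0, 1:] = -fc - ge * j_arange
        else:
            Iy[0, 1:] = 0.0
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        if m:
            M[i, 1:] = S[i - 1] + prev_best[:-1]
        open_from = np.maximum(M[i - 1], Iy[i - 1]) - fc
        Ix[i] = np.maximum(open_from, Ix[i - 1] - ge)
        if not penalize_ends:
            Ix[i, 0] = 0.0
        if m:
            # In-row horizontal recurrence solved by a prefix max:
            # Iy[i, j] = max_{k<j} ( max(M[i,k], Ix[i,k]) - fc - (j-1-k)·ge )
            P = np.maximum(M[i, :m], Ix[i, :m])
            acc = np.maximum.accumulate(P + ge * j_arange)
            Iy[i, 1:] = acc - fc - ge * j_arange
    return M, Ix, Iy


def _final_score(M, Ix, Iy, penalize_ends):
    best = np.maximum(np.maximum(M, Ix), Iy)
    if penalize_ends:
        return float(best[-1, -1])
    # free terminal gaps: finish anywhere on the last row or column
    return float(max(best[-1, :].max(), best[:, -1].max()))


def _traceback(a, b, M, Ix, Iy, fc, ge):
    n, m = len(a), len(b)
    out_a, out_b = [], []
    tol = 1e-9

    def pick(i, j):
        vals = (M[i, j], Ix[i, j], Iy[i, j])
        best = max(vals)
        for state, v in zip("MXY", vals):  # diagonal, then up, then left
            if v >= best - tol:
                return state
        raise AssertionError("unreachable")

    state = pick(n, m)
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = pick(i, j) if (i or j) else "M"
        elif state == "X":  # gap in b, consume a
            out_a.append(a[i - 1])
            out_b.append("-")
            target = Ix[i, j]
            i -= 1
            if abs(M[i, j] - fc - target) <= tol:
                state = "M"
            elif abs(Ix[i, j] - ge - target) <= tol:
                state = "X"
            else:
                state = "Y"
        else:  # gap in a, consume b
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Iy[i, j]
            j -= 1
            if abs(M[i, j] - fc - target) <= tol:
                state = "M"
            elif abs(Ix[i, j] - fc - target) <= tol:
                state = "X"
            else:
                state = "Y"
    return "".join(reversed(out_a)), "".join(reversed(out_b))
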