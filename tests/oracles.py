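"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own dynamic-programming and
vectorized counting code paths: alignments are enumerated exhaustively and
scored by scanning the aligned strings, and substitution counts are
accumulated with plain Python loops.
"""

import math
from itertools import combinations

import numpy as np

from foldsub.structio import AA20

GAP_IDX = 20


def score_aligned(sa, sb, alphabet, vals, gap_open, gap_extend,
                  open_includes_extend=False):
    """Score an alignment by scanning columns and charging gap runs."""
    idx = {c: i for i, c in enumerate(alphabet)}
    first = gap_open if open_includes_extend else gap_open + gap_extend
    s = 0.0
    prev = None
    for ca, cb in zip(sa, sb):
        if ca == "-" and cb == "-":
            raise ValueError("both-gap column")
        if ca == "-":
            state = "Y"
        elif cb == "-":
            state = "X"
        else:
            state = "M"
        if state == "M":
            s += vals[idx[ca], idx[cb]]
        else:
            s -= first if prev != state else gap_extend
        prev = state
    return s


def enumerate_alignments(a, b):
    """Yield every global alignment of a and b (no both-gap columns)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for sa, sb in enumerate_alignments(a[1:], b):
            yield a[0] + sa, "-" + sb
    if b:
        for sa, sb in enumerate_alignments(a, b[1:]):
            yield "-" + sa, b[0] + sb
    if a and b:
        for sa, sb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + sa, b[0] + sb


def best_alignment_score(a, b, alphabet, vals, gap_open, gap_extend,
                         open_includes_extend=False):
    """Optimal global score by exhaustive enumeration (tiny inputs only)."""
    return max(
        score_aligned(sa, sb, alphabet, vals, gap_open, gap_extend,
                      open_includes_extend)
        for sa, sb in enumerate_alignments(a, b)
    )


def brute_force_counts(msta, cutoff):
    """Substitution/gap count table by plain loops over pairs and columns."""
    table = np.zeros((21, 21), dtype=np.int64)
    n_events = 0
    for i, j in combinations(range(msta.n_structures), 2):
        for c in range(msta.n_columns):
            ri, rj = msta.index[i, c], msta.index[j, c]
            if ri < 0 and rj < 0:
                continue
            if ri >= 0 and rj >= 0:
                aa = msta.chains[i].sequence[ri]
                bb = msta.chains[j].sequence[rj]
                if aa not in AA20 or bb not in AA20:
                    continue
                ia, ib = AA20.index(aa), AA20.index(bb)
                d = math.dist(msta.chains[i].coords[ri], msta.chains[j].coords[rj])
                if d <= cutoff:
                    table[ia, ib] += 1
                    if ia != ib:
                        table[ib, ia] += 1
                else:
                    for r in (ia, ib):
                        table[r, GAP_IDX] += 1
                        table[GAP_IDX, r] += 1
                n_events += 1
            else:
                chain, r = ((msta.chains[i], ri) if ri >= 0
                            else (msta.chains[j], rj))
                aa = chain.sequence[r]
                if aa not in AA20:
                    continue
                ia = AA20.index(aa)
                table[ia, GAP_IDX] += 1
                table[GAP_IDX, ia] += 1
                n_events += 1
    return table, n_events
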