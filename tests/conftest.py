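import numpy as np
import pytest

from foldsub.structio import (
    AA20,
    GappedAlignment,
    MultiStructureAlignment,
    StructureChain,
    load_blosum62,
)


def build_msta(rows, coords):
    """Assemble a MultiStructureAlignment from gapped rows and coordinates.

    ``rows``: {id: gapped string}; ``coords``: {id: (n_residues, 3) array}.
    """
    chains = []
    for rid, row in rows.items():
        seq = row.replace("-", "")
        chains.append(StructureChain(id=rid, sequence=seq,
                                     coords=np.asarray(coords[rid], float)))
    return MultiStructureAlignment(
        chains=tuple(chains),
        alignment=GappedAlignment(ids=tuple(rows), rows=tuple(rows.values())),
    )


def random_msta(rng, n_structures=3, n_columns=8, gap_p=0.2, spread=5.0):
    """A random small alignment bundle with arbitrary coordinates."""
    rows, coords = {}, {}
    for s in range(n_structures):
        while True:
            gaps = rng.random(n_columns) < gap_p
            if not gaps.all():
                break
        row = "".join(
            "-" if g else AA20[rng.integers(0, 20)] for g in gaps
        )
        rows[f"s{s}"] = row
        n_res = sum(1 for ch in row if ch != "-")
        coords[f"s{s}"] = rng.normal(0.0, spread, size=(n_res, 3))
    return build_msta(rows, coords)


@pytest.fixture(scope="session")
def blosum62():
    return load_blosum62()


def toy_matrix(match=2, mismatch=-1, alphabet="ACGT"):
    n = len(alphabet)
    vals = np.full((n, n), mismatch, dtype=float)
    np.fill_diagonal(vals, match)
    return alphabet, vals
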