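"""Deterministic synthetic superposed-structure families.

These families stand in for CATH homology-level structure sets (synthetic;
no real folds are modelled). Each family descends from a random ancestor
sequence: descendants substitute residues at a background rate, with
designated residue pairs exchanged preferentially (the planted
topology-specific signal the pipeline should recover), and drop residues at
an indel rate. All structures share an ideal α-helix backbone — rise 1.5 Å,
100° per residue, radius 2.3 Å, textbook constants — so that aligned
residues sit at the same backbone point up to independent Gaussian
coordinate jitter. The jitter standard deviation plays the role of
structure-superposition error and is what the Cα cutoff filters on.

Held-out test pairs (two extra descendants per family, never used for
matrix building) emulate structurally-similar-but-sequence-dissimilar
benchmark pairs at a requested divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evaluate import PairEntry, PairSet
from .structio import AA20, GappedAlignment, MultiStructureAlignment, StructureChain

logger = logging.getLogger(__name__)

HELIX_RISE = 1.5  # Å per residue
HELIX_TURN = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å

# Stream tags: independent deterministic RNG streams derived from one seed.
_ANCESTOR, _FAMILY, _HELDOUT = 0, 1, 2


class FixtureUsageError(ValueError):
    pass


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic homology-level family.

    ``preferred_pairs`` are (aa, aa, enrichment) triples: when either member
    mutates, the partner is drawn ``enrichment`` times more often than any
    other replacement.
    """

    topology_id: str = "1.10.10"
    clazz: str = "mainly-alpha"
    n_structures: int = 4
    length: int = 120
    jitter_sigma: float = 0.5
    background_sub_rate: float = 0.3
    preferred_pairs: tuple = (("E", "K", 5.0),)
    indel_rate: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_structures < 2:
            raise FixtureUsageError("n_structures must be ≥ 2")
        if self.length < 3:
            raise FixtureUsageError("length must be ≥ 3")
        for p in (self.background_sub_rate, self.indel_rate):
            if not 0.0 <= p <= 1.0:
                raise FixtureUsageError(f"rate {p} outside [0, 1]")
        if self.jitter_sigma < 0:
            raise FixtureUsageError("jitter_sigma must be nonnegative")
        for a, b, f in self.preferred_pairs:
            if a not in AA20 or b not in AA20 or a == b:
                raise FixtureUsageError(f"invalid preferred pair ({a}, {b})")
            if f < 1:
                raise FixtureUsageError("enrichment factor must be ≥ 1")


@dataclass(frozen=True)
class FamilyBundle:
    """A generated family: the superposed alignment plus its ancestor."""

    spec: FamilySpec
    msta: MultiStructureAlignment
    ancestor: str


def helix_backbone(length: int) -> np.ndarray:
    """Ideal α-helix Cα positions: (length, 3) array in Å."""
    k = np.arange(length)
    theta = np.deg2rad(HELIX_TURN) * k
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * k]
    )


def _rng(spec: FamilySpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), stream])


def _replacement_weights(preferred_pairs) -> np.ndarray:
    """(20, 20) replacement weight table; diagonal zero."""
    w = np.ones((20, 20))
    np.fill_diagonal(w, 0.0)
    for a, b, f in preferred_pairs:
        ia, ib = AA20.index(a), AA20.index(b)
        w[ia, ib] *= f
        w[ib, ia] *= f
    return w / w.sum(axis=1, keepdims=True)


def mutate_sequence(
    seq: str, rate: float, preferred_pairs, rng: np.random.Generator
) -> str:
    """Substitute each site with probability ``rate``, enriched replacements."""
    weights = _replacement_weights(preferred_pairs)
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    for pos in np.nonzero(hit)[0]:
        ia = AA20.index(seq[pos])
        out[pos] = AA20[rng.choice(20, p=weights[ia])]
    return "".join(out)


def _sample_ancestor(spec: FamilySpec) -> str:
    rng = _rng(spec, _ANCESTOR)
    return "".join(AA20[i] for i in rng.integers(0, 20, size=spec.length))


def make_family(spec: FamilySpec) -> FamilyBundle:
    """Generate one superposed family; same spec + seed → identical output."""
    ancestor = _sample_ancestor(spec)
    backbone = helix_backbone(spec.length)
    rng = _rng(spec, _FAMILY)

    ids, rows, chains = [], [], []
    for s in range(spec.n_structures):
        seq = mutate_sequence(ancestor, spec.background_sub_rate,
                              spec.preferred_pairs, rng)
        keep = rng.random(spec.length) >= spec.indel_rate
        if keep.sum() == 0:  # degenerate draw; keep one residue
            keep[0] = True
        row = "".join(ch if k else "-" for ch, k in zip(seq, keep))
        coords = backbone[keep]
        if spec.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sigma, coords.shape)
        sid = f"{spec.topology_id}.h{spec.seed}_s{s}"
        ids.append(sid)
        rows.append(row)
        chains.append(
            StructureChain(id=sid, sequence="".join(ch for ch in row if ch != "-"),
                           coords=coords)
        )
    msta = MultiStructureAlignment(
        chains=tuple(chains),
        alignment=GappedAlignment(ids=tuple(ids), rows=tuple(rows)),
    )
    return FamilyBundle(spec=spec, msta=msta, ancestor=ancestor)


def make_pairset(
    specs: Sequence[FamilySpec],
    divergence: float = 0.7,
    identity_ceiling: float = 0.3,
) -> PairSet:
    """Held-out similar pairs, one per family spec.

    Two extra descendants of each family's ancestor are drawn from an RNG
    stream disjoint from the one used by :func:`make_family`, so pair
    sequences never appear in the matrix-training alignments. Each pair's
    positional identity is checked against ``identity_ceiling`` (a warning
    reports the achieved identity when the ceiling is exceeded).
    """
    if len(specs) < 3:
        raise FixtureUsageError("need at least 3 family specs for a pair set")
    entries = []
    for spec in specs:
        ancestor = _sample_ancestor(spec)
        rng = _rng(spec, _HELDOUT)
        seq_a = mutate_sequence(ancestor, divergence, spec.preferred_pairs, rng)
        seq_b = mutate_sequence(ancestor, divergence, spec.preferred_pairs, rng)
        identity = float(np.mean([x == y for x, y in zip(seq_a, seq_b)]))
        if identity >= identity_ceiling:
            logger.warning(
                "similar pair for %s has identity %.1f%% (ceiling %.0f%%)",
                spec.topology_id, 100 * identity, 100 * identity_ceiling,
            )
        entries.append(
            PairEntry(topology_id=spec.topology_id, clazz=spec.clazz,
                      seq_a=seq_a, seq_b=seq_b)
        )
    return PairSet(entries=tuple(entries))


def random_preferred_pairs(rng: np.random.Generator, n_pairs: int = 3,
                           enrichment: float = 5.0) -> tuple:
    """Draw ``n_pairs`` distinct unordered residue pairs with one enrichment."""
    pairs = set()
    while len(pairs) < n_pairs:
        i, j = rng.choice(20, size=2, replace=False)
        pairs.add((min(i, j), max(i, j)))
    return tuple((AA20[i], AA20[j], float(enrichment)) for i, j in sorted(pairs))


def make_benchmark(
    n_topologies: int = 10,
    families_per_topology: int = 12,
    seed: int = 0,
    divergence: float = 0.7,
    n_pairs_preferred: int = 3,
    enrichment: float = 5.0,
    clazz: str = "mainly-alpha",
    **spec_kwargs,
):
    """A full synthetic benchmark: training bundles plus held-out pair set.

    Returns ``(bundles, pairset)`` where ``bundles`` maps topology id to a
    list of :class:`MultiStructureAlignment` (one per synthetic homology
    level). Each topology gets its own randomly drawn preferred residue
    pairs, so its planted substitution signal is topology-specific.
    """
    master = np.random.default_rng(int(seed))
    bundles: dict = {}
    pair_specs = []
    for t in range(n_topologies):
        topo_id = f"9.{10 + t}.{10}"
        preferred = random_preferred_pairs(master, n_pairs_preferred, enrichment)
        fam_specs = [
            FamilySpec(
                topology_id=topo_id,
                clazz=clazz,
                preferred_pairs=preferred,
                seed=int(master.integers(0, 2**31 - 1)),
                **spec_kwargs,
            )
            for _ in range(families_per_topology)
        ]
        bundles[topo_id] = [make_family(fs).msta for fs in fam_specs]
        pair_specs.append(fam_specs[0])
    pairset = make_pairset(pair_specs, divergence=divergence)
    return bundles, pairset
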