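import numpy as np
import pytest

from foldsub.counts import (
    CountsUsageError,
    GAP_IDX,
    SubstitutionCounts,
    aggregate_topology,
    count_substitutions,
    normalize_counts,
)
from foldsub.structio import AA20

from conftest import build_msta, random_msta
from oracles import brute_force_counts

A, G, C, R = (AA20.index(x) for x in "AGCR")


def _counts_from_table(table, cutoff=3.0):
    return SubstitutionCounts(
        table=table, cutoff=cutoff, n_pairs_examined=1, n_events=0,
        n_substitution_events=0, n_distance_gap_events=0,
        n_onesided_gap_events=0, n_excluded_events=0,
    )


def test_identical_superposed_structures_give_diagonal_counts():
    coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], float)
    msta = build_msta({"a": "AGC", "b": "AGC"}, {"a": coords, "b": coords})
    c = count_substitutions(msta, 3.0)
    assert c.table[A, A] == c.table[G, G] == c.table[C, C] == 1
    assert c.table[:, GAP_IDX].sum() == 0
    assert c.n_events == 3 and c.n_substitution_events == 3


def test_distance_failure_counts_two_gap_cells():
    coords_a = np.array([[0.0, 0, 0]])
    coords_b = np.array([[3.5, 0, 0]])
    msta = build_msta({"a": "A", "b": "R"}, {"a": coords_a, "b": coords_b})
    c = count_substitutions(msta, 3.0)
    assert c.table[A, R] == 0
    assert c.table[A, GAP_IDX] == 1 and c.table[R, GAP_IDX] == 1
    assert c.n_distance_gap_events == 1


def test_onesided_gap_column_counts_one_gap_cell():
    msta = build_msta(
        {"a": "AG", "b": "A-"},
        {"a": np.zeros((2, 3)), "b": np.zeros((1, 3))},
    )
    c = count_substitutions(msta, 3.0)
    assert c.table[G, GAP_IDX] == 1
    assert c.n_onesided_gap_events == 1


@pytest.mark.parametrize("cutoff", [1.0, 3.0, 8.0])
@pytest.mark.parametrize("seed", range(8))
def test_counts_match_brute_force_enumeration(seed, cutoff):
    """Vectorized counting equals a plain pair × column enumeration."""
    rng = np.random.default_rng(seed)
    msta = random_msta(rng, n_structures=int(rng.integers(2, 5)),
                       n_columns=int(rng.integers(3, 11)))
    c = count_substitutions(msta, cutoff)
    expected, n_events = brute_force_counts(msta, cutoff)
    np.testing.assert_array_equal(c.table, expected)
    assert c.n_events == n_events


@pytest.mark.parametrize("seed", range(10))
def test_event_conservation_and_cutoff_monotonicity(seed):
    rng = np.random.default_rng(100 + seed)
    msta = random_msta(rng, n_structures=3, n_columns=10)
    prev = None
    for cutoff in (0.5, 2.0, 5.0, 20.0):
        c = count_substitutions(msta, cutoff)
        # one aa–aa cell per substitution event, two gap increments per
        # distance failure, one per one-sided column
        aa_block = c.table[:20, :20]
        upper = np.triu(aa_block).sum()
        assert upper == c.n_substitution_events
        assert c.table[:20, GAP_IDX].sum() == (
            2 * c.n_distance_gap_events + c.n_onesided_gap_events
        )
        assert c.n_events == (c.n_substitution_events
                              + c.n_distance_gap_events
                              + c.n_onesided_gap_events)
        if prev is not None:
            assert np.all(aa_block >= prev.table[:20, :20])
            assert np.all(c.table[:20, GAP_IDX] <= prev.table[:20, GAP_IDX])
            assert c.n_events == prev.n_events
        prev = c


def test_gap_cells_vanish_beyond_max_pair_distance():
    rng = np.random.default_rng(7)
    msta = random_msta(rng, n_structures=3, n_columns=8, gap_p=0.0)
    c = count_substitutions(msta, 1e6)
    assert c.n_distance_gap_events == 0
    assert c.table[:20, GAP_IDX].sum() == c.n_onesided_gap_events


def test_usage_errors():
    coords = np.zeros((2, 3))
    msta = build_msta({"a": "AG", "b": "AG"}, {"a": coords, "b": coords})
    with pytest.raises(CountsUsageError):
        count_substitutions(msta, -1.0)
    from foldsub.structio import GappedAlignment, MultiStructureAlignment
    single = MultiStructureAlignment(
        chains=(msta.chains[0],),
        alignment=GappedAlignment(ids=("a",), rows=("AG",)),
    )
    with pytest.raises(CountsUsageError):
        count_substitutions(single, 3.0)


def test_normalization_matches_worked_ratio():
    """C→R count divided by C-replaced-by-anything-but-R gives 0.5."""
    table = np.zeros((21, 21), dtype=np.int64)
    table[C, R] = table[R, C] = 2
    table[C, C] = 3
    table[C, GAP_IDX] = table[GAP_IDX, C] = 1
    nm = normalize_counts(_counts_from_table(table), symmetrize=False)
    assert nm.values[C, R] == pytest.approx(2 / (3 + 1))
    # the gap column follows the same rule: 1 / (2 + 3)
    assert nm.gap_row[C] == pytest.approx(1 / 5)


def test_normalization_of_zero_counts_is_zero():
    nm = normalize_counts(_counts_from_table(np.zeros((21, 21), dtype=np.int64)))
    assert not nm.values.any() and not nm.gap_row.any()


@pytest.mark.parametrize("seed", range(5))
def test_symmetrization_is_mean_of_raw_and_transpose(seed):
    rng = np.random.default_rng(seed)
    t = rng.integers(0, 20, size=(21, 21))
    table = np.triu(t) + np.triu(t, 1).T
    table[GAP_IDX, GAP_IDX] = 0
    counts = _counts_from_table(table)
    raw = normalize_counts(counts, symmetrize=False).values
    # independent recomputation of the raw ratio, then the symmetric mean
    expected_raw = np.zeros((20, 20))
    for a in range(20):
        for b in range(20):
            denom = table[a, :].sum() - table[a, b]
            expected_raw[a, b] = table[a, b] / denom if denom else 0.0
    np.testing.assert_allclose(raw, expected_raw)
    sym = normalize_counts(counts).values
    np.testing.assert_allclose(sym, (expected_raw + expected_raw.T) / 2)
    assert np.allclose(sym, sym.T)


def test_aggregate_sums_then_scales_to_unit_max():
    from foldsub.counts import NormalizedMatrix

    h1 = np.zeros((20, 20)); h1[A, A] = 0.5
    h2 = np.zeros((20, 20)); h2[A, A] = 0.5
    tm = aggregate_topology(
        [NormalizedMatrix(h1, np.zeros(20)), NormalizedMatrix(h2, np.zeros(20))],
        "1.10.10",
    )
    assert tm.values[A, A] == 1.0
    assert tm.n_homology_levels == 2

    L, I = AA20.index("L"), AA20.index("I")
    h3 = np.zeros((20, 20)); h3[L, I] = h3[I, L] = 0.25; h3[A, A] = 0.1
    tm2 = aggregate_topology([NormalizedMatrix(h3, np.full(20, 0.05))], "t")
    assert tm2.values[L, I] == 1.0
    assert tm2.values[A, A] == pytest.approx(0.4)
    np.testing.assert_allclose(tm2.gap_row, 0.05 / 0.25)


@pytest.mark.parametrize("seed", range(3))
def test_aggregate_proportional_to_elementwise_sum(seed):
    from foldsub.counts import NormalizedMatrix

    rng = np.random.default_rng(seed)
    hmats = [
        NormalizedMatrix(rng.random((20, 20)), rng.random(20)) for _ in range(3)
    ]
    tm = aggregate_topology(hmats, "t")
    total = sum(h.values for h in hmats)
    assert tm.values.max() == pytest.approx(1.0)
    np.testing.assert_allclose(tm.values, total / total.max())


def test_aggregate_empty_list_is_usage_error():
    with pytest.raises(CountsUsageError):
        aggregate_topology([], "t")


def test_aggregate_all_zero_stays_zero():
    from foldsub.counts import NormalizedMatrix

    tm = aggregate_topology([NormalizedMatrix(np.zeros((20, 20)), np.zeros(20))], "t")
    assert not tm.values.any()
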