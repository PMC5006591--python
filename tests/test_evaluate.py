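import numpy as np
import pytest

from foldsub.align import nw_score
from foldsub.combine import combine_matrices
from foldsub.counts import build_topology_matrix
from foldsub.evaluate import (
    EvaluateUsageError,
    PairEntry,
    PairSet,
    compute_zscore,
    evaluate_topology,
    percent_improvement,
    sweep_parameters,
    topology_scores,
)
from foldsub.fixtures import FamilySpec, make_benchmark, make_pairset
from foldsub.structio import MatrixFile


def test_zscore_hand_cases():
    assert compute_zscore(4, [1, 2, 3]) == pytest.approx(2.0)  # sample sd = 1
    assert compute_zscore(2, [1, 2, 3]) == pytest.approx(0.0)
    assert np.isnan(compute_zscore(6, [5, 5, 5]))
    with pytest.raises(EvaluateUsageError):
        compute_zscore(1, [1])


def test_percent_improvement_conventions():
    assert percent_improvement(1.5, 1.0) == pytest.approx(50.0)
    # negative baseline uses the absolute denominator
    assert percent_improvement(1.0, -0.1) == pytest.approx(1100.0)
    assert np.isnan(percent_improvement(1.0, 0.0))


@pytest.fixture(scope="module")
def small_pairset():
    specs = [FamilySpec(topology_id=f"1.10.{k}", seed=50 + k, length=60)
             for k in range(5)]
    return make_pairset(specs, divergence=0.6)


def test_zscore_invariant_under_affine_score_transform(small_pairset, blosum62):
    """Scaling matrix and gap penalties by k=100 leaves every z unchanged."""
    scaled = MatrixFile(name="B62x100", alphabet=blosum62.alphabet,
                        values=100 * blosum62.values)
    base = topology_scores(small_pairset, blosum62, 10, 1)
    big = topology_scores(small_pairset, scaled, 1000, 100)
    for topo in base:
        z0 = compute_zscore(base[topo][0], base[topo][1])
        z1 = compute_zscore(big[topo][0], big[topo][1])
        assert z1 == pytest.approx(z0, rel=1e-9)


def test_evaluate_matches_flat_loop_recomputation(small_pairset, blosum62):
    """Report z-scores equal an independent per-pair recomputation."""
    toy = MatrixFile(name="shifted", alphabet=blosum62.alphabet,
                     values=blosum62.values + 1)
    matrices = {"b62": blosum62, "shifted": toy}
    report = evaluate_topology(small_pairset, matrices)
    entries = small_pairset.entries
    for name, m in matrices.items():
        for i, e in enumerate(entries):
            similar = nw_score(e.seq_a, e.seq_b, m, 10, 1)
            cross = [nw_score(e.seq_a, o.seq_b, m, 10, 1)
                     for j, o in enumerate(entries) if j != i]
            z = (similar - np.mean(cross)) / np.std(cross, ddof=1)
            got = report.scores.query(
                "topology == @e.topology_id and matrix == @name"
            )["z"].item()
            assert got == pytest.approx(z)


def test_report_shape_and_cross_counts(small_pairset, blosum62):
    report = evaluate_topology(small_pairset, {"b62": blosum62})
    assert len(report.scores) == len(small_pairset) * 1
    scores = topology_scores(small_pairset, blosum62)
    for topo, (_, cross) in scores.items():
        assert len(cross) == len(small_pairset) - 1


def test_improved_flag_requires_beating_every_generic(small_pairset, blosum62):
    worse = MatrixFile(name="worse", alphabet=blosum62.alphabet,
                       values=blosum62.values)
    combined = {
        e.topology_id: {5.0: blosum62} for e in small_pairset.entries
    }
    report = evaluate_topology(small_pairset, {"b62": blosum62, "dup": worse},
                               combined)
    # combined == generic everywhere, so z_combined == z_generic: never improved
    assert not report.summary["improved"].any()
    assert (report.summary["pct_improvement"].abs() < 1e-9).all()


def test_sweep_weight_zero_ratio_is_one(blosum62):
    bundles, pairset = make_benchmark(n_topologies=3, families_per_topology=1,
                                      seed=11, length=50)
    result = sweep_parameters(bundles, pairset, cutoffs=[3.0], weights=[0.0],
                              anchor=blosum62)
    assert np.allclose(result.grid["z_ratio"], 1.0)
    assert result.errors.empty


def test_sweep_grid_matches_manual_single_runs(blosum62):
    bundles, pairset = make_benchmark(n_topologies=4, families_per_topology=1,
                                      seed=12, length=50)
    cutoffs, weights = [2.0, 4.0], [0.0, 5.0, 15.0]
    result = sweep_parameters(bundles, pairset, cutoffs, weights, blosum62)
    assert len(result.grid) == len(cutoffs) * len(weights)  # one class
    classes = pairset.classes()
    for _, row in result.grid.iterrows():
        zs = []
        for topo, mstas in bundles.items():
            tm = build_topology_matrix(mstas, topo, row["cutoff"])
            cm = combine_matrices(blosum62, tm, row["weight"])
            similar, cross = topology_scores(
                pairset, cm, only_topology=topo
            )[topo]
            zs.append(compute_zscore(similar, cross))
        assert row["mean_z_combined"] == pytest.approx(np.mean(zs), nan_ok=True)


def test_tight_cutoff_discards_true_correspondences_under_jitter():
    """With 0.5 Å superposition jitter a 1 Å cutoff rejects a large share
    of genuinely aligned residues that a 3 Å cutoff keeps."""
    from foldsub.counts import count_substitutions
    from foldsub.fixtures import FamilySpec, make_family

    kept = {}
    for cutoff in (1.0, 3.0):
        n_sub = n_ev = 0
        for seed in range(5):
            fam = make_family(FamilySpec(seed=400 + seed, length=120))
            c = count_substitutions(fam.msta, cutoff)
            n_sub += c.n_substitution_events
            n_ev += c.n_events
        kept[cutoff] = n_sub / n_ev
    # pairwise Cα distance under 0.5 Å jitter is ~0.71·chi(3): essentially
    # all mass below 3 Å, under half below 1 Å (indel columns dilute both)
    assert kept[3.0] > 0.9
    assert kept[1.0] < 0.5


def test_pairset_rejects_duplicates():
    e = PairEntry("t1", "mainly-alpha", "ACD", "ACD")
    with pytest.raises(EvaluateUsageError):
        PairSet(entries=(e, e))


def test_evaluate_requires_three_topologies(blosum62):
    e1 = PairEntry("t1", "mainly-alpha", "ACDEF", "ACDEF")
    e2 = PairEntry("t2", "mainly-alpha", "GHIKL", "GHIKL")
    with pytest.raises(EvaluateUsageError):
        evaluate_topology(PairSet(entries=(e1, e2)), {"b62": blosum62})
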