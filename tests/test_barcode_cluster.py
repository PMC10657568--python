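"""p-distances, objective (threshold) clustering and merge profiles."""

import numpy as np
import pytest

from cryptomorph import merge_profile, objective_cluster, p_distance_matrix
from cryptomorph.barcode_cluster import DistanceMatrix
from cryptomorph.io_formats import DatasetError, SequenceSet


def mutate(seq: str, positions, base_map) -> str:
    out = list(seq)
    for p in positions:
        out[p] = base_map.get(out[p], "A")
    return "".join(out)


FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


def test_crafted_pair_13_of_313(rng):
    base = "".join(rng.choice(list("ACGT"), 313))
    other = mutate(base, range(13), FLIP)
    dm = p_distance_matrix(SequenceSet(ids=["a", "b"], sequences=[base, other]))
    assert dm.matrix[0, 1] == pytest.approx(13 / 313, abs=1e-12)
    assert dm.comparable[0, 1] == 313
    assert dm.matrix[0, 0] == 0 and dm.matrix[1, 1] == 0


def test_ambiguous_sites_excluded_pairwise():
    a = "ACGTACGTAC"
    b = mutate(a, [0], FLIP)  # 1 difference in 10 sites
    b = b[:5] + "N" + b[6:]  # and one N column
    dm = p_distance_matrix(SequenceSet(ids=["a", "b"], sequences=[a, b]))
    assert dm.comparable[0, 1] == 9
    assert dm.matrix[0, 1] == pytest.approx(1 / 9)


def test_gaps_and_other_ambiguities_treated_as_missing():
    a = "ACGTACGTAC"
    b = "RC-TACGTAC"  # R and '-' both excluded
    dm = p_distance_matrix(SequenceSet(ids=["a", "b"], sequences=[a, b]))
    assert dm.comparable[0, 1] == 8
    assert dm.matrix[0, 1] == 0.0


def test_no_comparable_sites_flagged():
    dm = p_distance_matrix(SequenceSet(ids=["a", "b"], sequences=["NNNN", "ACGT"]))
    assert np.isnan(dm.matrix[0, 1])
    assert dm.has_missing


def test_matrix_symmetric_and_order_equivariant(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(6)]
    ids = [f"s{i}" for i in range(6)]
    dm = p_distance_matrix(SequenceSet(ids=ids, sequences=seqs))
    np.testing.assert_allclose(dm.matrix, dm.matrix.T)
    assert np.all(np.diag(dm.matrix) == 0)
    perm = [3, 1, 4, 0, 5, 2]
    dm2 = p_distance_matrix(
        SequenceSet(ids=[ids[i] for i in perm], sequences=[seqs[i] for i in perm])
    )
    np.testing.assert_allclose(dm2.matrix, dm.matrix[np.ix_(perm, perm)])


# --- clustering ------------------------------------------------------------

def simple_matrix(values, ids=None):
    n = len(values)
    return DistanceMatrix(
        ids=ids or [f"s{i}" for i in range(n)],
        matrix=np.asarray(values, float),
        comparable=np.full((n, n), 100),
    )


def test_threshold_extremes(rng):
    M = rng.random((5, 5)) * 0.2
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    dm = simple_matrix(M)
    assert objective_cluster(dm, 1.0).n_clusters == 1
    tiny = M[M > 0].min() / 2
    assert objective_cluster(dm, tiny).n_clusters == 5


def test_threshold_outside_range_raises():
    dm = simple_matrix(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        objective_cluster(dm, 1.5)


def test_clusters_nested_and_nonincreasing(rng):
    M = rng.random((12, 12))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    dm = simple_matrix(M)
    prev_n = None
    prev_assign = None
    for t in np.linspace(0.05, 0.95, 10):
        part = objective_cluster(dm, t)
        if prev_n is not None:
            assert part.n_clusters <= prev_n
            # refinement: members together at smaller t stay together
            for i in range(12):
                for j in range(12):
                    a, b = f"s{i}", f"s{j}"
                    if prev_assign[a] == prev_assign[b]:
                        assert part.assignment[a] == part.assignment[b]
        prev_n, prev_assign = part.n_clusters, part.assignment


def test_components_equal_transitive_closure_bruteforce(rng):
    for n in (5, 20, 50):
        M = rng.random((n, n)) * 0.3
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        dm = simple_matrix(M)
        t = 0.05
        part = objective_cluster(dm, t)
        # brute-force transitive closure of the threshold relation
        adj = (M <= t).astype(bool)
        reach = adj.copy()
        for _ in range(n):
            reach = reach | (reach @ adj)
        labels = part.labels(dm.ids)
        for i in range(n):
            for j in range(n):
                assert (labels[i] == labels[j]) == bool(reach[i, j])


def test_missing_distance_warns():
    M = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
    dm = simple_matrix(M)
    with pytest.warns(UserWarning, match="missing"):
        part = objective_cluster(dm, 0.15)
    assert part.n_clusters == 2  # s0-s1 join; s2 separate (nan edge ignored)


# --- merge profile ---------------------------------------------------------

def test_three_taxon_merge_heights():
    M = np.array([[0, 0.01, 0.10], [0.01, 0, 0.10], [0.10, 0.10, 0]])
    profile = merge_profile(simple_matrix(M, ids=["A", "B", "C"]))
    heights = profile.merge_heights()
    np.testing.assert_allclose(heights, [0.01, 0.10])
    assert profile.events[0][1] | profile.events[0][2] == {"A", "B"}


def naive_single_linkage(M):
    """O(n^3) repeated-minimum-search agglomeration (oracle)."""
    n = len(M)
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(M[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return np.array(heights)


def test_merge_profile_matches_bruteforce(rng):
    for n in (5, 12, 30):
        M = rng.random((n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        profile = merge_profile(simple_matrix(M))
        np.testing.assert_allclose(
            profile.merge_heights(), naive_single_linkage(M), atol=1e-12
        )


def test_cut_equals_objective_cluster(rng):
    M = rng.random((10, 10)) * 0.2
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    dm = simple_matrix(M)
    profile = merge_profile(dm)
    for t in (0.02, 0.05, 0.1, 0.18):
        a = profile.cut(t)
        b = objective_cluster(dm, t)
        assert a.n_clusters == b.n_clusters
        la, lb = a.labels(dm.ids), b.labels(dm.ids)
        assert ((la[:, None] == la[None, :]) == (lb[:, None] == lb[None, :])).all()


def test_newick_export_parseable(rng):
    import dendropy

    M = rng.random((6, 6)) * 0.2
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    profile = merge_profile(simple_matrix(M))
    tree = dendropy.Tree.get(data=profile.to_newick(), schema="newick")
    assert {t.label for t in tree.taxon_namespace} == set(profile.ids)


def test_merge_profile_contracts():
    with pytest.raises(DatasetError, match="2 sequences"):
        merge_profile(simple_matrix(np.zeros((1, 1))))
    M = np.array([[0, np.nan], [np.nan, 0]])
    with pytest.raises(DatasetError, match="complete"):
        merge_profile(simple_matrix(M))
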