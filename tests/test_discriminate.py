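"""CVA, jackknifed classification and pairwise PERMANOVA."""

from itertools import permutations

import numpy as np
import pytest

from cryptomorph import (
    between_group_pca,
    cva,
    jackknife_classify,
    pairwise_permanova,
)
from cryptomorph.discriminate import (
    _two_group_permanova,
    permanova_pseudo_f,
    pseudo_f_from_coords,
)
from cryptomorph.io_formats import DatasetError


def two_clusters(rng, n_per=15, d=4, sep=3.0):
    X = rng.standard_normal((2 * n_per, d))
    X[n_per:] += sep
    return X, np.repeat(["a", "b"], n_per)


def test_two_groups_cv1_explains_all(rng):
    X, groups = two_clusters(rng)
    fit = cva(X, groups, retain="all")
    assert fit.percent_variance[0] == pytest.approx(100.0)
    assert fit.eigenvalues.size == 1


def test_cva_equals_bgpca_under_identity_within_covariance(rng):
    """With whitened (identity) within-group covariance, CVA axes coincide
    with between-group PCA axes up to sign."""
    n_per, d = 20, 5
    groups = np.repeat(["a", "b", "c"], n_per)
    means = rng.standard_normal((3, d)) * 2
    resid = []
    for _ in range(3):
        E = rng.standard_normal((n_per, d))
        E -= E.mean(axis=0)
        # exact whitening of this group's residuals
        cov = E.T @ E / (n_per - 1)
        L = np.linalg.cholesky(np.linalg.inv(cov))
        resid.append(E @ L)
    X = np.vstack([m + e for m, e in zip(means, resid)])
    fit = cva(X, groups, retain="all")
    pca = between_group_pca(X, groups)
    for j in range(min(fit.axes.shape[1], pca.axes.shape[1])):
        a = fit.axes[:, j] / np.linalg.norm(fit.axes[:, j])
        b = pca.axes[:, j]
        assert abs(a @ b) == pytest.approx(1.0, abs=1e-6)


def test_retention_guard_reports_singularity(rng):
    X = rng.standard_normal((10, 3))
    X = np.hstack([X, X])  # duplicated columns: singular within covariance
    groups = np.repeat(["a", "b"], 5)
    with pytest.raises(DatasetError, match="retain"):
        cva(X, groups, retain="all")


def test_jackknife_perfect_separation(rng):
    X, groups = two_clusters(rng, sep=10.0)
    cm = jackknife_classify(X, groups)
    assert cm.accuracy == 100.0
    assert cm.counts.sum() == len(X)


def test_confusion_matrix_row_sums_and_accuracy(rng):
    X, groups = two_clusters(rng, sep=1.0)
    cm = jackknife_classify(X, groups)
    for gi, lv in enumerate(cm.groups):
        assert cm.counts[gi].sum() == np.sum(groups == lv)
    assert cm.accuracy == pytest.approx(
        100.0 * np.trace(cm.counts) / cm.counts.sum()
    )


def test_jackknife_chance_level_under_null():
    """Random labels among g equal groups: accuracy ~ 100/g percent."""
    g, n_per, n_sim = 2, 10, 200
    rng = np.random.default_rng(99)
    accs = []
    for _ in range(n_sim):
        X = rng.standard_normal((g * n_per, 3))
        groups = rng.permutation(np.repeat([f"g{i}" for i in range(g)], n_per))
        accs.append(jackknife_classify(X, groups, retain="all").accuracy)
    assert abs(np.mean(accs) - 100.0 / g) < 5.0


def test_singleton_group_raises(rng):
    X = rng.standard_normal((5, 2))
    with pytest.raises(DatasetError, match="size 1"):
        jackknife_classify(X, np.array(["a", "a", "a", "a", "b"]))


# --- PERMANOVA -------------------------------------------------------------

def test_gower_identity(rng):
    """Pseudo-F from the distance matrix equals the coordinate form."""
    X = rng.standard_normal((24, 5))
    codes = np.repeat([0, 1, 2], 8)
    d = X[:, None] - X[None, :]
    D2 = np.einsum("ijk,ijk->ij", d, d)
    f_dist = permanova_pseudo_f(D2, codes)
    f_coord = pseudo_f_from_coords(X, codes)
    assert f_dist == pytest.approx(f_coord, abs=1e-8)


def test_exhaustive_permutation_oracle(rng):
    """n=6: sampled permutation p agrees with exhaustive enumeration."""
    X = rng.standard_normal((6, 2))
    X[3:] += 1.0
    groups = np.repeat(["a", "b"], 3)
    codes = np.repeat([0, 1], 3)
    d = X[:, None] - X[None, :]
    D2 = np.einsum("ijk,ijk->ij", d, d)
    F_obs = permanova_pseudo_f(D2, codes)
    perms = list(permutations(range(6)))
    F_all = np.array([permanova_pseudo_f(D2[np.ix_(p, p)], codes) for p in perms])
    p_exact = np.mean(F_all >= F_obs - 1e-12)
    _, p_sampled = _two_group_permanova(
        X[:3], X[3:], 9999, np.random.default_rng(0)
    )
    # sampled p converges to the exhaustive value within Monte-Carlo error
    se = np.sqrt(p_exact * (1 - p_exact) / 9999)
    assert abs(p_sampled - p_exact) < 4 * se + 2e-4


def test_pairwise_table_invariants(rng):
    X = rng.standard_normal((30, 4))
    groups = np.repeat(["a", "b", "c"], 10)
    X[10:20] += 1.5
    tests = pairwise_permanova(X, groups, n_perm=199, seed=3)
    F = tests.f_values
    assert (F.values.T == F.values).all()
    assert (np.diag(F.values) == 0).all()
    up = np.triu_indices(3, 1)
    assert np.all(tests.p_corrected.values[up] >= tests.p_raw.values[up] - 1e-15)
    assert np.all(tests.p_corrected.values[up] <= 1.0)


def test_permanova_seed_reproducible(rng):
    X = rng.standard_normal((20, 3))
    groups = np.repeat(["a", "b"], 10)
    p1 = pairwise_permanova(X, groups, n_perm=199, seed=11).p_raw.iloc[0, 1]
    p2 = pairwise_permanova(X, groups, n_perm=199, seed=11).p_raw.iloc[0, 1]
    assert p1 == p2
    p3 = pairwise_permanova(X, groups, n_perm=199, seed=12).p_raw.iloc[0, 1]
    assert abs(p3 - p1) < 0.2  # different seeds: binomial-scale wobble only


def test_permanova_input_contracts(rng):
    X = rng.standard_normal((10, 2))
    groups = np.repeat(["a", "b"], 5)
    with pytest.raises(ValueError, match="99"):
        pairwise_permanova(X, groups, n_perm=10)
    with pytest.raises(DatasetError, match="2 members"):
        pairwise_permanova(X, np.array(["a"] * 9 + ["b"]), n_perm=199)
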