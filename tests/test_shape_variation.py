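"""Procrustes ANOVA, relative warps and between-group PCA."""

import numpy as np
import pytest

from cryptomorph import (
    between_group_pca,
    gpa,
    procrustes_anova,
    relative_warps,
    simulate_shapes,
)
from cryptomorph.io_formats import DatasetError
from conftest import hexagon_spec


def test_planted_species_effect_dominates():
    """Mean-shape offset >> noise: species explains most SS, p at floor."""
    spec = hexagon_spec(species_effect_scale=0.1, sigma=0.01, n_specimens=10, seed=21)
    aligned = gpa(simulate_shapes(spec))
    table = procrustes_anova(aligned, factors=["species"], n_perm=999, seed=0)
    assert table.percent("species") > 50
    assert table.p_value("species") <= 0.001


def test_anova_table_invariants(small_aligned):
    table = procrustes_anova(
        small_aligned, factors=["species", "site", "replicate_id"], n_perm=99, seed=0
    ).table
    factors = table.drop(index="Total")
    assert factors["ss"].sum() == pytest.approx(table.loc["Total", "ss"], rel=1e-6)
    assert factors["percent_ss"].sum() == pytest.approx(100.0, abs=1e-6)
    ps = factors.drop(index="Residual")["p"]
    assert ((ps > 0) & (ps <= 1)).all()


def test_anova_seed_reproducible(small_aligned):
    a = procrustes_anova(small_aligned, factors=["species"], n_perm=199, seed=5).table
    b = procrustes_anova(small_aligned, factors=["species"], n_perm=199, seed=5).table
    assert (a["p"].dropna() == b["p"].dropna()).all()


def test_species_percent_monotone_in_effect_size():
    """Species %SS is non-decreasing in effect scale s in {0, .5, 1, 2} x sigma."""
    sigma = 0.01
    percents = []
    for mult in (0.0, 0.5, 1.0, 2.0):
        spec = hexagon_spec(
            species_effect_scale=mult * sigma, sigma=sigma, n_specimens=15, seed=31
        )
        aligned = gpa(simulate_shapes(spec))
        table = procrustes_anova(aligned, factors=["species"], n_perm=99, seed=0)
        percents.append(table.percent("species"))
    assert all(b >= a - 1e-9 for a, b in zip(percents, percents[1:]))


def test_constant_factor_raises(small_aligned):
    labels = small_aligned.labels.copy()
    labels["species"] = "same"
    aligned = small_aligned
    old = aligned.labels
    aligned.labels = labels
    try:
        with pytest.raises(DatasetError, match="constant"):
            procrustes_anova(aligned, factors=["species"], n_perm=99, seed=0)
    finally:
        aligned.labels = old


# --- relative warps --------------------------------------------------------

def test_warp_eigenvalue_sum_is_total_variance(small_aligned):
    warps = relative_warps(small_aligned)
    X = small_aligned.flat()
    total = np.sum(np.var(X, axis=0, ddof=1))
    assert warps.eigenvalues.sum() == pytest.approx(total, rel=1e-8)
    assert warps.percent_variance.sum() == pytest.approx(100.0, abs=1e-8)
    assert np.all(np.diff(warps.eigenvalues) <= 1e-12)


def test_warp_scores_isometric_to_tangent_space(small_aligned):
    warps = relative_warps(small_aligned)
    X = small_aligned.flat()
    d_scores = np.linalg.norm(
        warps.scores[:, None] - warps.scores[None, :], axis=2
    )
    d_tangent = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    np.testing.assert_allclose(d_scores, d_tangent, atol=1e-8)


def test_warp_rank_bounds():
    spec = hexagon_spec(n_species=1, n_specimens=2, n_replicates=2, seed=41)
    ds = simulate_shapes(spec)
    sub = gpa(ds.coords()[:3])
    warps = relative_warps(sub)
    assert warps.m <= 2  # n - 1
    aligned = gpa(ds)
    k = aligned.k
    assert relative_warps(aligned).m <= min(aligned.n - 1, 2 * k - 4)


def test_warp_spectrum_rotation_invariant(small_aligned, rng):
    """Rotating the tangent data in score space leaves eigenvalues unchanged."""
    warps = relative_warps(small_aligned)
    X = small_aligned.flat()
    d = X.shape[1]
    M = rng.standard_normal((d, d))
    Q, _ = np.linalg.qr(M)
    rotated = small_aligned
    old_coords = rotated.coords
    rotated.coords = (X @ Q).reshape(small_aligned.n, -1, 2)
    try:
        spun = relative_warps(rotated)
    finally:
        rotated.coords = old_coords
    np.testing.assert_allclose(spun.eigenvalues, warps.eigenvalues, atol=1e-10)


def test_relative_warps_needs_three(small_aligned):
    sub = gpa(np.stack([np.eye(3, 2), np.eye(3, 2) * 2]))
    with pytest.raises(DatasetError):
        relative_warps(sub)


# --- between-group PCA -----------------------------------------------------

def test_two_groups_single_axis_along_mean_difference(rng):
    X = rng.standard_normal((30, 6))
    groups = np.repeat(["a", "b"], 15)
    X[15:] += np.array([1, 2, 0, 0, -1, 3]) * 0.5
    pca = between_group_pca(X, groups)
    assert pca.axes.shape[1] == 1
    diff = X[15:].mean(axis=0) - X[:15].mean(axis=0)
    cosine = abs(diff @ pca.axes[:, 0]) / np.linalg.norm(diff)
    assert cosine == pytest.approx(1.0, abs=1e-10)


def test_identical_group_means_zero_eigenvalues(rng):
    base = rng.standard_normal((10, 4))
    X = np.vstack([base, base])  # same mean by construction
    groups = np.repeat(["a", "b"], 10)
    pca = between_group_pca(X, groups)
    assert pca.eigenvalues.size == 0


def test_axis_count_and_group_mean_projection(rng):
    X = rng.standard_normal((40, 8))
    groups = np.repeat(list("abcd"), 10)
    X += np.repeat(rng.standard_normal((4, 8)), 10, axis=0)
    pca = between_group_pca(X, groups)
    assert pca.axes.shape[1] <= 3
    # projecting the group means reproduces their score-space positions
    for gi, lv in enumerate(pca.groups):
        mean_scores = pca.scores[groups == lv].mean(axis=0)
        np.testing.assert_allclose(mean_scores, pca.group_means[gi], atol=1e-10)


def test_single_group_raises(rng):
    with pytest.raises(DatasetError):
        between_group_pca(rng.standard_normal((5, 3)), np.repeat("a", 5))
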