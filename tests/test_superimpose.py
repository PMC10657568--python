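"""GPA, semilandmark sliding and the tangent-space approximation check."""

import numpy as np
import pytest

from cryptomorph import (
    SlidersSpec,
    centroid_size,
    fit_tps,
    gpa,
    head_like_sliders,
    head_like_template,
    simulate_shapes,
    slide_semilandmarks,
    tangent_check,
)
from cryptomorph.io_formats import DatasetError
from cryptomorph.superimpose import _optimal_rotation, _through_origin_regression
from conftest import hexagon_spec

TRIANGLE = np.array([(0.0, 0.0), (2.0, 0.0), (0.5, 1.5)])


def rigid(pts, theta, scale, t):
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return scale * pts @ R.T + t


def test_centroid_size_unit_square():
    square = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float)
    assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)


def test_centroid_size_homogeneous(rng):
    pts = rng.random((7, 2))
    c = rng.uniform(0.1, 5)
    assert centroid_size(c * pts) == pytest.approx(c * centroid_size(pts), rel=1e-12)


def test_centroid_size_degenerate_zero():
    assert centroid_size(np.ones((4, 2))) == 0.0


def test_copies_of_one_shape_align_exactly(rng):
    configs = np.stack(
        [
            rigid(TRIANGLE, rng.uniform(0, 2 * np.pi), rng.uniform(0.5, 2), rng.normal(size=2))
            for _ in range(6)
        ]
    )
    aligned = gpa(configs)
    for i in range(6):
        np.testing.assert_allclose(aligned.coords[i], aligned.consensus, atol=1e-9)
    flat = aligned.flat()
    d = np.linalg.norm(flat[:, None] - flat[None, :], axis=2)
    assert d.max() < 1e-9


def test_aligned_preshapes_centered_unit_size(rng):
    two = np.stack([TRIANGLE, TRIANGLE + rng.normal(scale=0.1, size=TRIANGLE.shape)])
    aligned = gpa(two)
    for shape in aligned.preshapes:
        np.testing.assert_allclose(shape.mean(axis=0), 0, atol=1e-9)
        assert centroid_size(shape) == pytest.approx(1.0, abs=1e-9)


def test_optimal_rotation_matches_grid_search(rng):
    """Closed-form rotation vs brute-force search over a 0.001-rad grid."""
    for _ in range(10):
        A = rng.random((6, 2)) - 0.5
        B = rng.random((6, 2)) - 0.5
        A -= A.mean(0)
        B -= B.mean(0)
        R = _optimal_rotation(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        thetas = np.arange(0, 2 * np.pi, 0.001)
        cos, sin = np.cos(thetas), np.sin(thetas)
        # ||A R(theta) - B||^2 minimized over the grid
        costs = np.einsum("kj,kj->", A, A) + np.einsum("kj,kj->", B, B) - 2 * (
            cos * (A * B).sum() + sin * (A[:, 0] * B[:, 1] - A[:, 1] * B[:, 0]).sum()
        )
        best = thetas[np.argmin(costs)]
        theta_closed = np.arctan2(R[0, 1], R[0, 0])
        diff = np.angle(np.exp(1j * (best - theta_closed)))
        assert abs(diff) < 0.001


def test_gpa_invariant_to_nuisance_transforms(rng):
    spec = hexagon_spec(n_specimens=5, seed=3)
    ds = simulate_shapes(spec)
    base = gpa(ds.coords())
    perturbed = ds.coords().copy()
    for i in range(perturbed.shape[0]):
        perturbed[i] = rigid(
            perturbed[i], rng.uniform(0, 2 * np.pi), rng.uniform(0.5, 2), rng.normal(size=2)
        )
    again = gpa(perturbed)
    np.testing.assert_allclose(again.coords, base.coords, atol=1e-8)


def test_gpa_consensus_is_fixed_point(rng):
    ds = simulate_shapes(hexagon_spec(n_specimens=5, seed=4))
    first = gpa(ds.coords())
    second = gpa(first.preshapes)
    np.testing.assert_allclose(second.coords, first.coords, atol=1e-8)
    np.testing.assert_allclose(second.consensus, first.consensus, atol=1e-8)
    np.testing.assert_allclose(first.coords.mean(axis=0), first.consensus, atol=1e-9)


def test_rotation_local_optimality(rng):
    """No single configuration improves by a small extra rotation."""
    ds = simulate_shapes(hexagon_spec(n_specimens=4, seed=5))
    aligned = gpa(ds.coords())
    c = aligned.consensus
    for i in range(0, aligned.n, 5):
        base = np.sum((aligned.preshapes[i] - c) ** 2)
        for dtheta in (-0.01, 0.01):
            R = np.array(
                [[np.cos(dtheta), -np.sin(dtheta)], [np.sin(dtheta), np.cos(dtheta)]]
            )
            assert np.sum((aligned.preshapes[i] @ R.T - c) ** 2) >= base - 1e-12


def test_degenerate_configuration_named():
    bad = np.stack([TRIANGLE, np.zeros((3, 2))])
    with pytest.raises(DatasetError, match="1"):
        gpa(bad)


# --- sliding ---------------------------------------------------------------

def test_empty_sliders_identity(rng):
    ds = simulate_shapes(hexagon_spec(n_specimens=4, seed=6))
    aligned = gpa(ds.coords())
    out = slide_semilandmarks(aligned, SlidersSpec([]))
    assert out is aligned


def test_sliding_reduces_bending_energy():
    spec = hexagon_spec(
        template=head_like_template(), n_specimens=4, sigma=0.01, seed=8
    )
    ds = simulate_shapes(spec)
    aligned = gpa(ds.coords())
    sliders = head_like_sliders()
    slid = slide_semilandmarks(aligned, sliders, mode="bending_energy", resuperimpose=False)
    for i in range(aligned.n):
        before = fit_tps(aligned.consensus, aligned.preshapes[i]).bending_energy
        after = fit_tps(aligned.consensus, slid.coords[i]).bending_energy
        assert after <= before + 1e-12


def test_sliding_fixed_point():
    """Semilandmarks already optimal (shapes equal consensus) do not move."""
    template = head_like_template()
    copies = np.stack([template] * 3 + [template * 2.0])
    aligned = gpa(copies)
    sliders = head_like_sliders()
    out = slide_semilandmarks(aligned, sliders, resuperimpose=False)
    np.testing.assert_allclose(out.coords, aligned.preshapes, atol=1e-8)


def test_unknown_sliding_mode_raises():
    aligned = gpa(simulate_shapes(hexagon_spec(n_specimens=3, seed=1)).coords())
    triplet = SlidersSpec([(1, 2, 3)])
    with pytest.raises(ValueError, match="mode"):
        slide_semilandmarks(aligned, triplet, mode="nope")


# --- tangent check ---------------------------------------------------------

def test_tangent_check_small_variation(rng):
    spec = hexagon_spec(n_specimens=20, sigma=1e-3, sigma_rep=0.0, seed=11)
    aligned = gpa(simulate_shapes(spec).coords())
    tc = tangent_check(aligned)
    assert 0.999 <= tc.slope <= 1.0
    assert tc.correlation > 0.9999


def test_through_origin_regression_identity():
    x = np.array([0.1, 0.2, 0.3])
    tc = _through_origin_regression(x, x)
    assert tc.slope == pytest.approx(1.0)
    assert tc.correlation == pytest.approx(1.0)


def test_tangent_check_zero_variation_raises():
    copies = np.stack([TRIANGLE] * 4)
    aligned = gpa(copies)
    with pytest.raises(DatasetError, match="variation"):
        tangent_check(aligned)
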