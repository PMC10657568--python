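"""Thin-plate spline (TPS) interpolation, bending energy and deformation grids.

The TPS is the unique minimum-bending interpolant mapping a reference
landmark configuration onto a target.  With the kernel convention
``U(r) = r^2 log r^2`` (Bookstein), the map decomposes into an affine part
and a non-affine part whose coefficients solve the bordered kernel system

    [ K  Q ] [ W ]   [ v ]
    [ Q' 0 ] [ A ] = [ 0 ]

where ``K_ij = U(|p_i - p_j|)`` and ``Q = [1 x y]``.  The bending energy
``tr(W' K W)`` is the quadratic-form magnitude of non-affine deformation;
the determinant of the map's Jacobian is the local area expansion factor
(``> 1`` expansion, ``< 1`` contraction) used to colour deformation grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve

__all__ = [
    "TpsWarp",
    "DeformationGrid",
    "fit_tps",
    "bending_energy",
    "bending_energy_matrix",
    "warp_points",
    "jacobian_grid",
]


def _kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2, with the removable singularity U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _pairwise_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


@dataclass
class TpsWarp:
    """A fitted 2-D thin-plate spline warp from ``reference`` to ``target``."""

    reference: np.ndarray  # (k, 2)
    target: np.ndarray  # (k, 2)
    affine: np.ndarray  # (3, 2): rows constant, x, y; columns output coords
    weights: np.ndarray  # (k, 2) non-affine coefficients
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return warp_points(self, points)


@dataclass
class DeformationGrid:
    """Jacobian expansion factors of a warp sampled at grid cell centers."""

    x: np.ndarray  # (nx,) cell-center x coordinates
    y: np.ndarray  # (ny,) cell-center y coordinates
    jacobian: np.ndarray  # (ny, nx) det J at each cell center


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """The k x k bending-energy matrix of a reference configuration.

    This is the upper-left block of the inverse bordered system; for any
    target ``v`` (per coordinate), the bending energy is ``v' B v``.
    Used by the semilandmark sliding step and by CVA-free warp algebra.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    L = _bordered_system(ref)
    Linv = np.linalg.inv(L)
    Be = Linv[:k, :k]
    return (Be + Be.T) / 2.0


def _bordered_system(ref: np.ndarray) -> np.ndarray:
    k = ref.shape[0]
    K = _kernel(_pairwise_sq(ref, ref))
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    return L


def fit_tps(reference: np.ndarray, target: np.ndarray) -> TpsWarp:
    """Fit the TPS interpolant carrying ``reference`` landmarks onto ``target``.

    Raises ``np.linalg.LinAlgError`` for collinear or duplicated reference
    landmarks (singular bordered system).
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("reference and target must both be (k, 2)")
    k = ref.shape[0]
    if k < 3:
        raise ValueError("TPS needs k >= 3 landmarks")
    L = _bordered_system(ref)
    # detect collinear/duplicate references before solving
    if np.linalg.matrix_rank(L) < k + 3:
        raise np.linalg.LinAlgError(
            "singular TPS system: reference landmarks collinear or duplicated"
        )
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    params = solve(L, rhs)
    W = params[:k]
    A = params[k:]
    K = L[:k, :k]
    be = float(np.einsum("id,ij,jd->", W, K, W))
    be = max(be, 0.0)  # clip away negative round-off
    return TpsWarp(reference=ref, target=tgt, affine=A, weights=W, bending_energy=be)


def bending_energy(warp: TpsWarp) -> float:
    """Bending energy ``tr(W' K W)`` of a fitted warp (0 iff affine)."""
    return warp.bending_energy


def warp_points(warp: TpsWarp, points: np.ndarray) -> np.ndarray:
    """Evaluate the warp at arbitrary points ((m, 2) -> (m, 2))."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    U = _kernel(_pairwise_sq(pts, warp.reference))  # (m, k)
    Q = np.column_stack([np.ones(len(pts)), pts])  # (m, 3)
    return Q @ warp.affine + U @ warp.weights


def warp_jacobian(warp: TpsWarp, points: np.ndarray) -> np.ndarray:
    """Analytic Jacobian matrices of the warp at each point ((m, 2, 2)).

    ``J[m][i][j] = d f_i / d x_j``.  The kernel gradient is
    ``grad U = 2 (p - c) (log r^2 + 1)``, which vanishes as r -> 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts[:, None, :] - warp.reference[None, :, :]  # (m, k, 2)
    r2 = np.einsum("mkj,mkj->mk", d, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.log(r2) + 1.0
    g = np.where(r2 > 0, g, 0.0)
    # dU/dx_j at point m for center k: 2 * d[m,k,j] * g[m,k]
    gradU = 2.0 * d * g[:, :, None]  # (m, k, 2)
    J = np.einsum("kd,mkj->mdj", warp.weights, gradU)  # (m, 2out, 2in)
    J += warp.affine[1:].T[None, :, :]  # affine rows x,y give dA_d/dx_j
    return J


def jacobian_grid(
    warp: TpsWarp,
    resolution: tuple[int, int] = (24, 24),
    bbox: tuple[float, float, float, float] | None = None,
) -> DeformationGrid:
    """Sample det(J) of the warp at the cell centers of a regular grid.

    ``bbox`` is (xmin, xmax, ymin, ymax); by default the reference's bounding
    box padded by 5%.  Values > 1 mark local expansion, < 1 contraction; the
    identity warp gives exactly 1 everywhere.
    """
    nx, ny = resolution
    if nx < 2 or ny < 2:
        raise ValueError("grid resolution must be at least 2 x 2")
    if bbox is None:
        mins = warp.reference.min(axis=0)
        maxs = warp.reference.max(axis=0)
        pad = 0.05 * (maxs - mins)
        bbox = (mins[0] - pad[0], maxs[0] + pad[0], mins[1] - pad[1], maxs[1] + pad[1])
    xmin, xmax, ymin, ymax = bbox
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounding box {bbox}")
    dx = (xmax - xmin) / nx
    dy = (ymax - ymin) / ny
    xc = xmin + dx * (np.arange(nx) + 0.5)
    yc = ymin + dy * (np.arange(ny) + 0.5)
    XX, YY = np.meshgrid(xc, yc)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    J = warp_jacobian(warp, pts)
    detJ = np.linalg.det(J).reshape(ny, nx)
    if not np.all(np.isfinite(detJ)):
        raise FloatingPointError("non-finite Jacobian determinant on grid")
    return DeformationGrid(x=xc, y=yc, jacobian=detJ)
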