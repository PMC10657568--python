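"""Generalized Procrustes analysis (GPA) with sliding semilandmarks.

GPA iteratively translates, scales and rotates a sample of landmark
configurations onto their evolving consensus, removing position,
orientation and size.  Rotation uses the closed-form 2-D orthogonal
Procrustes solution with the determinant constrained to +1 (reflections are
disallowed: left/right identity is biologically meaningful).

Semilandmarks — points along outlines whose exact position on the curve is
arbitrary — are optionally slid along the chord between their declared
neighbours so that their spacing contributes minimally to apparent shape
differences, under either the bending-energy criterion (default, the
classic relative-warps behaviour) or the Procrustes-distance criterion.

After convergence, configurations are orthogonally projected onto the
linear tangent space at the consensus; all downstream variance analyses
consume tangent coordinates.  :func:`tangent_check` quantifies how well the
tangent plane approximates shape space (regression of tangent on Procrustes
distance; slopes near 1 mean the approximation is safe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DatasetError, ShapeDataset, SlidersSpec, LandmarkConfiguration
from .tps_warp import bending_energy_matrix

__all__ = [
    "AlignedDataset",
    "TangentCheck",
    "centroid_size",
    "gpa",
    "slide_semilandmarks",
    "tangent_check",
]


def centroid_size(config: "LandmarkConfiguration | np.ndarray") -> float:
    """Centroid size: sqrt of summed squared distances of points to centroid.

    The size standard removed by Procrustes scaling; scales linearly with
    the configuration.  All-coincident points return 0.
    """
    pts = config.points if hasattr(config, "points") else np.asarray(config, float)
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


@dataclass
class AlignedDataset:
    """Procrustes-aligned coordinates and bookkeeping from a GPA run."""

    coords: np.ndarray  # (n, k, 2) aligned (optionally tangent-projected)
    centroid_sizes: np.ndarray  # (n,) original centroid sizes
    consensus: np.ndarray  # (k, 2) mean shape (unit centroid size)
    n_iterations: int
    converged_delta: float
    converged: bool = True
    tangent_projected: bool = True
    preshapes: np.ndarray | None = None  # (n, k, 2) pre-projection unit shapes
    ids: list[str] = field(default_factory=list)
    labels: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        """(n, 2k) row-major flattened coordinates."""
        return self.coords.reshape(self.n, -1)

    def label_vector(self, column: str) -> np.ndarray:
        if self.labels is None:
            raise DatasetError("aligned dataset carries no label table")
        return self.labels.loc[self.ids, column].to_numpy()


@dataclass
class TangentCheck:
    """Through-origin regression of tangent on Procrustes distances."""

    slope: float
    correlation: float


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||A R - B||_F for (k, 2) matrices."""
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def _orientation_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation putting the first off-center consensus landmark on +x."""
    radii = np.linalg.norm(consensus, axis=1)
    idx = np.flatnonzero(radii > 1e-6 * radii.max())
    j = int(idx[0]) if idx.size else 0
    phi = -np.arctan2(consensus[j, 1], consensus[j, 0])
    c, s = np.cos(phi), np.sin(phi)
    # for row vectors p, p @ R rotates by phi
    return np.array([[c, s], [-s, c]])


def _preshape(pts: np.ndarray, name: str = "") -> tuple[np.ndarray, float]:
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size <= 0 or not np.isfinite(size):
        raise DatasetError(f"degenerate configuration {name!r}: zero centroid size")
    return centered / size, size


def gpa(
    dataset: "ShapeDataset | np.ndarray",
    sliders: SlidersSpec | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    project_to_tangent: bool = True,
    slide_mode: str = "bending_energy",
    n_slide_iterations: int = 3,
) -> AlignedDataset:
    """Generalized Procrustes superimposition of a sample of configurations.

    Each iteration centers and unit-scales every configuration, rotates it
    onto the current consensus, optionally performs one semilandmark sliding
    pass, and recomputes the consensus; iteration stops when the RMS
    consensus change drops below ``tol``.  Sliding happens during the first
    ``n_slide_iterations`` iterations only — the sliding criterion leaves
    along-chord drift unpenalized, so alternating sliding with consensus
    updates indefinitely need not settle; a few passes followed by plain
    GPA is the conventional remedy.  Non-convergence after ``max_iter``
    returns a result flagged ``converged=False`` with a warning.
    """
    if isinstance(dataset, ShapeDataset):
        raw = dataset.coords()
        ids = dataset.ids
        labels = dataset.labels
    else:
        raw = np.asarray(dataset, dtype=float)
        ids = [str(i) for i in range(raw.shape[0])]
        labels = None
    n, k = raw.shape[0], raw.shape[1]
    if n < 2:
        raise DatasetError("GPA needs at least 2 configurations")
    if sliders is not None:
        sliders.validate(k)
        if len(sliders) == 0:
            sliders = None

    shapes = np.empty_like(raw)
    sizes = np.empty(n)
    for i in range(n):
        shapes[i], sizes[i] = _preshape(raw[i], ids[i])

    # initial consensus: first shape (any choice; iteration removes it)
    consensus = shapes[0].copy()
    n_it = 0
    delta = np.inf
    for n_it in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        if sliders is not None and n_it <= n_slide_iterations:
            _slide_inplace(shapes, consensus, sliders, slide_mode)
            for i in range(n):
                shapes[i], _ = _preshape(shapes[i], ids[i])
                shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus, _ = _preshape(new_consensus, "<consensus>")
        delta = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if delta < tol:
            break
    converged = delta < tol
    if not converged:
        warnings.warn(
            f"GPA did not converge after {max_iter} iterations (delta={delta:.3g})",
            stacklevel=2,
        )

    # polish: rotation-only fixed-point iterations so the stored consensus
    # matches the mean of the aligned shapes to near machine precision
    for _ in range(30):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus, _ = _preshape(shapes.mean(axis=0), "<consensus>")
        d = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if d < 1e-14:
            break
    for i in range(n):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)

    # canonical orientation: GPA determines the solution only up to one
    # global rotation, so rotate everything to put the consensus' first
    # off-center landmark on the +x axis; output is then invariant to
    # nuisance transforms of the inputs
    R = _orientation_rotation(consensus)
    consensus = consensus @ R
    shapes = shapes @ R

    preshapes = shapes.copy()
    if project_to_tangent:
        flat = shapes.reshape(n, -1)
        c = consensus.ravel()
        c = c / np.linalg.norm(c)
        proj = flat - (flat @ c)[:, None] * c[None, :] + c[None, :]
        coords = proj.reshape(n, k, 2)
        out_consensus = consensus
    else:
        coords = shapes
        out_consensus = consensus

    return AlignedDataset(
        coords=coords,
        centroid_sizes=sizes,
        consensus=out_consensus,
        n_iterations=n_it,
        converged_delta=delta,
        converged=converged,
        tangent_projected=project_to_tangent,
        preshapes=preshapes,
        ids=list(ids),
        labels=labels,
    )


def _slide_inplace(
    shapes: np.ndarray,
    consensus: np.ndarray,
    sliders: SlidersSpec,
    mode: str,
) -> None:
    """One sliding pass: move each semilandmark along its neighbour chord.

    Displacements minimize either the bending energy of the deformation
    from the consensus (``bending_energy``) or the squared Procrustes
    distance to the consensus (``procrustes_distance``).
    """
    if mode not in ("bending_energy", "procrustes_distance"):
        raise ValueError(f"unknown sliding mode {mode!r}")
    n, k, _ = shapes.shape
    nbrs = sliders.neighbours0()
    slid = sorted(nbrs)
    s = len(slid)
    if mode == "bending_energy":
        Be = bending_energy_matrix(consensus)
        E = np.kron(np.eye(2), Be)  # stacked [x; y] block metric
    else:
        E = np.eye(2 * k)
    for i in range(n):
        y = shapes[i]
        # unit tangent per slider from the configuration's own neighbour chord
        U = np.zeros((2 * k, s))
        for col, j in enumerate(slid):
            b, a = nbrs[j]
            t = y[a] - y[b]
            norm = np.linalg.norm(t)
            if norm <= 0:
                continue
            t = t / norm
            U[j, col] = t[0]
            U[k + j, col] = t[1]
        v = np.concatenate([y[:, 0] - consensus[:, 0], y[:, 1] - consensus[:, 1]])
        M = U.T @ E @ U
        rhs = -U.T @ (E @ v)
        t_opt, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        disp = U @ t_opt
        y[:, 0] += disp[:k]
        y[:, 1] += disp[k:]


def slide_semilandmarks(
    aligned: AlignedDataset,
    sliders: SlidersSpec,
    mode: str = "bending_energy",
    resuperimpose: bool = True,
) -> AlignedDataset:
    """Slide semilandmarks of an aligned dataset and re-superimpose.

    With an empty slider spec the dataset is returned unchanged.  Sliding in
    ``bending_energy`` mode never increases a configuration's bending energy
    against the consensus.  ``resuperimpose=False`` returns the raw slid
    shapes against the unchanged consensus (useful for inspecting the
    sliding step in isolation).
    """
    if len(sliders) == 0:
        return aligned
    sliders.validate(aligned.k)
    base = aligned.preshapes if aligned.preshapes is not None else aligned.coords
    shapes = base.copy()
    _slide_inplace(shapes, aligned.consensus, sliders, mode)
    if not resuperimpose:
        return AlignedDataset(
            coords=shapes.copy(),
            centroid_sizes=aligned.centroid_sizes,
            consensus=aligned.consensus,
            n_iterations=aligned.n_iterations,
            converged_delta=aligned.converged_delta,
            converged=aligned.converged,
            tangent_projected=False,
            preshapes=shapes,
            ids=aligned.ids,
            labels=aligned.labels,
        )
    realigned = gpa(
        shapes,
        sliders=None,
        project_to_tangent=aligned.tangent_projected,
    )
    realigned.centroid_sizes = aligned.centroid_sizes
    realigned.ids = aligned.ids
    realigned.labels = aligned.labels
    return realigned


def _through_origin_regression(y: np.ndarray, x: np.ndarray) -> TangentCheck:
    slope = float(np.sum(x * y) / np.sum(x * x))
    corr = float(np.corrcoef(x, y)[0, 1]) if len(x) > 1 else 1.0
    if np.isnan(corr):  # zero-variance distances: perfectly collinear
        corr = 1.0
    return TangentCheck(slope=slope, correlation=corr)


def tangent_check(aligned: AlignedDataset) -> TangentCheck:
    """Regression of tangent (Euclidean) on Procrustes (geodesic) distances.

    Distances are measured from every configuration to the consensus: the
    geodesic is ``rho = arccos(<x, c>)`` on the pre-shape sphere and the
    tangent distance is the norm of the orthogonal projection residual
    (``sin rho``).  Slopes near 1 and correlations near 1 certify the
    tangent-plane approximation.
    """
    if aligned.preshapes is None:
        raise DatasetError("tangent_check requires GPA pre-shapes")
    n = aligned.n
    if n < 3:
        raise DatasetError("tangent_check needs at least 3 configurations")
    flat = aligned.preshapes.reshape(n, -1)
    c = aligned.consensus.ravel()
    c = c / np.linalg.norm(c)
    cosr = np.clip(flat @ c, -1.0, 1.0)
    rho = np.arccos(cosr)
    resid = flat - cosr[:, None] * c[None, :]
    d_tan = np.linalg.norm(resid, axis=1)
    if np.all(rho < 1e-7):  # arccos resolves ~1e-8 at cos ~ 1
        raise DatasetError("zero shape variation: tangent regression undefined")
    return _through_origin_regression(d_tan, rho)
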