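"""Synthetic landmark datasets and barcode alignments with known ground truth.

The shape generator emulates the structure a replicated digitization study
assumes: per-species mean configurations (smooth, low-bending-energy
deformations of a common template, drawn once per run), additive site
effects of the same smooth kind, isotropic per-landmark Gaussian specimen
variation, small replicate (digitization) error, and per-configuration
nuisance rotation/translation/scale that superimposition must remove.  The
default template mimics an ant head in full-face view: 13 fixed landmarks
plus two lateral curves of 10 semilandmarks each (33 points), so slider
logic is exercised.

The sequence generator plants a known group structure in an aligned
barcode matrix: a target between-group divergence matrix is realized by
neighbor-joining it into a tree and giving every edge a disjoint block of
sites mutated on one side of that edge, so tree-consistent targets are met
exactly up to rounding; within-group variation mutates individuals from
their group ancestor.  Mutations are placed uniformly without
back-mutation correction — the targets are uncorrected p-distances, so
this is exact by construction up to sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    DatasetError,
    LandmarkConfiguration,
    SequenceSet,
    ShapeDataset,
    SlidersSpec,
)
from .tps_warp import fit_tps, warp_points

__all__ = [
    "ShapeSimSpec",
    "SeqSimSpec",
    "head_like_template",
    "head_like_sliders",
    "simulate_shapes",
    "simulate_sequences",
]


def head_like_template() -> np.ndarray:
    """A 33-point template evoking an ant head in full-face view.

    13 fixed landmarks (vertex corners and midpoint, eye margins, clypeal
    and mandibular loci) followed by two 10-point semilandmark curves along
    the left and right lateral head margins.  Unit centroid size.
    """
    fixed = np.array(
        [
            (-0.45, 0.55),  # vertex corner L
            (0.45, 0.55),  # vertex corner R
            (0.0, 0.60),  # vertex midpoint
            (-0.38, 0.15),  # eye top L
            (0.38, 0.15),  # eye top R
            (-0.34, -0.05),  # eye bottom L
            (0.34, -0.05),  # eye bottom R
            (-0.16, -0.52),  # mandible insertion L
            (0.16, -0.52),  # mandible insertion R
            (-0.10, -0.38),  # clypeus corner L
            (0.10, -0.38),  # clypeus corner R
            (0.0, -0.45),  # clypeus midpoint
            (0.0, 0.0),  # median head centre
        ]
    )
    t = np.linspace(0.12, 0.88, 10)
    left = np.column_stack(
        [-0.45 - 0.08 * np.sin(np.pi * t), 0.55 - 1.07 * t]
    )
    right = np.column_stack([-left[:, 0], left[:, 1]])
    pts = np.vstack([fixed, left, right])
    pts -= pts.mean(axis=0)
    return pts / np.sqrt(np.sum(pts**2))


def head_like_sliders() -> SlidersSpec:
    """Slider triplets for the two curves of :func:`head_like_template`.

    Curve points slide along the chord of their curve neighbours; curve
    ends use the adjacent fixed landmarks (vertex corner, mandible
    insertion) as anchors.  1-based indices.
    """
    triplets: list[tuple[int, int, int]] = []
    for start, anchor_before, anchor_after in ((14, 1, 8), (24, 2, 9)):
        idx = list(range(start, start + 10))
        chain = [anchor_before] + idx + [anchor_after]
        for j in range(1, len(chain) - 1):
            triplets.append((chain[j - 1], chain[j], chain[j + 1]))
    return SlidersSpec(triplets)


def _smooth_field(
    template: np.ndarray, scale: float, rng: np.random.Generator, n_anchors: int = 5
) -> np.ndarray:
    """A smooth displacement field over the template, RMS magnitude ``scale``.

    Drawn as a thin-plate spline through a few random anchor displacements,
    so synthetic species differ the way biological shapes do rather than by
    white noise.
    """
    k = template.shape[0]
    if scale <= 0:
        return np.zeros((k, 2))
    span = template.max(axis=0) - template.min(axis=0)
    lo = template.min(axis=0)
    for _ in range(50):
        anchors = lo + rng.random((n_anchors, 2)) * span
        if np.linalg.matrix_rank(np.column_stack([np.ones(n_anchors), anchors])) == 3:
            break
    disp = rng.standard_normal((n_anchors, 2))
    warp = fit_tps(anchors, anchors + 0.1 * span.mean() * disp)
    field = warp_points(warp, template) - template
    rms = np.sqrt(np.mean(np.sum(field**2, axis=1)))
    if rms <= 0:
        return np.zeros((k, 2))
    return field * (scale / rms)


@dataclass
class ShapeSimSpec:
    """Ground-truth recipe for a labelled synthetic landmark dataset.

    ``species_effect_scale`` and ``site_effect_scale`` are RMS per-landmark
    displacements of the smooth mean-shape fields; ``sigma`` is the
    isotropic per-landmark specimen sd and ``sigma_rep`` the digitization
    (replicate) error sd — all in template units (template has unit
    centroid size).  Nuisance rotation/translation/scale are drawn per
    configuration and must be removed by superimposition.
    """

    template: np.ndarray = field(default_factory=head_like_template)
    n_species: int = 4
    n_sites: int = 2
    n_specimens: int = 5  # per species x site
    n_replicates: int = 2
    species_effect_scale: float = 0.05
    site_effect_scale: float = 0.015
    sigma: float = 0.01
    sigma_rep: float = 0.003
    rotation_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    translation_range: float = 0.5
    scale_range: tuple[float, float] = (0.75, 1.25)
    colony_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if self.template.shape[0] < 3:
            raise DatasetError("template needs k >= 3 landmarks")
        if self.sigma < 0 or self.sigma_rep < 0:
            raise DatasetError("noise sds must be non-negative")
        if min(self.n_species, self.n_sites, self.n_specimens, self.n_replicates) < 1:
            raise DatasetError("counts must be >= 1")


def simulate_shapes(spec: ShapeSimSpec) -> ShapeDataset:
    """Generate a labelled landmark dataset from a :class:`ShapeSimSpec`.

    Each configuration is ``nuisance(template + species field + site field
    + N(0, sigma^2) + N(0, sigma_rep^2))`` with the replicate term redrawn
    per replicate; the same seed reproduces the dataset bit-for-bit.  The
    label table carries species, site, colony and replicate_id.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.template.shape[0]
    species_fields = {
        f"sp{i + 1}": _smooth_field(spec.template, spec.species_effect_scale, rng)
        for i in range(spec.n_species)
    }
    site_fields = {
        (sp, f"site{j + 1}"): _smooth_field(spec.template, spec.site_effect_scale, rng)
        for sp in species_fields
        for j in range(spec.n_sites)
    }

    configs: list[LandmarkConfiguration] = []
    rows: list[dict] = []
    for sp, sp_field in species_fields.items():
        for j in range(spec.n_sites):
            site = f"site{j + 1}"
            st_field = site_fields[(sp, site)]
            for m in range(spec.n_specimens):
                specimen = (
                    spec.template
                    + sp_field
                    + st_field
                    + rng.normal(0.0, spec.sigma, (k, 2))
                )
                colony = f"{sp}_{site}_c{m // spec.colony_size + 1}"
                for r in range(spec.n_replicates):
                    pts = specimen + rng.normal(0.0, spec.sigma_rep, (k, 2))
                    theta = rng.uniform(*spec.rotation_range)
                    R = np.array(
                        [
                            [np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)],
                        ]
                    )
                    s = rng.uniform(*spec.scale_range)
                    t = rng.uniform(-spec.translation_range, spec.translation_range, 2)
                    pts = s * pts @ R.T + t
                    cid = f"{sp}_{site}_i{m + 1}_r{r + 1}"
                    configs.append(
                        LandmarkConfiguration(
                            id=cid, points=pts, scale=1.0, image_name=f"{cid}.jpg"
                        )
                    )
                    rows.append(
                        dict(
                            id=cid,
                            species=sp,
                            site=site,
                            colony=colony,
                            replicate_id=f"r{r + 1}",
                        )
                    )
    labels = pd.DataFrame(rows).set_index("id")
    return ShapeDataset(configs, labels)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SeqSimSpec:
    """Recipe for an aligned sequence set with planted group divergences.

    ``divergence`` is the symmetric target matrix of mean between-group
    uncorrected p-distances (fractions); ``within`` the expected mean
    within-group pairwise distance; ``sizes`` the per-group sample sizes.
    """

    divergence: np.ndarray  # (g, g) symmetric, zero diagonal
    sizes: list[int] = field(default_factory=lambda: [5, 5])
    within: float = 0.01
    length: int = 313
    seed: int = 0
    group_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.divergence = np.asarray(self.divergence, dtype=float)
        g = self.divergence.shape[0]
        if self.divergence.shape != (g, g):
            raise DatasetError("divergence matrix must be square")
        if not np.allclose(self.divergence, self.divergence.T):
            raise DatasetError("divergence matrix must be symmetric")
        if np.any(np.diag(self.divergence) != 0):
            raise DatasetError("divergence matrix must have zero diagonal")
        if np.any(self.divergence < 0) or np.any(self.divergence > 0.75):
            raise DatasetError("divergences must lie in [0, 0.75]")
        if len(self.sizes) != g:
            raise DatasetError("sizes must match the number of groups")
        if self.within < 0:
            raise DatasetError("within-group divergence must be non-negative")
        if self.group_names is None:
            self.group_names = [f"g{i + 1}" for i in range(g)]

    @property
    def g(self) -> int:
        return self.divergence.shape[0]


def _nj_edge_clades(D: np.ndarray, names: list[str]) -> list[tuple[set, float]]:
    """Neighbor-join a distance matrix; return (tip-set below edge, length).

    Raises on clearly infeasible matrices (edges more negative than the
    rounding tolerance); small negative lengths from near-additivity are
    clamped to zero.
    """
    from skbio import DistanceMatrix as _SkbioDM
    from skbio.tree import nj as _nj

    tree = _nj(_SkbioDM(D, ids=names), neg_as_zero=False)
    edges: list[tuple[set, float]] = []
    for node in tree.postorder(include_self=False):
        length = float(node.length or 0.0)
        if length < -1e-3:
            raise DatasetError(
                "divergence matrix is not realizable as a tree "
                f"(negative branch {length:.4f}); check the triangle inequality"
            )
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        edges.append((tips, max(length, 0.0)))
    return edges


def simulate_sequences(spec: SeqSimSpec) -> tuple[SequenceSet, pd.DataFrame]:
    """Generate an aligned sequence set realizing a target divergence matrix.

    A root sequence is drawn; each tree edge of the neighbor-joined target
    matrix mutates a disjoint block of sites in all groups below it, so
    between-group ancestor distances equal tree path lengths exactly.
    Individuals then receive ``within/2`` extra mutations from their group
    ancestor (mean within-group pairwise distance ~ ``within``); ancestor
    divergences are pre-shrunk by ``within`` so realized between-group
    means match the targets.  Returns the sequences and a label table.
    """
    rng = np.random.default_rng(spec.seed)
    g, L = spec.g, spec.length
    names = list(spec.group_names)
    D_anc = spec.divergence - spec.within
    np.fill_diagonal(D_anc, 0.0)
    off = ~np.eye(g, dtype=bool)
    if g > 1 and np.any(D_anc[off] < -1e-9):
        if np.all(spec.divergence[off] == 0) and spec.within == 0:
            D_anc = np.zeros_like(D_anc)
        else:
            raise DatasetError(
                "between-group divergences must exceed the within-group rate"
            )
    D_anc = np.clip(D_anc, 0.0, None)

    root = rng.choice(_BASES, size=L)
    ancestors = {name: root.copy() for name in names}

    if g == 2:
        edges = [({names[0]}, float(D_anc[0, 1]))]
    elif g > 2:
        edges = _nj_edge_clades(D_anc, names)
    else:
        edges = []

    site_counts = [int(round(ln * L)) for _, ln in edges]
    if sum(site_counts) > L:
        raise DatasetError(
            f"divergence targets need {sum(site_counts)} sites but length is {L}"
        )
    pool = rng.permutation(L)
    cursor = 0
    for (tips, _), n_sites in zip(edges, site_counts):
        block = pool[cursor : cursor + n_sites]
        cursor += n_sites
        for site in block:
            old = root[site]
            new = rng.choice(_BASES[_BASES != old])
            for name in tips:
                ancestors[name][site] = new

    ids: list[str] = []
    seqs: list[str] = []
    rows: list[dict] = []
    n_mut = int(round(spec.within / 2.0 * L))
    for gi, name in enumerate(names):
        for si in range(spec.sizes[gi]):
            seq = ancestors[name].copy()
            if n_mut:
                sites = rng.choice(L, size=n_mut, replace=False)
                for site in sites:
                    seq[site] = rng.choice(_BASES[_BASES != seq[site]])
            sid = f"{name}_s{si + 1:02d}"
            ids.append(sid)
            seqs.append(seq.tobytes().decode("ascii"))
            rows.append(dict(id=sid, group=name))
    labels = pd.DataFrame(rows).set_index("id")
    return SequenceSet(ids=ids, sequences=seqs), labels
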