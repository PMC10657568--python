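"""Variance decomposition and ordination of Procrustes-aligned shapes.

* :func:`procrustes_anova` — permutation-based Procrustes ANOVA (Goodall's
  F test): sequential (Type I) sums of squares of the tangent coordinates
  treated as a multivariate response, with significance from randomized
  residual permutation (RRPP).  Used to quantify how much shape variation
  species, collection site and digitization replicate each explain.
* :func:`relative_warps` — principal components of the tangent coordinates
  (relative warps with the weighting exponent alpha = 0 and the uniform
  component included); the shape variables consumed by CVA and PERMANOVA.
* :func:`between_group_pca` — eigen-analysis of the covariance of group
  mean shapes with all individuals projected onto the group-mean axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DatasetError
from .superimpose import AlignedDataset

__all__ = [
    "AnovaTable",
    "WarpScores",
    "PcaResult",
    "procrustes_anova",
    "relative_warps",
    "between_group_pca",
]


@dataclass
class AnovaTable:
    """Goodall's-F ANOVA table with factor, residual and total rows."""

    table: pd.DataFrame  # rows: factors, Residual, Total
    n_perm: int
    seed: int

    def percent(self, factor: str) -> float:
        return float(self.table.loc[factor, "percent_ss"])

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])


@dataclass
class WarpScores:
    """Relative-warp (principal component) scores of tangent coordinates."""

    scores: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,) descending
    percent_variance: np.ndarray  # (m,) sums to 100
    axes: np.ndarray  # (2k, m) loading vectors
    center: np.ndarray  # (2k,) mean tangent coordinates
    alpha: float = 0.0
    uniform_included: bool = True

    @property
    def m(self) -> int:
        return self.scores.shape[1]


@dataclass
class PcaResult:
    """Between-group PCA: axes of the group-mean covariance."""

    axes: np.ndarray  # (d, a) orthonormal loading vectors
    eigenvalues: np.ndarray  # (a,)
    percent_variance: np.ndarray  # (a,) share of group-mean variance
    percent_total: np.ndarray  # (a,) share of total projected variance
    scores: np.ndarray  # (n, a) all individuals projected
    group_means: np.ndarray  # (g, a) group means in score space
    groups: list = field(default_factory=list)
    center: np.ndarray | None = None


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _dummies(values: np.ndarray) -> np.ndarray:
    levels = pd.unique(values)
    return (values[:, None] == levels[None, :]).astype(float)


def _orthobasis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0:
        return U[:, :0]
    rank = int(np.sum(s > s[0] * 1e-10))
    return U[:, :rank]


def procrustes_anova(
    aligned: AlignedDataset,
    factors: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    nest_site_in_species: bool = True,
) -> AnovaTable:
    """Permutation-based Procrustes ANOVA (Goodall's F) on tangent coordinates.

    Factors enter sequentially (Type I) in the order given — by default
    species, then site, then replicate — with site nested in species when
    ``nest_site_in_species`` (sites are geographic subsets of species
    samples).  Sums of squares are summed squared Euclidean distances of the
    flattened tangent coordinates; per factor, Goodall's
    ``F = (SS_f / df_f) / (SS_res / df_res)`` and the p-value comes from
    randomized residual permutation under the reduced model, with
    ``p = (#{F* >= F} + 1) / (n_perm + 1)``.
    """
    if factors is None:
        # auto-select the standard factors, skipping absent or constant ones
        factors = [
            c
            for c in ("species", "site", "replicate_id")
            if _has(aligned, c) and aligned.labels[c].nunique() > 1
        ]
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    Y = aligned.flat()
    n = Y.shape[0]

    columns: dict[str, np.ndarray] = {}
    for f in factors:
        vals = np.asarray(aligned.label_vector(f)).astype(str)
        if len(pd.unique(vals)) < 2:
            raise DatasetError(f"factor {f!r} is constant")
        columns[f] = vals
    if nest_site_in_species and "site" in columns and "species" in columns:
        columns["site"] = np.char.add(
            np.char.add(columns["species"], ":"), columns["site"]
        )

    # cumulative orthonormal bases: intercept, then each added term
    bases: list[np.ndarray] = []
    X = np.ones((n, 1))
    bases.append(_orthobasis(X))
    for f in factors:
        X = np.column_stack([X, _dummies(columns[f])])
        bases.append(_orthobasis(X))

    ss_fit = np.array([np.sum((B.T @ Y) ** 2) for B in bases])
    dfs = np.array([B.shape[1] for B in bases])
    ss_total = float(np.sum(Y**2) - ss_fit[0])
    ss_terms = np.diff(ss_fit)
    df_terms = np.diff(dfs)
    if np.any(df_terms < 1):
        bad = factors[int(np.argmin(df_terms))]
        raise DatasetError(f"factor {bad!r} adds no degrees of freedom (aliased)")
    df_res = n - dfs[-1]
    ss_res = float(np.sum(Y**2) - ss_fit[-1])
    if df_res < 1:
        raise DatasetError("no residual degrees of freedom")
    F_obs = (ss_terms / df_terms) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    p_vals = np.ones(len(factors))
    for t in range(len(factors)):
        B_red, B_full_t = bases[t], bases[t + 1]
        B_full = bases[-1]
        fitted = B_red @ (B_red.T @ Y)
        resid = Y - fitted
        count = 0
        for _ in range(n_perm):
            Yp = fitted + resid[rng.permutation(n)]
            fit_red = np.sum((B_red.T @ Yp) ** 2)
            fit_t = np.sum((B_full_t.T @ Yp) ** 2)
            fit_full = np.sum((B_full.T @ Yp) ** 2)
            ss_t = fit_t - fit_red
            ss_r = np.sum(Yp**2) - fit_full
            Fp = (ss_t / df_terms[t]) / (ss_r / df_res)
            if Fp >= F_obs[t] - 1e-12:
                count += 1
        p_vals[t] = (count + 1) / (n_perm + 1)

    rows = []
    for t, f in enumerate(factors):
        rows.append(
            dict(
                source=f,
                df=int(df_terms[t]),
                ss=float(ss_terms[t]),
                percent_ss=100.0 * ss_terms[t] / ss_total,
                F=float(F_obs[t]),
                p=float(p_vals[t]),
                n_perm=n_perm,
            )
        )
    rows.append(
        dict(
            source="Residual",
            df=int(df_res),
            ss=ss_res,
            percent_ss=100.0 * ss_res / ss_total,
            F=np.nan,
            p=np.nan,
            n_perm=n_perm,
        )
    )
    rows.append(
        dict(
            source="Total",
            df=int(n - 1),
            ss=ss_total,
            percent_ss=100.0,
            F=np.nan,
            p=np.nan,
            n_perm=n_perm,
        )
    )
    table = pd.DataFrame(rows).set_index("source")
    return AnovaTable(table=table, n_perm=n_perm, seed=seed)


def _has(aligned: AlignedDataset, column: str) -> bool:
    return aligned.labels is not None and column in aligned.labels.columns


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def relative_warps(aligned: AlignedDataset) -> WarpScores:
    """Principal components of tangent coordinates (relative warps, alpha=0).

    With alpha = 0 and the uniform component included, relative-warp scores
    are exactly PC scores of the flattened tangent coordinates; pairwise
    Euclidean distances in full score space equal tangent-space distances.
    """
    if aligned.n < 3:
        raise DatasetError("relative warps need at least 3 configurations")
    X = aligned.flat()
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0:
        raise DatasetError("zero shape variation")
    keep = s > s[0] * 1e-9
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # sign convention: largest-magnitude loading positive
    flips = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    Vt = Vt * flips[:, None]
    U = U * flips[None, :]
    eig = s**2 / (aligned.n - 1)
    return WarpScores(
        scores=U * s,
        eigenvalues=eig,
        percent_variance=100.0 * eig / eig.sum(),
        axes=Vt.T,
        center=center,
    )


def between_group_pca(
    X: np.ndarray,
    groups: np.ndarray,
) -> PcaResult:
    """Between-group PCA: eigen-decomposition of the group-mean covariance.

    Group means are weighted equally (not by sample size).  All individuals
    are projected onto the axes; percent variance per axis is reported both
    as the share of group-mean variance (``percent_variance``, the figure
    used for ordination summaries) and as the share of total projected
    individual variance (``percent_total``).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    g = len(levels)
    if g < 2:
        raise DatasetError("between-group PCA needs at least 2 groups")
    means = np.stack([X[groups == lv].mean(axis=0) for lv in levels])
    center = means.mean(axis=0)
    M = means - center
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    keep = s > (s[0] * 1e-9 if s[0] > 0 else np.inf)
    s, Vt = s[keep], Vt[keep]
    a = min(len(s), g - 1)
    s, Vt = s[:a], Vt[:a]
    flips = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)]) if a else np.array([])
    if a:
        Vt = Vt * flips[:, None]
    eig = s**2 / (g - 1) if a else np.zeros(0)
    axes = Vt.T
    scores = (X - center) @ axes
    group_scores = (means - center) @ axes
    total_var = np.sum((X - X.mean(axis=0)) ** 2) / (len(X) - 1)
    proj_var = scores.var(axis=0, ddof=1) if a else np.zeros(0)
    return PcaResult(
        axes=axes,
        eigenvalues=eig,
        percent_variance=(100.0 * eig / eig.sum()) if a else np.zeros(0),
        percent_total=(100.0 * proj_var / total_var) if a else np.zeros(0),
        scores=scores,
        group_means=group_scores,
        groups=levels,
        center=center,
    )
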