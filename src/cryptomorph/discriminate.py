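"""Group discrimination on shape variables.

* :func:`cva` — canonical variates analysis: the generalized eigenproblem
  of between-group vs pooled within-group covariance, maximizing group
  separation relative to within-group variation.
* :func:`jackknife_classify` — leave-one-out cross-validated classification:
  each individual is withheld, the CVA refitted, the individual projected
  and assigned to the nearest group mean in canonical space; tallied into a
  confusion matrix with overall accuracy.
* :func:`pairwise_permanova` — one-way PERMANOVA (pseudo-F on Euclidean
  distances) for every pair of groups, permutation p-values and Bonferroni
  correction.

Input scores are assumed variance-ordered (relative warps / PCs); the
``retain`` rule truncates them before CVA to keep the pooled within-group
covariance well-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg

from .io_formats import DatasetError

__all__ = [
    "CvaResult",
    "ConfusionMatrix",
    "PairwiseTests",
    "cva",
    "jackknife_classify",
    "pairwise_permanova",
    "permanova_pseudo_f",
    "pseudo_f_from_coords",
]


@dataclass
class CvaResult:
    """Canonical variates: axes, eigenvalues and scores."""

    axes: np.ndarray  # (m', a) canonical vectors on retained dimensions
    eigenvalues: np.ndarray  # (a,) descending
    percent_variance: np.ndarray  # (a,) share of among-group variance
    scores: np.ndarray  # (n, a)
    group_means: np.ndarray  # (g, a)
    groups: list = field(default_factory=list)
    retained: int = 0  # m' input dimensions kept
    center: np.ndarray | None = None


@dataclass
class ConfusionMatrix:
    """Jackknifed classification tally: true rows x assigned columns."""

    groups: list
    counts: np.ndarray  # (g, g) int

    @property
    def accuracy(self) -> float:
        """Overall percent of individuals assigned to their true group."""
        return 100.0 * float(np.trace(self.counts)) / float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.groups, columns=self.groups)


@dataclass
class PairwiseTests:
    """Pairwise PERMANOVA results with Bonferroni correction."""

    groups: list
    f_values: pd.DataFrame  # symmetric, zero diagonal
    p_raw: pd.DataFrame
    p_corrected: pd.DataFrame
    n_perm: int
    sizes: dict


def _resolve_retain(X: np.ndarray, groups: np.ndarray, retain) -> int:
    """Number of leading (variance-ordered) columns to keep before CVA."""
    n, m = X.shape
    g = len(pd.unique(groups))
    cap = max(1, min(m, n - g - 1))
    if retain is None or retain == "variance99":
        var = X.var(axis=0, ddof=1)
        total = var.sum()
        if total <= 0:
            raise DatasetError("zero variance in scores")
        cum = np.cumsum(var) / total
        m99 = int(np.searchsorted(cum, 0.99 - 1e-12) + 1)
        return min(m99, cap)
    if retain == "all":
        return cap
    if isinstance(retain, float) and 0 < retain < 1:
        var = X.var(axis=0, ddof=1)
        cum = np.cumsum(var) / var.sum()
        return min(int(np.searchsorted(cum, retain - 1e-12) + 1), cap)
    if isinstance(retain, (int, np.integer)) and retain >= 1:
        return min(int(retain), cap)
    raise ValueError(f"unrecognized retention rule {retain!r}")


def _cva_core(X: np.ndarray, groups: np.ndarray, levels: list) -> tuple:
    """Solve the between vs pooled-within generalized eigenproblem."""
    n, m = X.shape
    g = len(levels)
    grand = X.mean(axis=0)
    W = np.zeros((m, m))
    means = np.zeros((g, m))
    for gi, lv in enumerate(levels):
        sub = X[groups == lv]
        means[gi] = sub.mean(axis=0)
        dev = sub - means[gi]
        W += dev.T @ dev
    B = np.zeros((m, m))
    for gi, lv in enumerate(levels):
        n_g = np.sum(groups == lv)
        d = means[gi] - grand
        B += n_g * np.outer(d, d)
    W /= max(n - g, 1)
    B /= max(g - 1, 1)
    try:
        evals, evecs = scipy.linalg.eigh(B, W)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise DatasetError(
            "singular pooled within-group covariance: retain fewer dimensions"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    a = min(g - 1, m)
    evals, evecs = np.clip(evals[:a], 0, None), evecs[:, :a]
    # drop numerically-null axes and fix signs
    keep = evals > (evals[0] * 1e-12 if evals[0] > 0 else np.inf)
    evals, evecs = evals[keep], evecs[:, keep]
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return grand, means, evals, evecs


def cva(X: np.ndarray, groups: np.ndarray, retain="variance99") -> CvaResult:
    """Canonical variates analysis of variance-ordered score columns.

    ``retain`` keeps the leading columns explaining 99% of variance
    (bounded by n - g - 1) before solving, to avoid a singular within-group
    covariance; pass an integer, a fraction, or ``"all"`` to override.
    Percent per canonical axis is its eigenvalue share.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise DatasetError("CVA needs at least 2 groups")
    m_keep = _resolve_retain(X, groups, retain)
    Xr = X[:, :m_keep]
    grand, means, evals, evecs = _cva_core(Xr, groups, levels)
    scores = (Xr - grand) @ evecs
    gmeans = (means - grand) @ evecs
    total = evals.sum()
    return CvaResult(
        axes=evecs,
        eigenvalues=evals,
        percent_variance=100.0 * evals / total if total > 0 else evals,
        scores=scores,
        group_means=gmeans,
        groups=levels,
        retained=m_keep,
        center=grand,
    )


def jackknife_classify(
    X: np.ndarray,
    groups: np.ndarray,
    retain="variance99",
    refit: str = "full",
) -> ConfusionMatrix:
    """Leave-one-out cross-validated classification via CVA.

    ``refit="full"`` refits the CVA without each individual before
    projecting and assigning it to the nearest group mean in canonical
    space (Euclidean there = Mahalanobis in the original space under the
    CVA metric).  ``refit="means"`` is the cheaper variant that reuses the
    full-data axes and only recomputes group means.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    g = len(levels)
    sizes = {lv: int(np.sum(groups == lv)) for lv in levels}
    small = [lv for lv, s in sizes.items() if s < 2]
    if small:
        raise DatasetError(f"groups of size 1 cannot be jackknifed: {small}")
    idx = {lv: i for i, lv in enumerate(levels)}
    counts = np.zeros((g, g), dtype=int)
    n = len(X)

    if refit == "means":
        full = cva(X, groups, retain=retain)
        Xr = X[:, : full.retained]
        proj = (Xr - full.center) @ full.axes
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            d = [
                np.linalg.norm(proj[i] - proj[mask & (groups == lv)].mean(axis=0))
                for lv in levels
            ]
            counts[idx[groups[i]], int(np.argmin(d))] += 1
        return ConfusionMatrix(groups=levels, counts=counts)
    if refit != "full":
        raise ValueError(f"unknown refit mode {refit!r}")

    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        fit = cva(X[mask], groups[mask], retain=retain)
        xi = (X[i, : fit.retained] - fit.center) @ fit.axes
        d = [np.linalg.norm(xi - fit.group_means[fit.groups.index(lv)]) for lv in levels]
        counts[idx[groups[i]], int(np.argmin(d))] += 1
    return ConfusionMatrix(groups=levels, counts=counts)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova_pseudo_f(D2: np.ndarray, membership: np.ndarray) -> float:
    """One-way pseudo-F from a squared Euclidean distance matrix.

    Gower identity: total SS = sum(d^2)/n over all unordered pairs; within
    SS analogously per group.  ``membership`` codes groups as integers
    0..g-1.  F = (SS_between/(g-1)) / (SS_within/(n-g)).
    """
    n = len(membership)
    codes = np.asarray(membership)
    g = len(np.unique(codes))
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for c in np.unique(codes):
        z = codes == c
        n_c = int(z.sum())
        ss_within += D2[np.ix_(z, z)].sum() / (2.0 * n_c)
    ss_between = ss_total - ss_within
    return float((ss_between / (g - 1)) / (ss_within / (n - g)))


def pseudo_f_from_coords(X: np.ndarray, membership: np.ndarray) -> float:
    """Pseudo-F computed directly from centered coordinates (cross-check).

    Equals :func:`permanova_pseudo_f` on the corresponding Euclidean
    distance matrix by the Gower identity.
    """
    X = np.asarray(X, dtype=float)
    codes = np.asarray(membership)
    n = len(X)
    g = len(np.unique(codes))
    grand = X.mean(axis=0)
    ss_total = float(np.sum((X - grand) ** 2))
    ss_within = 0.0
    for c in np.unique(codes):
        sub = X[codes == c]
        ss_within += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _two_group_permanova(
    Xa: np.ndarray, Xb: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed pseudo-F and permutation p for one pair (vectorized)."""
    X = np.vstack([Xa, Xb])
    n, na = len(X), len(Xa)
    d = X[:, None, :] - X[None, :, :]
    D2 = np.einsum("ijk,ijk->ij", d, d)
    codes = np.zeros(n, dtype=int)
    codes[na:] = 1
    F_obs = permanova_pseudo_f(D2, codes)

    total = D2.sum() / (2.0 * n)
    # permuted within-SS via membership indicator algebra: for group A with
    # indicator z, sum of within-pair d^2 = z' D2 z (diagonal is 0)
    Z = np.zeros((n, n_perm))
    for p in range(n_perm):
        Z[rng.permutation(n)[:na], p] = 1.0
    quad_a = np.einsum("ip,ij,jp->p", Z, D2, Z)
    Zb = 1.0 - Z
    quad_b = np.einsum("ip,ij,jp->p", Zb, D2, Zb)
    ss_within = quad_a / (2.0 * na) + quad_b / (2.0 * (n - na))
    ss_between = total - ss_within
    F_perm = (ss_between / 1.0) / (ss_within / (n - 2))
    p_val = (np.sum(F_perm >= F_obs - 1e-12) + 1) / (n_perm + 1)
    return F_obs, float(p_val)


def pairwise_permanova(
    X: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    correction: str = "bonferroni",
) -> PairwiseTests:
    """Pairwise one-way PERMANOVA on Euclidean distances between all groups.

    Per pair: pseudo-F from the distance matrix, p by permutation of group
    membership (``p = (#{F* >= F} + 1)/(n_perm + 1)``), then Bonferroni
    correction across all pairs (``p_corr = min(1, p * n_pairs)``).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}")
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise DatasetError("pairwise PERMANOVA needs at least 2 groups")
    sizes = {lv: int(np.sum(groups == lv)) for lv in levels}
    small = [lv for lv, s in sizes.items() if s < 2]
    if small:
        raise DatasetError(f"groups with < 2 members cannot be tested: {small}")
    pairs = list(combinations(levels, 2))
    n_pairs = len(pairs)
    rng = np.random.default_rng(seed)
    F = pd.DataFrame(0.0, index=levels, columns=levels)
    P = pd.DataFrame(np.nan, index=levels, columns=levels)
    Pc = pd.DataFrame(np.nan, index=levels, columns=levels)
    for a, b in pairs:
        f, p = _two_group_permanova(X[groups == a], X[groups == b], n_perm, rng)
        F.loc[a, b] = F.loc[b, a] = f
        P.loc[a, b] = P.loc[b, a] = p
        pc = min(1.0, p * n_pairs)
        Pc.loc[a, b] = Pc.loc[b, a] = pc
    return PairwiseTests(
        groups=levels, f_values=F, p_raw=P, p_corrected=Pc, n_perm=n_perm, sizes=sizes
    )
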