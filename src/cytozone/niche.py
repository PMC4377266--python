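"""Niche vectors from accompanying species, Pillai MANOVA, PCA, breadth.

The realised micro-niche of each individual is summarised by the
unweighted arithmetic mean of the indicator values (T, L, F, R, N, H) of
the vascular plant species found within its plot, the target species
itself excluded.  Group differentiation is tested with the
Pillai–Bartlett trace; ordination uses PCA of the standardized matrix;
niche breadth is the mean distance of group members to their centroid in
score space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .config import INDICATOR_NAMES

logger = logging.getLogger("cytozone.niche")


def compute_niche_matrix(
    plots: pd.DataFrame,
    indicators: pd.DataFrame,
    exclude_species=(),
) -> pd.DataFrame:
    """Per-individual mean indicator values over accompanying species.

    Missing indicator values are handled per indicator: the mean is taken
    over the species that have a value for that indicator.  Individuals
    with no usable accompanying species, or with an indicator for which no
    accompanying species has a value, are dropped with a logged warning.
    """
    exclude = set(exclude_species)
    cols = list(INDICATOR_NAMES)
    rows = {}
    dropped = []
    for ind, group in plots.groupby("individual_id", sort=False):
        species = [s for s in group["species"] if s not in exclude]
        known = [s for s in species if s in indicators.index]
        unknown = sorted(set(species) - set(known))
        if unknown:
            logger.warning(
                "individual %s: species without indicator values skipped: %s",
                ind, unknown,
            )
        if not known:
            dropped.append(ind)
            continue
        means = indicators.loc[known, cols].mean(axis=0, skipna=True)
        if means.isna().any():
            dropped.append(ind)
            continue
        rows[ind] = means
    for ind in dropped:
        logger.warning("individual %s dropped: no usable accompanying species", ind)
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


@dataclass
class ManovaResult:
    """Pillai–Bartlett trace with its standard F approximation."""

    pillai: float
    F: float
    df1: int
    df2: int
    p: float
    n: int
    n_groups: int
    n_responses: int


def pillai_manova(niche, groups) -> ManovaResult:
    """One-way MANOVA using the Pillai–Bartlett trace.

    ``V = sum_i lambda_i / (1 + lambda_i)`` over the eigenvalues of
    ``W^{-1} B`` (within / between cross-product matrices).  The F
    approximation uses ``s = min(p, g-1)``, ``m = (|p-g+1|-1)/2``,
    ``n' = (dfe-p-1)/2``:

        F = ((2n'+s+1)/(2m+s+1)) * (V/s) / (1 - V/s),
        df1 = s(2m+s+1),  df2 = s(2n'+s+1).
    """
    Y, codes, levels = _align(niche, groups)
    n, p = Y.shape
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes, minlength=g)
    if (counts < 2).any():
        lvl = levels[int(np.argmin(counts))]
        raise ValueError(f"group {lvl!r} has fewer than 2 members")
    if n <= p + g:
        raise ValueError(f"total n={n} must exceed responses+groups={p + g}")
    B, W = _cross_products(Y, codes, g)
    V = _pillai_trace(B, W)
    return _finish_manova(V, p, g, n)


def _finish_manova(V: float, p: int, g: int, n: int) -> ManovaResult:
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    dfe = n - g
    nprime = (dfe - p - 1) / 2.0
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * nprime + s + 1)))
    ratio = V / s
    ratio = min(ratio, 1 - 1e-300)
    F = ((2 * nprime + s + 1) / (2 * m + s + 1)) * ratio / (1 - ratio)
    pval = float(stats.f.sf(F, df1, df2))
    return ManovaResult(
        pillai=float(V), F=float(F), df1=df1, df2=df2, p=pval,
        n=n, n_groups=g, n_responses=p,
    )


def _cross_products(Y: np.ndarray, codes: np.ndarray, g: int):
    """Between- and within-group cross-product matrices."""
    n, p = Y.shape
    grand = Y.mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for k in range(g):
        Yk = Y[codes == k]
        mk = Yk.mean(axis=0)
        d = mk - grand
        B += len(Yk) * np.outer(d, d)
        R = Yk - mk
        W += R.T @ R
    return B, W


def _pillai_trace(B: np.ndarray, W: np.ndarray) -> float:
    # eigh can silently return garbage for a numerically singular metric,
    # so test conditioning explicitly
    if np.linalg.matrix_rank(W, hermitian=True) < W.shape[0]:
        raise ValueError(
            "within-group cross-product matrix is singular; remove constant "
            "or collinear response columns"
        )
    try:
        lam = linalg.eigh(B, W, eigvals_only=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "within-group cross-product matrix is singular; remove constant "
            "or collinear response columns"
        ) from exc
    lam = np.clip(lam, 0.0, None)
    return float(np.sum(lam / (1.0 + lam)))


def manova_F(Y: np.ndarray, codes: np.ndarray, g: int) -> float:
    """Lean Pillai-approximation F for permutation loops (no validation)."""
    n, p = Y.shape
    B, W = _cross_products(Y, codes, g)
    V = _pillai_trace(B, W)
    return _finish_manova(V, p, g, n).F


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    """PCA of the standardized niche matrix.

    ``scores`` are individuals x components, ``loadings`` variables x
    components (orthonormal, largest-magnitude loading per component
    positive), ``explained`` the variance fractions (sum to 1).  When
    groups are supplied, per-group ``centroids`` and score-space
    ``sd`` describe the confidence ellipses.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    centroids: pd.DataFrame | None = None
    sd: pd.DataFrame | None = None


def pca_niche(niche: pd.DataFrame, groups=None) -> PcaResult:
    """PCA of the correlation-scaled (zero-mean, unit-variance) matrix."""
    if niche.shape[0] < 2:
        raise ValueError("need at least 2 individuals for PCA")
    X = niche.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(niche.columns[~keep])
        logger.warning("PCA: constant column(s) dropped: %s", dropped)
    cols = niche.columns[keep]
    X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # reproducible orientation: largest-|loading| per component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    comp = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=niche.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=cols, columns=comp)
    explained = S**2 / np.sum(S**2)
    centroids = sds = None
    if groups is not None:
        groups = _as_series(groups, niche.index)
        centroids = scores.groupby(groups).mean()
        sds = scores.groupby(groups).std(ddof=1)
    return PcaResult(scores, loadings, explained, centroids, sds)


def niche_breadth(pca: PcaResult, groups) -> pd.DataFrame:
    """Mean (± standard error) Euclidean distance of each group member to
    its group centroid in full score space.  Single-member groups get a
    missing SE.
    """
    groups = _as_series(groups, pca.scores.index)
    rows = []
    for lvl, idx in groups.groupby(groups).groups.items():
        pts = pca.scores.loc[idx].to_numpy()
        centroid = pts.mean(axis=0)
        d = np.linalg.norm(pts - centroid, axis=1)
        se = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else float("nan")
        rows.append({"group": lvl, "n": len(d), "mean_dist": float(d.mean()), "se": se})
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------

def _align(niche, groups):
    if isinstance(niche, pd.DataFrame):
        Y = niche.to_numpy(dtype=float)
        index = niche.index
    else:
        Y = np.asarray(niche, dtype=float)
        index = pd.RangeIndex(len(Y))
    g = _as_series(groups, index)
    codes, levels = pd.factorize(g, sort=True)
    return Y, codes, list(levels)


def _as_series(groups, index) -> pd.Series:
    if isinstance(groups, pd.Series):
        missing = [i for i in index if i not in groups.index]
        if missing:
            raise ValueError(f"no group label for {missing[:3]}")
        return groups.loc[index]
    groups = pd.Series(list(groups), index=index)
    return groups
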