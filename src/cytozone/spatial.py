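"""Microspatial clustering of cytotypes: Mantel test with Kendall's tau.

Spatial segregation is quantified by correlating pairwise geographic
distance with a binary cytotype distance (0 = same ploidy, 1 =
different).  The correlation is Kendall's tau-b over the strict lower
triangles — tau-b because the 0/1 matrix is almost entirely ties — and
significance comes from jointly permuting rows and columns of one
matrix (the standard Mantel null, preserving distance-matrix
structure), with an add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


def geo_distances(individuals: pd.DataFrame) -> pd.DataFrame:
    """Euclidean pairwise distances (metres) between individuals."""
    coords = individuals[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    D = squareform(pdist(coords))
    ids = individuals["id"]
    return pd.DataFrame(D, index=ids, columns=ids)


def cytotype_distances(individuals: pd.DataFrame) -> pd.DataFrame:
    """Binary distance: 0 for same cytotype, 1 for different."""
    cyt = individuals["cytotype"].to_numpy()
    D = (cyt[:, None] != cyt[None, :]).astype(float)
    ids = individuals["id"]
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    n: int
    null: np.ndarray | None = None


def mantel_kendall(
    d_geo,
    d_cyt,
    n_perm: int = 999,
    seed: int | None = None,
    keep_null: bool = False,
) -> MantelResult:
    """Mantel-type permutation test with Kendall's tau-b.

    ``r`` is tau-b between the strict lower-triangle entries of the two
    matrices; the null permutes individuals (rows and columns jointly) of
    the cytotype matrix ``n_perm`` times.  One-tailed (clustering) upper
    p-value with add-one correction:
    ``p = (#{null r >= observed} + 1) / (n_perm + 1)``.
    """
    G = _as_square(d_geo)
    C = _as_square(d_cyt)
    if G.shape != C.shape:
        raise ValueError("distance matrices are not conformable")
    n = G.shape[0]
    il = np.tril_indices(n, k=-1)
    g = G[il]
    c = C[il]
    if np.all(c == c[0]):
        raise ValueError("cytotype distance has zero variance")
    obs = stats.kendalltau(g, c).statistic
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        cp = C[np.ix_(perm, perm)][il]
        null[i] = stats.kendalltau(g, cp).statistic
    p = (np.sum(null >= obs) + 1) / (n_perm + 1)
    return MantelResult(
        r=float(obs), p=float(p), n_perm=n_perm, seed=seed, n=n,
        null=null if keep_null else None,
    )


def _as_square(d) -> np.ndarray:
    D = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    return D
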