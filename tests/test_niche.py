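"""Niche vectors, Pillai MANOVA (against definitional and library
oracles), PCA, and niche breadth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytozone import (
    compute_niche_matrix,
    niche_breadth,
    pca_niche,
    pillai_manova,
)
from cytozone.config import INDICATOR_NAMES


def _indicators(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(INDICATOR_NAMES))


# ---------------------------------------------------------------------------
# niche matrix

def test_single_species_plot_equals_its_indicator_values():
    indicators = _indicators({"spA": [2, 4, 3, 2, 2, 3]})
    plots = pd.DataFrame({"individual_id": ["i1"], "species": ["spA"]})
    niche = compute_niche_matrix(plots, indicators)
    assert list(niche.loc["i1"]) == [2, 4, 3, 2, 2, 3]


def test_per_indicator_missing_rule():
    """Means are taken per indicator over the species that have a value:
    T averages both species, L falls back to the one species with an L."""
    indicators = _indicators(
        {"spA": [1, 2, 3, 3, 3, 3], "spB": [4, np.nan, 3, 3, 3, 3]}
    )
    plots = pd.DataFrame(
        {"individual_id": ["i1", "i1"], "species": ["spA", "spB"]}
    )
    niche = compute_niche_matrix(plots, indicators)
    assert niche.loc["i1", "T"] == pytest.approx(2.5)
    assert niche.loc["i1", "L"] == pytest.approx(2.0)


def test_target_only_plot_dropped():
    indicators = _indicators({"spA": [2, 2, 2, 2, 2, 2]})
    plots = pd.DataFrame(
        {"individual_id": ["i1", "i2"], "species": ["target", "spA"]}
    )
    niche = compute_niche_matrix(plots, indicators, exclude_species={"target"})
    assert "i1" not in niche.index and "i2" in niche.index


# ---------------------------------------------------------------------------
# Pillai MANOVA

def _oracle_pillai(Y, codes):
    """Definitional oracle: eigenvalues of W^-1 B from cross-products."""
    grand = Y.mean(axis=0)
    p = Y.shape[1]
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for k in np.unique(codes):
        Yk = Y[codes == k]
        d = Yk.mean(axis=0) - grand
        B += len(Yk) * np.outer(d, d)
        R = Yk - Yk.mean(axis=0)
        W += R.T @ R
    lam = np.linalg.eigvals(np.linalg.inv(W) @ B)
    return float(np.sum(lam.real / (1 + lam.real)))


def test_pillai_matches_bruteforce_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        Y = rng.normal(size=(20, 6))
        codes = np.array([0] * 10 + [1] * 10)
        got = pillai_manova(Y, codes).pillai
        assert got == pytest.approx(_oracle_pillai(Y, codes), abs=1e-10)


def test_pillai_matches_statsmodels():
    from statsmodels.multivariate.manova import MANOVA

    rng = np.random.default_rng(2)
    Y = rng.normal(size=(30, 4))
    Y[:15] += 0.8
    g = np.array(["a"] * 15 + ["b"] * 15)
    res = pillai_manova(Y, g)
    sm = MANOVA(Y, pd.get_dummies(g, dtype=float).to_numpy())
    tbl = sm.mv_test(
        hypotheses=[("grp", np.array([[1.0, -1.0]]), None)]
    ).results["grp"]["stat"]
    assert res.pillai == pytest.approx(tbl.loc["Pillai's trace", "Value"], abs=1e-8)
    assert res.F == pytest.approx(tbl.loc["Pillai's trace", "F Value"], rel=1e-6)
    assert res.p == pytest.approx(tbl.loc["Pillai's trace", "Pr > F"], abs=1e-10)


def test_identical_group_distributions_give_zero_trace():
    rng = np.random.default_rng(3)
    block = rng.normal(size=(8, 6))
    Y = np.vstack([block, block])  # both groups hold the same rows
    codes = np.array([0] * 8 + [1] * 8)
    assert pillai_manova(Y, codes).pillai == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "sizes,df2",
    [((110, 165), 268), ((90, 91), 174), ((90, 74), 157), ((90, 26), 109), ((26, 74), 93)],
)
def test_degrees_of_freedom_two_groups_six_responses(sizes, df2):
    rng = np.random.default_rng(sum(sizes))
    Y = rng.normal(size=(sum(sizes), 6))
    codes = np.array([0] * sizes[0] + [1] * sizes[1])
    res = pillai_manova(Y, codes)
    assert (res.df1, res.df2) == (6, df2)
    assert res.df2 == res.n - 7


def test_one_response_two_groups_equals_eta_squared():
    rng = np.random.default_rng(4)
    y = rng.normal(size=40)
    y[:20] += 1.0
    codes = np.array([0] * 20 + [1] * 20)
    ssb = sum(
        20 * (y[codes == k].mean() - y.mean()) ** 2 for k in (0, 1)
    )
    sst = ((y - y.mean()) ** 2).sum()
    res = pillai_manova(y[:, None], codes)
    assert res.pillai == pytest.approx(ssb / sst, abs=1e-12)


def test_singular_within_matrix_raises():
    rng = np.random.default_rng(5)
    Y = rng.normal(size=(20, 3))
    Y = np.hstack([Y, Y[:, :1]])  # duplicated column -> singular W
    codes = np.array([0] * 10 + [1] * 10)
    with pytest.raises(ValueError, match="singular"):
        pillai_manova(Y, codes)


def test_null_label_shuffle_p_uniform():
    """With exchangeable labels the MANOVA p-value is uniform."""
    rng = np.random.default_rng(6)
    pvals = []
    for _ in range(200):
        Y = rng.normal(size=(40, 6))
        codes = rng.permutation(np.array([0] * 20 + [1] * 20))
        pvals.append(pillai_manova(Y, codes).p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# PCA

def test_perfectly_correlated_pair_loads_on_one_component():
    x = np.linspace(0, 1, 12)
    niche = pd.DataFrame({"T": x, "L": 2 * x + 1})
    pca = pca_niche(niche)
    assert pca.explained[0] == pytest.approx(1.0)


def test_loadings_orthonormal_and_explained_sums_to_one():
    rng = np.random.default_rng(7)
    niche = pd.DataFrame(rng.normal(size=(25, 6)), columns=list(INDICATOR_NAMES))
    pca = pca_niche(niche)
    L = pca.loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
    assert pca.explained.sum() == pytest.approx(1.0)
    # sign convention: each component's largest-|loading| entry is positive
    for j in range(L.shape[1]):
        assert L[np.abs(L[:, j]).argmax(), j] > 0


def test_explained_matches_correlation_eigenvalues():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(10, 6)) @ rng.normal(size=(6, 6))
    niche = pd.DataFrame(X, columns=list(INDICATOR_NAMES))
    pca = pca_niche(niche)
    eig = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    assert np.allclose(pca.explained, eig / eig.sum(), atol=1e-10)


def test_constant_column_dropped_with_warning(caplog):
    rng = np.random.default_rng(9)
    niche = pd.DataFrame(rng.normal(size=(10, 6)), columns=list(INDICATOR_NAMES))
    niche["H"] = 3.0
    with caplog.at_level("WARNING", logger="cytozone.niche"):
        pca = pca_niche(niche)
    assert "H" not in pca.loadings.index
    assert any("constant" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# niche breadth

def test_breadth_zero_at_centroid_and_symmetric_pair():
    scores = pd.DataFrame(
        {
            "PC1": [1.0, 1.0, 1.0, -2.0, 2.0],
            "PC2": [0.5, 0.5, 0.5, 0.0, 0.0],
        },
        index=["a1", "a2", "a3", "b1", "b2"],
    )
    pca = pca_niche(pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3))))
    pca.scores = scores  # inject a hand-built score matrix
    groups = pd.Series(["A", "A", "A", "B", "B"], index=scores.index)
    b = niche_breadth(pca, groups)
    assert b.loc["A", "mean_dist"] == pytest.approx(0.0)
    assert b.loc["B", "mean_dist"] == pytest.approx(2.0)  # symmetric about centroid
    assert b.loc["B", "se"] == pytest.approx(0.0)


def test_breadth_hand_computed_five_points():
    pts = np.array([[0, 0], [2, 0], [0, 2], [-2, 0], [0, -2]], dtype=float)
    scores = pd.DataFrame(pts, columns=["PC1", "PC2"], index=list("abcde"))
    pca = pca_niche(pd.DataFrame(np.random.default_rng(1).normal(size=(5, 3))))
    pca.scores = scores
    b = niche_breadth(pca, pd.Series(["g"] * 5, index=scores.index))
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    assert b.loc["g", "mean_dist"] == pytest.approx(d.mean())
    assert b.loc["g", "se"] == pytest.approx(d.std(ddof=1) / np.sqrt(5))


def test_breadth_single_member_group_has_missing_se():
    scores = pd.DataFrame({"PC1": [0.0, 1.0]}, index=["a", "b"])
    pca = pca_niche(pd.DataFrame(np.random.default_rng(2).normal(size=(2, 2))))
    pca.scores = scores
    b = niche_breadth(pca, pd.Series(["A", "B"], index=scores.index))
    assert np.isnan(b.loc["A", "se"])
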