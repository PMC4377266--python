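"""Generator contracts: determinism, value ranges, injected QC counts,
forced-genotype edge cases, and the niche-shift power surface."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytozone import (
    MarkerSimConfig,
    ZoneConfig,
    compute_niche_matrix,
    error_rate,
    gen_contact_zone,
    gen_marker_matrix,
    pillai_manova,
)


def _zone_cfg(seed=0, **kw):
    base = dict(
        n_per_cytotype={"2x": 15, "4x": 15},
        cluster_centers={"2x": (0.0, 0.0), "4x": (8.0, 0.0)},
        cluster_sd=2.0,
        gradient_vector=(0.05, 0.0),
        species_pool_size=30,
        seed=seed,
    )
    base.update(kw)
    return ZoneConfig(**base)


def test_zone_determinism_and_ranges():
    a = gen_contact_zone(_zone_cfg(seed=5))
    b = gen_contact_zone(_zone_cfg(seed=5))
    for ta, tb in zip(a[:3], b[:3]):
        pd.testing.assert_frame_equal(ta, tb)
    individuals, plots, indicators, truth = a
    assert individuals["id"].is_unique
    assert indicators.to_numpy().min() >= 1 and indicators.to_numpy().max() <= 5
    # every individual has at least one accompanying species
    assert set(individuals["id"]) == set(plots["individual_id"])
    c = gen_contact_zone(_zone_cfg(seed=6))
    assert not individuals.equals(c[0])


def test_zone_zero_individuals_rejected():
    with pytest.raises(ValueError):
        ZoneConfig(
            n_per_cytotype={"2x": 0, "4x": 0},
            cluster_centers={"2x": (0, 0), "4x": (0, 0)},
        )


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_zone_indicator_range_any_seed(seed):
    _, _, indicators, _ = gen_contact_zone(_zone_cfg(seed=seed))
    vals = indicators.to_numpy()
    assert ((vals >= 1) & (vals <= 5)).all()


def test_manova_power_at_stated_shift():
    """niche_shift 2.0 between two cytotypes, 50+50 individuals, 60-species
    pool: the MANOVA should reject at alpha=0.05 in at least 95% of 200
    simulated zones."""
    rejections = 0
    for seed in range(200):
        cfg = ZoneConfig(
            n_per_cytotype={"2x": 50, "4x": 50},
            cluster_centers={"2x": (0.0, 0.0), "4x": (0.0, 0.0)},
            cluster_sd=2.0,
            gradient_vector=(0.0, 0.0),
            niche_shift={"2x": 0.0, "4x": 2.0},
            species_pool_size=60,
            seed=seed,
        )
        individuals, plots, indicators, _ = gen_contact_zone(cfg)
        niche = compute_niche_matrix(plots, indicators)
        groups = individuals.set_index("id")["cytotype"].loc[niche.index]
        if pillai_manova(niche, groups).p < 0.05:
            rejections += 1
    assert rejections >= 0.95 * 200


# ---------------------------------------------------------------------------
# marker generator

def test_marker_determinism_and_binary():
    cfg = MarkerSimConfig(
        n_loci=40, class_counts={"Pure0": 10, "F2": 10}, flip_error=0.05,
        n_nonreproducible=3, n_singleton=2, n_monomorphic=5, n_replicates=4,
        seed=11,
    )
    a, ta = gen_marker_matrix(cfg)
    b, _ = gen_marker_matrix(cfg)
    pd.testing.assert_frame_equal(a.df, b.df)
    assert set(np.unique(a.df.to_numpy())) <= {0, 1}
    assert len(ta["injected"]["nonreproducible"]) == 3
    assert len(ta["injected"]["singleton"]) == 2
    assert len(ta["injected"]["monomorphic"]) == 5
    assert a.df.shape[1] == 40 + 3 + 2 + 5
    # injected singleton columns really carry exactly one band
    for name in ta["injected"]["singleton"]:
        assert a.df[name].sum() == 1


def test_replicates_error_free_when_no_flip_error():
    cfg = MarkerSimConfig(
        n_loci=30, class_counts={"Pure0": 8, "Pure1": 8},
        flip_error=0.0, n_replicates=5, seed=3,
    )
    mm, _ = gen_marker_matrix(cfg)
    rate, n_mis, n_cmp = error_rate(mm)
    assert rate == 0.0 and n_mis == 0 and n_cmp == 5 * 30


def test_forced_genotypes_pure_classes():
    """f0=0 (every pool-0 allele real) and f1=1 (every pool-1 allele null)
    force all-band Pure0 rows and all-blank Pure1 rows."""
    cfg = MarkerSimConfig(
        n_loci=25, f0=0.0, f1=1.0,
        class_counts={"Pure0": 6, "Pure1": 6}, flip_error=0.0, seed=1,
    )
    mm, truth = gen_marker_matrix(cfg)
    for ind, cls in truth["class"].items():
        row = mm.df.loc[ind].iloc[:25]
        assert (row == (1 if cls == "Pure0" else 0)).all()


def test_f1_band_guaranteed_when_one_pool_never_null():
    """An F1 carries one allele from each pool; with f1=0 the pool-1 copy is
    always non-null, so the band appears with probability 1."""
    cfg = MarkerSimConfig(
        n_loci=20, f0=1.0, f1=0.0, class_counts={"F1": 15},
        flip_error=0.0, seed=2,
    )
    mm, _ = gen_marker_matrix(cfg)
    assert (mm.df.to_numpy() == 1).all()


def test_f_length_mismatch_rejected():
    with pytest.raises(ValueError, match="n_loci"):
        MarkerSimConfig(n_loci=10, f0=[0.5] * 9)
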