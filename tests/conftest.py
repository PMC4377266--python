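"""Shared fixtures: small synthetic datasets and the one expensive
two-pool marker simulation + Gibbs fit reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytozone import (
    MarkerSimConfig,
    ZoneConfig,
    fit_hybrid_model,
    gen_contact_zone,
    gen_marker_matrix,
)


@pytest.fixture(scope="session")
def shifted_zone():
    """Two cytotypes with a clear niche shift along the gradient."""
    cfg = ZoneConfig(
        n_per_cytotype={"2x": 40, "4x": 40},
        cluster_centers={"2x": (0.0, 0.0), "4x": (12.0, 0.0)},
        cluster_sd=3.0,
        gradient_vector=(0.05, 0.0),
        niche_shift={"2x": -0.75, "4x": 0.75},
        species_pool_size=50,
        seed=42,
    )
    return gen_contact_zone(cfg)


@pytest.fixture(scope="session")
def null_zone():
    """Identical spatial clusters, no niche shift: full exchangeability."""
    cfg = ZoneConfig(
        n_per_cytotype={"2x": 30, "4x": 30},
        cluster_centers={"2x": (0.0, 0.0), "4x": (0.0, 0.0)},
        cluster_sd=3.0,
        gradient_vector=(0.05, 0.0),
        niche_shift={"2x": 0.0, "4x": 0.0},
        species_pool_size=40,
        seed=7,
    )
    return gen_contact_zone(cfg)


def two_pool_frequencies(n_loci: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Well-differentiated null-allele frequencies (mean |f0-f1| = 0.7)."""
    rng = np.random.default_rng(seed)
    half = np.arange(n_loci) % 2 == 0
    f0 = np.where(half, rng.uniform(0.05, 0.25, n_loci), rng.uniform(0.75, 0.95, n_loci))
    f1 = np.where(half, rng.uniform(0.75, 0.95, n_loci), rng.uniform(0.05, 0.25, n_loci))
    return f0, f1


@pytest.fixture(scope="session")
def two_pool_fit():
    """40+40 pure individuals plus 20 F1 at 200 strongly differentiated
    loci, fit at 20,000 sweeps / 2,000 burn-in.  Session-scoped: the fit
    is the package's costliest operation and several tests inspect it.
    """
    f0, f1 = two_pool_frequencies(200, seed=101)
    assert np.abs(f0 - f1).mean() >= 0.6
    cfg = MarkerSimConfig(
        n_loci=200,
        f0=f0,
        f1=f1,
        class_counts={"Pure0": 40, "Pure1": 40, "F1": 20},
        flip_error=0.0,
        seed=202,
    )
    markers, truth = gen_marker_matrix(cfg)
    posterior = fit_hybrid_model(markers, n_sweeps=20_000, burn_in=2_000, seed=303)
    return markers, truth, posterior


def align_pure_labels(posterior, truth):
    """Resolve parental label switching against the simulation truth."""
    from cytozone import orient_posterior

    cyt = pd.Series(
        {i: ("P0" if c == "Pure0" else "other") for i, c in truth["class"].items()}
    )
    return orient_posterior(posterior, cyt, "P0")
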