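"""Synthetic contact-zone and dominant-marker generators with known truth.

The zone generator lays cytotype-specific Gaussian spatial clusters on a
plane crossed by a latent environmental gradient.  Accompanying species
respond unimodally to the local environment — presence probability is a
logistic function, exp-quadratic in (local gradient value − species
optimum) — and carry ordinal indicator values tied to their optima, so
cytotype niche separation in downstream mean-indicator analyses scales
with the configured per-cytotype gradient shift.

The marker generator draws per-locus ancestry states from each hybrid
category's Mendelian expectations, genotypes from the pool null-allele
frequencies, observes a band iff at least one copy is non-null, applies
a per-call flip error, duplicates replicate profiles with independent
error, and appends flagged nonreproducible / singleton / monomorphic
fragments so QC filters have a known answer.

Both generators are byte-reproducible given the same config and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import INDICATOR_NAMES, MarkerSimConfig, ZoneConfig
from .hybrids import PHI_TABLE
from .io import MarkerMatrix

#: Per-indicator coupling of species indicator values to the gradient.
#: Varied strengths keep the six responses correlated but not collinear.
_INDICATOR_COUPLING = (1.0, 0.8, 0.6, 0.5, 0.4, 0.3)
_INDICATOR_NOISE_SD = 0.6


def gen_contact_zone(config: ZoneConfig):
    """Generate a synthetic contact zone.

    Returns ``(individuals, plots, indicators, truth)``: the individual
    table (id, x, y, cytotype), long-form plot composition, species
    indicator table, and a truth record holding every generating
    parameter plus the latent per-individual environment and species
    optima.
    """
    rng = np.random.default_rng(config.seed)
    cytotypes = [c for c in config.n_per_cytotype if config.n_per_cytotype[c] > 0]

    ids, xs, ys, labels = [], [], [], []
    k = 0
    for cyt in cytotypes:
        n = config.n_per_cytotype[cyt]
        center = np.asarray(config.cluster_centers[cyt], dtype=float)
        pos = rng.normal(center, config.cluster_sd, size=(n, 2))
        for row in pos:
            k += 1
            ids.append(f"ind{k:04d}")
            xs.append(float(row[0]))
            ys.append(float(row[1]))
            labels.append(cyt)
    individuals = pd.DataFrame({"id": ids, "x": xs, "y": ys, "cytotype": labels})

    gv = np.asarray(config.gradient_vector, dtype=float)
    pos = individuals[["x", "y"]].to_numpy()
    shift = np.array([config.niche_shift[c] for c in labels])
    env = pos @ gv + shift + rng.normal(0.0, config.env_sd, size=len(ids))

    # species pool: optima spread over the realised gradient range
    lo, hi = env.min() - 0.5, env.max() + 0.5
    optima = rng.uniform(lo, hi, size=config.species_pool_size)
    span = hi - lo if hi > lo else 1.0
    scaled = 1.0 + 4.0 * (optima - lo) / span  # optimum mapped onto [1, 5]
    species = [f"sp{j + 1:03d}" for j in range(config.species_pool_size)]
    ind_values = {}
    for name, alpha in zip(INDICATOR_NAMES, _INDICATOR_COUPLING):
        raw = 3.0 + alpha * (scaled - 3.0) + rng.normal(
            0.0, _INDICATOR_NOISE_SD, size=len(species)
        )
        ind_values[name] = np.clip(np.rint(raw), 1, 5)
    indicators = pd.DataFrame(ind_values, index=pd.Index(species, name="species"))

    # presence: logistic response, exp-quadratic in (environment - optimum)
    d = (env[:, None] - optima[None, :]) / config.species_response_width
    prob = expit(config.richness_offset - 0.5 * d**2)
    pres = rng.random(prob.shape) < prob
    # every plot keeps at least one accompanying species: add the species
    # with the highest presence probability where sampling produced none
    empty = ~pres.any(axis=1)
    if empty.any():
        pres[np.where(empty)[0], prob[empty].argmax(axis=1)] = True
    ii, jj = np.nonzero(pres)
    plots = pd.DataFrame(
        {
            "individual_id": [ids[i] for i in ii],
            "species": [species[j] for j in jj],
        }
    )

    truth = {
        "config": config.to_dict(),
        "env": {i: float(e) for i, e in zip(ids, env)},
        "species_optima": {s: float(o) for s, o in zip(species, optima)},
        "mean_richness": float(pres.sum(axis=1).mean()),
    }
    return individuals, plots, indicators, truth


def gen_marker_matrix(config: MarkerSimConfig, ids=None, class_labels=None):
    """Generate a dominant binary marker matrix with known hybrid classes.

    Returns ``(MarkerMatrix, truth)``; ``truth['class']`` maps each
    individual id to its true category, ``truth['injected']`` lists the
    flagged / singleton / monomorphic locus ids.  ``ids`` and
    ``class_labels`` optionally name the rows and assign categories per
    individual (overriding ``class_counts``).
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_loci

    if class_labels is not None:
        class_labels = list(class_labels)
    else:
        class_labels = [
            cls for cls in config.class_counts for _ in range(config.class_counts[cls])
        ]
    n = len(class_labels)
    if n == 0:
        raise ValueError("zero individuals total")
    if ids is None:
        ids = [f"ind{i + 1:03d}" for i in range(n)]
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValueError("ids and class labels differ in length")

    f0 = config.f0 if config.f0 is not None else rng.beta(config.beta_a, config.beta_b, L)
    f1 = config.f1 if config.f1 is not None else rng.beta(config.beta_a, config.beta_b, L)
    f0 = np.asarray(f0, dtype=float)
    f1 = np.asarray(f1, dtype=float)

    phi = PHI_TABLE.loc[class_labels].to_numpy()  # (n, 3)
    # ancestry state per cell, then no-band probability given the state
    u = rng.random((n, L))
    cum = phi.cumsum(axis=1)
    state = (cum[:, None, :2] < u[:, :, None]).sum(axis=2)  # (n, L) in {0,1,2}
    nb_states = np.stack([f0**2, f0 * f1, f1**2], axis=-1)  # (L, 3)
    p_no_band = np.take_along_axis(
        np.broadcast_to(nb_states, (n, L, 3)), state[:, :, None], axis=2
    )[:, :, 0]
    true_pheno = (rng.random((n, L)) >= p_no_band).astype(np.int8)

    def observe(true_rows):
        flips = rng.random(true_rows.shape) < config.flip_error
        return np.where(flips, 1 - true_rows, true_rows).astype(np.int8)

    observed = observe(true_pheno)

    n_rep = min(config.n_replicates, n)
    rep_sources = list(range(n_rep))
    rep_rows = observe(true_pheno[rep_sources]) if n_rep else np.empty((0, L), np.int8)

    # injected QC fragments (appended after the informative loci)
    inj_cols = []
    inj_names: list[str] = []
    flags: dict[str, str] = {}
    injected = {"nonreproducible": [], "singleton": [], "monomorphic": []}
    n_rows = n + n_rep
    for j in range(config.n_nonreproducible):
        name = f"NR{j + 1:03d}"
        inj_cols.append(rng.integers(0, 2, size=n_rows).astype(np.int8))
        inj_names.append(name)
        flags[name] = "nonreproducible"
        injected["nonreproducible"].append(name)
    # singleton carriers are non-replicated individuals so the band count
    # over rows stays exactly one
    carrier_pool = np.arange(n_rep, n) if n > n_rep else np.arange(n)
    for j in range(config.n_singleton):
        name = f"SG{j + 1:03d}"
        col = np.zeros(n_rows, dtype=np.int8)
        col[int(rng.choice(carrier_pool))] = 1
        inj_cols.append(col)
        inj_names.append(name)
        injected["singleton"].append(name)
    for j in range(config.n_monomorphic):
        name = f"MM{j + 1:03d}"
        fill = np.int8(j % 2)
        inj_cols.append(np.full(n_rows, fill, dtype=np.int8))
        inj_names.append(name)
        injected["monomorphic"].append(name)

    all_ids = ids + [f"{ids[i]}_rep" for i in rep_sources]
    base = np.vstack([observed, rep_rows]) if n_rep else observed
    if inj_cols:
        base = np.hstack([base, np.column_stack(inj_cols)])
    loci = [f"L{j + 1:03d}" for j in range(L)] + inj_names
    df = pd.DataFrame(base, index=pd.Index(all_ids, name="id"), columns=loci)

    links = [(ids[i], f"{ids[i]}_rep") for i in rep_sources]
    locus_flags = pd.Series(
        [flags.get(c, "reproducible") for c in loci], index=df.columns
    )
    n_flagged = min(config.n_flagged_individuals, n)
    flagged_ids = ids[n - n_flagged:] if n_flagged else []
    individual_flags = pd.Series(
        ["nonreproducible" if i in set(flagged_ids) else "ok" for i in all_ids],
        index=df.index,
    )
    mm = MarkerMatrix(df, links, locus_flags, individual_flags)
    truth = {
        "config": config.to_dict(),
        "class": dict(zip(ids, class_labels)),
        "f0": f0.tolist(),
        "f1": f1.tolist(),
        "injected": injected,
        "flagged_individuals": list(flagged_ids),
    }
    return mm, truth
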