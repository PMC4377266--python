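"""Marker QC and Bayesian hybrid-category inference from dominant markers.

Dominant fingerprints (AFLP-like band phenotypes) observe only band
presence/absence per locus: a band appears iff at least one of the two
gene copies carries a non-null allele.  Each individual belongs to one
of six hybrid categories — the two pure parental classes, F1, F2 and the
two first-generation backcrosses — and each category fixes, by Mendelian
expectation, the probability phi that a locus carries (both copies from
pool 0, one from each, both from pool 1).  With per-locus null-allele
frequencies ``f0``/``f1`` in the parental gene pools, the no-band
probability given a category is ``phi0*f0^2 + phi1*f0*f1 + phi2*f1^2``.

Inference is by Gibbs sampling with latent-genotype augmentation:

1. category ``z_i`` from its conditional given ``f``, mixing weights
   ``pi`` and the individual's phenotypes (latent genotypes marginalised
   through the closed-form band probability);
2. per-(individual, locus) ancestry state and null/non-null allele pair
   given ``z`` and the phenotype;
3. conjugate Beta updates of ``f0``, ``f1`` from latent allele counts;
4. Dirichlet update of ``pi`` from category counts.

Posterior class probabilities are post-burn-in visit frequencies of
``z``.  The two-allele (diploid-equivalent) likelihood is applied to all
cytotypes; allele dosage in polyploids is deliberately not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CLASS_NAMES
from .io import MarkerMatrix, SchemaError

logger = logging.getLogger("cytozone.hybrids")

HYBRID_CLASSES = CLASS_NAMES

#: Expected proportions of per-locus ancestry states (both copies from
#: pool 0 / one from each / both from pool 1) for each hybrid category.
PHI_TABLE = pd.DataFrame(
    [
        [1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 1.0, 0.0],
        [0.25, 0.5, 0.25],
        [0.5, 0.5, 0.0],
        [0.0, 0.5, 0.5],
    ],
    index=list(HYBRID_CLASSES),
    columns=["p00", "p01", "p11"],
)


def band_prob(phi_row, f0, f1):
    """Probability of band presence given ancestry proportions and null-allele
    frequencies.

    ``P(no band) = phi0*f0**2 + phi1*f0*f1 + phi2*f1**2``; the band is seen
    iff at least one gene copy is non-null.  Broadcasts over array inputs.
    """
    phi = np.asarray(phi_row, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    no_band = phi[..., 0] * f0**2 + phi[..., 1] * f0 * f1 + phi[..., 2] * f1**2
    return 1.0 - no_band


# ---------------------------------------------------------------------------
# QC

def error_rate(markers: MarkerMatrix) -> tuple[float, int, int]:
    """Replicate mismatch rate: mismatches over phenotypic comparisons
    across all replicate pairs and loci scored in both profiles.
    """
    if not markers.replicate_links:
        raise ValueError("no replicate pairs available for error-rate estimation")
    n_mismatch = 0
    n_comparisons = 0
    for a, b in markers.replicate_links:
        pa = markers.df.loc[a].to_numpy()
        pb = markers.df.loc[b].to_numpy()
        n_mismatch += int(np.sum(pa != pb))
        n_comparisons += pa.size
    return n_mismatch / n_comparisons, n_mismatch, n_comparisons


@dataclass
class FilterReport:
    n_total: int
    n_nonreproducible: int
    n_monomorphic: int
    n_singleton: int
    n_retained: int
    removed: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert (
            self.n_nonreproducible + self.n_monomorphic + self.n_singleton
            + self.n_retained == self.n_total
        )


def filter_markers(markers: MarkerMatrix) -> tuple[MarkerMatrix, FilterReport]:
    """Remove, in order: loci flagged nonreproducible; monomorphic loci;
    singleton loci (band present — or absent — in exactly one individual).
    """
    df = markers.df
    n_total = df.shape[1]
    nonrep = df.columns[(markers.locus_flags == "nonreproducible").to_numpy()]
    df = df.drop(columns=nonrep)
    sums = df.sum(axis=0)
    n = df.shape[0]
    mono = df.columns[(sums == 0) | (sums == n)]
    df = df.drop(columns=mono)
    sums = df.sum(axis=0)
    single = df.columns[(sums == 1) | (sums == n - 1)]
    df = df.drop(columns=single)
    if df.shape[1] == 0:
        logger.warning("fragment filter removed every locus")
    report = FilterReport(
        n_total=n_total,
        n_nonreproducible=len(nonrep),
        n_monomorphic=len(mono),
        n_singleton=len(single),
        n_retained=df.shape[1],
        removed={
            "nonreproducible": list(nonrep),
            "monomorphic": list(mono),
            "singleton": list(single),
        },
    )
    filtered = MarkerMatrix(
        df,
        replicate_links=list(markers.replicate_links),
        locus_flags=markers.locus_flags.reindex(df.columns),
        individual_flags=markers.individual_flags.copy(),
    )
    return filtered, report


def filter_individuals(
    markers: MarkerMatrix, flagged=None
) -> tuple[MarkerMatrix, list[str]]:
    """Drop individuals with nonreproducible profiles (by flag or explicit
    list); replicate links touching a removed row are pruned.
    """
    if flagged is None:
        flagged = markers.individual_flags.index[
            (markers.individual_flags == "nonreproducible").to_numpy()
        ]
    flagged = [str(x) for x in flagged]
    keep = [i for i in markers.df.index if i not in set(flagged)]
    links = [
        (a, b)
        for a, b in markers.replicate_links
        if a not in set(flagged) and b not in set(flagged)
    ]
    out = MarkerMatrix(
        markers.df.loc[keep],
        replicate_links=links,
        locus_flags=markers.locus_flags.copy(),
        individual_flags=markers.individual_flags.reindex(keep),
    )
    return out, flagged


def drop_replicate_rows(markers: MarkerMatrix) -> MarkerMatrix:
    """Keep the first profile of each replicate pair, drop the second."""
    drop = {b for _, b in markers.replicate_links}
    keep = [i for i in markers.df.index if i not in drop]
    return MarkerMatrix(
        markers.df.loc[keep],
        replicate_links=[],
        locus_flags=markers.locus_flags.copy(),
        individual_flags=markers.individual_flags.reindex(keep),
    )


# ---------------------------------------------------------------------------
# Gibbs sampler

@dataclass
class HybridPosterior:
    """Posterior over hybrid categories for each individual.

    ``probs`` rows sum to one; ``modal`` is the argmax with ties broken
    by fixed class order (logged).  ``traces`` holds thinned mixing-
    weight samples and running null-allele frequency means for
    convergence inspection.
    """

    probs: pd.DataFrame
    modal: pd.Series
    pi_mean: pd.Series
    f_mean: pd.DataFrame
    traces: dict
    n_sweeps: int
    burn_in: int
    seed: int | None
    ties: list[str] = field(default_factory=list)

    @property
    def classes(self) -> list[str]:
        return list(self.probs.columns)


def fit_hybrid_model(
    markers,
    n_sweeps: int = 100_000,
    burn_in: int = 10_000,
    seed: int | None = None,
    classes=HYBRID_CLASSES,
    prior: str = "uniform",
    fixed_f=None,
    fixed_pi=None,
    init_z=None,
    record_every: int = 200,
) -> HybridPosterior:
    """Fit the dominant-marker hybrid-category mixture by Gibbs sampling.

    Parameters
    ----------
    markers
        :class:`MarkerMatrix`, DataFrame or 0/1 array (individuals x loci).
    n_sweeps, burn_in
        Total sweeps and discarded initial sweeps.  The desk-scale
        default is 100,000 / 10,000; long production runs (e.g. 1.3e6 /
        1e5) are just parameters.
    prior
        'uniform' (Beta(1,1), Dirichlet(1)) or 'jeffreys' (Beta(1/2,1/2),
        Dirichlet(1/2)).
    fixed_f, fixed_pi
        Optionally hold the null-allele frequencies ((2, L) array) or the
        mixing weights fixed instead of sampling them — used for validation
        against exhaustive enumeration.
    init_z
        Optional initial class labels (names or indices); default random.
    """
    X, ids, loci = _as_phenotype_array(markers)
    n, L = X.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if L < 1:
        raise ValueError("need at least 1 locus")
    classes = list(classes)
    C = len(classes)
    phi = PHI_TABLE.loc[classes].to_numpy()
    if prior == "uniform":
        beta_prior, dir_prior = 1.0, 1.0
    elif prior == "jeffreys":
        beta_prior, dir_prior = 0.5, 0.5
    else:
        raise ValueError(f"unknown prior {prior!r}")

    rng = np.random.default_rng(seed)
    if fixed_f is not None:
        f = np.asarray(fixed_f, dtype=float).reshape(2, L).copy()
    else:
        f = rng.uniform(0.1, 0.9, size=(2, L))
    if fixed_pi is not None:
        pi = np.asarray(fixed_pi, dtype=float)
        pi = pi / pi.sum()
    else:
        pi = np.full(C, 1.0 / C)
    if init_z is not None:
        z = np.asarray(
            [classes.index(c) if isinstance(c, str) else int(c) for c in init_z]
        )
        if z.shape != (n,):
            raise ValueError("init_z length mismatch")
    else:
        z = rng.integers(0, C, size=n)

    Xb = X.astype(bool)
    Xf = X.astype(float)
    counts = np.zeros((n, C))
    f_sum = np.zeros((2, L))
    pi_sum = np.zeros(C)
    pi_trace = []
    f_trace = []
    n_kept = 0
    eps = 1e-12

    for sweep in range(n_sweeps):
        fc = np.clip(f, 1e-9, 1 - 1e-9)
        s00 = fc[0] ** 2
        s01 = fc[0] * fc[1]
        s11 = fc[1] ** 2
        # (1) ancestry state a in {00, 01, 11} per cell | z, phenotype
        q = np.stack([s00, s01, s11], axis=-1)  # (L, 3): no-band prob per state
        Q = np.where(Xb[:, :, None], 1.0 - q, q)
        P = phi[z][:, None, :] * Q
        P /= np.clip(P.sum(axis=-1, keepdims=True), eps, None)
        a = (P.cumsum(axis=-1) < rng.random((n, L, 1))).sum(axis=-1)

        # (2) latent alleles | a, phenotype -> null / non-null counts per pool
        u = rng.random((n, L))
        f0l = fc[0][None, :]
        f1l = fc[1][None, :]
        # no band: every copy is null; copies from pool0 = 2 - a, pool1 = a
        null0 = (2 - a).astype(np.int64)
        null1 = a.astype(np.int64)
        nn0 = np.zeros((n, L), dtype=np.int64)
        nn1 = np.zeros((n, L), dtype=np.int64)
        # band present: condition on >= 1 non-null copy
        m0 = Xb & (a == 0)  # both copies from pool 0
        k = (u < 2 * f0l / (1 + f0l)).astype(np.int64)  # one null vs zero null
        null0 = np.where(m0, k, null0)
        nn0 = np.where(m0, 2 - k, nn0)
        null1 = np.where(m0, 0, null1)
        m2 = Xb & (a == 2)
        k = (u < 2 * f1l / (1 + f1l)).astype(np.int64)
        null1 = np.where(m2, k, null1)
        nn1 = np.where(m2, 2 - k, nn1)
        null0 = np.where(m2, 0, null0)
        m1 = Xb & (a == 1)  # one copy from each pool, not both null
        zden = 1.0 - f0l * f1l
        t_both = (1 - f0l) * (1 - f1l) / zden
        t_p0null = t_both + f0l * (1 - f1l) / zden
        c0null = (u >= t_both) & (u < t_p0null)
        c1null = u >= t_p0null
        null0 = np.where(m1, c0null.astype(np.int64), null0)
        nn0 = np.where(m1, 1 - c0null.astype(np.int64), nn0)
        null1 = np.where(m1, c1null.astype(np.int64), null1)
        nn1 = np.where(m1, 1 - c1null.astype(np.int64), nn1)

        # (3) conjugate updates of f and pi from the latent counts
        if fixed_f is None:
            f[0] = rng.beta(beta_prior + null0.sum(axis=0), beta_prior + nn0.sum(axis=0))
            f[1] = rng.beta(beta_prior + null1.sum(axis=0), beta_prior + nn1.sum(axis=0))
        if fixed_pi is None:
            zc = np.bincount(z, minlength=C)
            pi = rng.dirichlet(dir_prior + zc)

        # (4) z | f, pi — latent genotypes marginalised analytically, so the
        # class update conditions on the freshly sampled frequencies
        fc = np.clip(f, 1e-9, 1 - 1e-9)
        no_band = (
            phi[:, [0]] * fc[0] ** 2
            + phi[:, [1]] * fc[0] * fc[1]
            + phi[:, [2]] * fc[1] ** 2
        )  # (C, L)
        no_band = np.clip(no_band, eps, 1 - eps)
        loglik = Xf @ np.log1p(-no_band).T + (1.0 - Xf) @ np.log(no_band).T
        loglik += np.log(np.clip(pi, eps, None))
        loglik -= loglik.max(axis=1, keepdims=True)
        pz = np.exp(loglik)
        pz /= pz.sum(axis=1, keepdims=True)
        z = (pz.cumsum(axis=1) < rng.random((n, 1))).sum(axis=1)

        if sweep >= burn_in:
            counts[np.arange(n), z] += 1
            f_sum += f
            pi_sum += pi
            n_kept += 1
        if sweep % record_every == 0:
            pi_trace.append(pi.copy())
            f_trace.append(f.mean(axis=1))

    probs = pd.DataFrame(counts / n_kept, index=ids, columns=classes)
    modal_idx = probs.to_numpy().argmax(axis=1)
    ties = []
    row_max = probs.to_numpy().max(axis=1)
    n_at_max = (probs.to_numpy() == row_max[:, None]).sum(axis=1)
    for i in np.where(n_at_max > 1)[0]:
        ties.append(str(ids[i]))
        logger.info(
            "modal-class tie for %s broken by class order -> %s",
            ids[i], classes[modal_idx[i]],
        )
    modal = pd.Series([classes[i] for i in modal_idx], index=ids, name="modal_class")
    return HybridPosterior(
        probs=probs,
        modal=modal,
        pi_mean=pd.Series(pi_sum / n_kept, index=classes),
        f_mean=pd.DataFrame(f_sum / n_kept, index=["f0", "f1"], columns=loci),
        traces={"pi": np.array(pi_trace), "f_mean": np.array(f_trace)},
        n_sweeps=n_sweeps,
        burn_in=burn_in,
        seed=seed,
        ties=ties,
    )


def orient_posterior(
    posterior: HybridPosterior, cytotypes: pd.Series, parent0_cytotype: str
) -> HybridPosterior:
    """Resolve parental label switching: relabel so that ``Pure0`` is the
    pure class favoured by individuals of ``parent0_cytotype`` (and
    ``BC0`` its backcross).  Returns a new posterior; no-op when already
    oriented or when the pure classes are absent.
    """
    cols = list(posterior.probs.columns)
    if "Pure0" not in cols or "Pure1" not in cols:
        return posterior
    anchor = [i for i in posterior.probs.index if cytotypes.get(i) == parent0_cytotype]
    if not anchor:
        return posterior
    sub = posterior.probs.loc[anchor]
    if sub["Pure0"].mean() >= sub["Pure1"].mean():
        return posterior
    swap = {"Pure0": "Pure1", "Pure1": "Pure0", "BC0": "BC1", "BC1": "BC0"}
    probs = posterior.probs.rename(columns=swap)[cols]
    modal = probs.columns[probs.to_numpy().argmax(axis=1)]
    pi_mean = posterior.pi_mean.rename(swap).reindex(cols)
    f_mean = posterior.f_mean.rename(index={"f0": "f1", "f1": "f0"}).reindex(["f0", "f1"])
    return HybridPosterior(
        probs=probs,
        modal=pd.Series(modal, index=probs.index, name="modal_class"),
        pi_mean=pi_mean,
        f_mean=f_mean,
        traces=posterior.traces,
        n_sweeps=posterior.n_sweeps,
        burn_in=posterior.burn_in,
        seed=posterior.seed,
        ties=posterior.ties,
    )


def summarize_classes(posterior, cytotypes: pd.Series, classes=None) -> pd.DataFrame:
    """Per cytotype x hybrid class: count of individuals whose modal class
    is that class, and percentage of the cytotype's total (long form).
    ``posterior`` may be a :class:`HybridPosterior` or a modal-class Series.
    """
    if isinstance(posterior, HybridPosterior):
        modal = posterior.modal
        classes = classes or posterior.classes
    else:
        modal = pd.Series(posterior)
        classes = classes or list(HYBRID_CLASSES)
    cytotypes = pd.Series(cytotypes)
    missing = [i for i in modal.index if i not in cytotypes.index]
    if missing:
        raise ValueError(f"no cytotype label for individual(s) {missing[:3]}")
    rows = []
    for cyt in sorted(cytotypes.loc[modal.index].unique()):
        members = modal.index[(cytotypes.loc[modal.index] == cyt).to_numpy()]
        total = len(members)
        vc = modal.loc[members].value_counts()
        for cls in classes:
            cnt = int(vc.get(cls, 0))
            rows.append(
                {
                    "cytotype": cyt,
                    "hybrid_class": cls,
                    "count": cnt,
                    "pct": 100.0 * cnt / total if total else float("nan"),
                    "n_cytotype": total,
                }
            )
    return pd.DataFrame(rows)


def _as_phenotype_array(markers):
    if isinstance(markers, MarkerMatrix):
        df = markers.df
        return df.to_numpy(dtype=np.int8), df.index, df.columns
    if isinstance(markers, pd.DataFrame):
        df = markers
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise SchemaError("marker phenotypes must be strictly 0/1")
        return values.astype(np.int8), df.index, df.columns
    arr = np.asarray(markers)
    if not np.isin(arr, (0, 1)).all():
        raise SchemaError("marker phenotypes must be strictly 0/1")
    n, L = arr.shape
    ids = pd.Index([f"ind{i:03d}" for i in range(n)])
    loci = pd.Index([f"L{j:03d}" for j in range(L)])
    return arr.astype(np.int8), ids, loci
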