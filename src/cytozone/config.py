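"""Configuration objects for the synthetic contact-zone generators.

Both configs are plain frozen-ish dataclasses with eager validation in
``__post_init__`` so that a bad parameter fails at construction time,
not deep inside a simulation loop.  The same seed and config always
reproduce the identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

#: The six indicator dimensions: temperature, light, soil moisture,
#: soil reaction, nutrients, humus.  Ordinal 1 (low) .. 5 (high).
INDICATOR_NAMES = ("T", "L", "F", "R", "N", "H")

#: Hybrid-category labels in fixed order.  Pure0/Pure1 are the parental
#: gene pools, BC0/BC1 the first-generation backcrosses to them.
CLASS_NAMES = ("Pure0", "Pure1", "F1", "F2", "BC0", "BC1")


@dataclass
class ZoneConfig:
    """Parameters of a synthetic mixed-ploidy contact zone.

    The zone is laid out on a 2-D plane (metres).  Each cytotype draws
    its individuals from an isotropic Gaussian spatial cluster.  A
    latent environmental gradient runs along ``gradient_vector`` (units:
    indicator value per metre); each individual's local environment is
    the gradient evaluated at its position, displaced by its cytotype's
    ``niche_shift`` and jittered by ``env_sd``.  Accompanying species
    respond unimodally to the environment, so cytotype niche separation
    scales with the shift.
    """

    n_per_cytotype: Mapping[str, int]
    cluster_centers: Mapping[str, Sequence[float]]
    cluster_sd: float = 3.0
    gradient_vector: Sequence[float] = (0.1, 0.0)
    niche_shift: Mapping[str, float] | None = None
    species_pool_size: int = 60
    species_response_width: float = 1.0
    plot_radius: float = 0.2
    env_sd: float = 0.25
    richness_offset: float = -0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_cytotype = dict(self.n_per_cytotype)
        self.cluster_centers = {
            k: tuple(float(c) for c in v) for k, v in self.cluster_centers.items()
        }
        if self.niche_shift is None:
            self.niche_shift = {k: 0.0 for k in self.n_per_cytotype}
        self.niche_shift = dict(self.niche_shift)
        for cyt, n in self.n_per_cytotype.items():
            if n < 0:
                raise ValueError(f"negative count for cytotype {cyt!r}")
            if cyt not in self.cluster_centers:
                raise ValueError(f"no cluster center for cytotype {cyt!r}")
            self.niche_shift.setdefault(cyt, 0.0)
        if sum(self.n_per_cytotype.values()) == 0:
            raise ValueError("zero individuals total")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be > 0")
        if self.plot_radius <= 0:
            raise ValueError("plot_radius must be > 0")
        if self.species_pool_size < 1:
            raise ValueError("species_pool_size must be >= 1")
        if self.species_response_width <= 0:
            raise ValueError("species_response_width must be > 0")
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MarkerSimConfig:
    """Parameters of a synthetic dominant (band presence/absence) marker set.

    ``f0``/``f1`` are per-locus frequencies of the *null* (band-absence)
    allele in the two parental gene pools.  They may be given as arrays
    of length ``n_loci``, as scalars, or left None to be drawn from
    Beta distributions (``beta_a``, ``beta_b``) independently per pool.
    ``class_counts`` maps hybrid-category labels to individual counts.
    Nonreproducible / singleton / monomorphic fragments are appended
    after the informative loci and flagged in the truth record so the
    QC filters have a known answer.
    """

    n_loci: int = 100
    f0: Sequence[float] | float | None = None
    f1: Sequence[float] | float | None = None
    class_counts: Mapping[str, int] = field(default_factory=lambda: {"Pure0": 20, "Pure1": 20})
    flip_error: float = 0.0
    n_nonreproducible: int = 0
    n_singleton: int = 0
    n_monomorphic: int = 0
    n_replicates: int = 0
    n_flagged_individuals: int = 0
    beta_a: float = 0.5
    beta_b: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        self.class_counts = dict(self.class_counts)
        for cls, n in self.class_counts.items():
            if cls not in CLASS_NAMES:
                raise ValueError(f"unknown hybrid class {cls!r}")
            if n < 0:
                raise ValueError(f"negative count for class {cls!r}")
        if not 0.0 <= self.flip_error <= 1.0:
            raise ValueError("flip_error must be in [0, 1]")
        for name in ("n_nonreproducible", "n_singleton", "n_monomorphic",
                     "n_replicates", "n_flagged_individuals"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("f0", "f1"):
            val = getattr(self, name)
            if val is None:
                continue
            arr = np.atleast_1d(np.asarray(val, dtype=float))
            if arr.size == 1:
                arr = np.full(self.n_loci, float(arr[0]))
            if arr.size != self.n_loci:
                raise ValueError(f"{name} length {arr.size} != n_loci {self.n_loci}")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} values must be in [0, 1]")
            setattr(self, name, arr)

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("f0", "f1"):
            if isinstance(d[name], np.ndarray):
                d[name] = d[name].tolist()
        return d
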