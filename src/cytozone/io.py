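"""Readers and writers for the tabular formats used throughout the pipeline.

All tables are plain delimited text with a header row:

* individuals — TSV ``id, x, y, cytotype``
* plot composition — long-form TSV ``individual_id, species``
* indicator values — TSV ``species, T, L, F, R, N, H`` (empty cell = missing)
* marker matrix — CSV, first column ``id``, remaining columns loci (0/1),
  with sidecar TSVs ``<stem>.replicates.tsv`` (columns ``rep_a, rep_b``),
  ``<stem>.locus_flags.tsv`` (``locus, flag``) and
  ``<stem>.individual_flags.tsv`` (``id, flag``)

Every writer/reader pair round-trips to an identical table with a
deterministic column order.  Schema violations raise :class:`SchemaError`
naming the offending row/column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import INDICATOR_NAMES

INDIVIDUAL_COLUMNS = ["id", "x", "y", "cytotype"]
PLOT_COLUMNS = ["individual_id", "species"]
INDICATOR_COLUMNS = ["species", *INDICATOR_NAMES]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass
class MarkerMatrix:
    """Binary marker phenotypes (individuals x loci) plus QC metadata.

    ``df`` holds strictly 0/1 band phenotypes.  ``replicate_links`` are
    pairs of row ids that are independent profiles of the same sample.
    ``locus_flags`` / ``individual_flags`` carry reproducibility labels
    ('reproducible'/'ok' or 'nonreproducible') used by the QC filters.
    """

    df: pd.DataFrame
    replicate_links: list[tuple[str, str]] = field(default_factory=list)
    locus_flags: pd.Series | None = None
    individual_flags: pd.Series | None = None

    def __post_init__(self) -> None:
        values = self.df.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"non-binary marker cell {values[i, j]!r} at individual "
                f"{self.df.index[i]!r}, locus {self.df.columns[j]!r}"
            )
        self.df = self.df.astype(np.int8)
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise SchemaError(f"duplicate individual id {dup!r} in marker matrix")
        ids = set(self.df.index)
        for a, b in self.replicate_links:
            if a not in ids or b not in ids:
                raise SchemaError(f"replicate link ({a!r}, {b!r}) references a missing row")
        if self.locus_flags is None:
            self.locus_flags = pd.Series("reproducible", index=self.df.columns)
        else:
            self.locus_flags = pd.Series(self.locus_flags).reindex(
                self.df.columns, fill_value="reproducible"
            )
        if self.individual_flags is None:
            self.individual_flags = pd.Series("ok", index=self.df.index)
        else:
            self.individual_flags = pd.Series(self.individual_flags).reindex(
                self.df.index, fill_value="ok"
            )

    @property
    def individuals(self) -> pd.Index:
        return self.df.index

    @property
    def loci(self) -> pd.Index:
        return self.df.columns


# ---------------------------------------------------------------------------
# individuals

def read_individuals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "cytotype": str})
    _require_columns(df, INDIVIDUAL_COLUMNS, path)
    df = df[INDIVIDUAL_COLUMNS]
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise SchemaError(f"duplicate individual id {dup!r} in {path}")
    coords = df[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        row = df["id"].iloc[int(np.argwhere(~np.isfinite(coords))[0][0])]
        raise SchemaError(f"non-finite coordinate for individual {row!r} in {path}")
    return df.reset_index(drop=True)


def write_individuals(df: pd.DataFrame, path) -> None:
    _require_columns(df, INDIVIDUAL_COLUMNS, "individual table")
    df[INDIVIDUAL_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# plot composition

def read_plots(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, PLOT_COLUMNS, path)
    return df[PLOT_COLUMNS].reset_index(drop=True)


def write_plots(df: pd.DataFrame, path) -> None:
    _require_columns(df, PLOT_COLUMNS, "plot table")
    df[PLOT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# indicator values

def read_indicators(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    _require_columns(df, INDICATOR_COLUMNS, path)
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].iloc[0]
        raise SchemaError(f"duplicate species {dup!r} in {path}")
    df = df.set_index("species")[list(INDICATOR_NAMES)].astype(float)
    out_of_range = (df < 1) | (df > 5)
    if out_of_range.any().any():
        sp = df.index[out_of_range.any(axis=1)][0]
        col = df.columns[out_of_range.loc[sp].to_numpy().argmax()]
        raise SchemaError(
            f"indicator value {df.loc[sp, col]} outside [1, 5] for species "
            f"{sp!r}, column {col!r} in {path}"
        )
    return df


def write_indicators(df: pd.DataFrame, path) -> None:
    out = df.reindex(columns=list(INDICATOR_NAMES))
    out.index.name = "species"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# marker matrix

def read_markers(path) -> MarkerMatrix:
    path = Path(path)
    raw = pd.read_csv(path, dtype={"id": str})
    _require_columns(raw, ["id"], path)
    df = raw.set_index("id")
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SchemaError(
            f"non-binary marker cell {values[i, j]!r} at individual "
            f"{df.index[i]!r}, locus {df.columns[j]!r} in {path}"
        )
    links: list[tuple[str, str]] = []
    rep_path = path.with_suffix(".replicates.tsv")
    if rep_path.exists():
        rep = pd.read_csv(rep_path, sep="\t", dtype=str)
        _require_columns(rep, ["rep_a", "rep_b"], rep_path)
        links = list(rep.itertuples(index=False, name=None))
    locus_flags = None
    lf_path = path.with_suffix(".locus_flags.tsv")
    if lf_path.exists():
        lf = pd.read_csv(lf_path, sep="\t", dtype=str)
        _require_columns(lf, ["locus", "flag"], lf_path)
        locus_flags = lf.set_index("locus")["flag"]
    individual_flags = None
    if_path = path.with_suffix(".individual_flags.tsv")
    if if_path.exists():
        fl = pd.read_csv(if_path, sep="\t", dtype=str)
        _require_columns(fl, ["id", "flag"], if_path)
        individual_flags = fl.set_index("id")["flag"]
    return MarkerMatrix(df, links, locus_flags, individual_flags)


def write_markers(mm: MarkerMatrix, path) -> None:
    path = Path(path)
    out = mm.df.copy()
    out.index.name = "id"
    out.to_csv(path)
    rep = pd.DataFrame(mm.replicate_links, columns=["rep_a", "rep_b"])
    rep.to_csv(path.with_suffix(".replicates.tsv"), sep="\t", index=False)
    lf = mm.locus_flags.rename("flag").rename_axis("locus").reset_index()
    lf.to_csv(path.with_suffix(".locus_flags.tsv"), sep="\t", index=False)
    fl = mm.individual_flags.rename("flag").rename_axis("id").reset_index()
    fl.to_csv(path.with_suffix(".individual_flags.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration / truth records

def read_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return data


def write_config(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _require_columns(df: pd.DataFrame, columns, source) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")
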