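"""End-to-end orchestration: simulate or load, then niche -> spatial ->
scale test -> hybrid inference -> niche-breadth comparison.

One config mapping and one master seed drive the whole run.  Every
stage writes its result tables as TSV under the output directory and
the report index records config hash, seeds, library versions and the
per-stage sample sizes, so each reported statistic is traceable to a
stored intermediate.  Stages whose inputs are absent are skipped with a
logged reason, not an error.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as czio
from .config import MarkerSimConfig, ZoneConfig
from .hybrids import (
    drop_replicate_rows,
    error_rate,
    filter_individuals,
    filter_markers,
    fit_hybrid_model,
    orient_posterior,
    summarize_classes,
)
from .niche import compute_niche_matrix, niche_breadth, pca_niche, pillai_manova
from .scale import mc_scale_test
from .spatial import cytotype_distances, geo_distances, mantel_kendall

logger = logging.getLogger("cytozone.pipeline")

STAGES = ("data", "niche", "spatial", "scaletest", "hybrids", "breadth")


@dataclass
class RunReport:
    outdir: Path
    tables: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def default_config() -> dict:
    """Default synthetic study conditions: a tetraploid/hexaploid contact
    zone with a pentaploid strip at the immediate contact, a range-wide
    pool with three-fold stronger niche shifts, and an AFLP-like marker
    set with the QC categories the filters expect.
    """
    return {
        "seed": 0,
        "simulate": {
            "zone": {
                "n_per_cytotype": {"4x": 90, "5x": 26, "6x": 74},
                "cluster_centers": {"4x": [8.0, 10.0], "5x": [15.0, 10.0], "6x": [22.0, 10.0]},
                "cluster_sd": 4.0,
                "gradient_vector": [0.05, 0.0],
                "niche_shift": {"4x": -0.3, "5x": 0.15, "6x": 0.3},
                "species_pool_size": 60,
                "species_response_width": 1.0,
            },
            "rangewide": {
                "n_per_cytotype": {"4x": 400, "5x": 60, "6x": 400},
                "cluster_centers": {"4x": [8.0, 10.0], "5x": [15.0, 10.0], "6x": [22.0, 10.0]},
                "cluster_sd": 4.0,
                "gradient_vector": [0.05, 0.0],
                "niche_shift": {"4x": -0.9, "5x": 0.45, "6x": 0.9},
                "species_pool_size": 60,
                "species_response_width": 1.0,
            },
            "markers": {
                "n_loci": 131,
                "flip_error": 0.016,
                "n_nonreproducible": 14,
                "n_singleton": 4,
                "n_monomorphic": 101,
                "n_replicates": 19,
                "n_flagged_individuals": 7,
                "class_mix": {
                    "4x": {"Pure0": 1.0},
                    "6x": {"Pure1": 0.65, "F2": 0.17, "BC1": 0.18},
                    "5x": {"F2": 0.85, "BC1": 0.10, "Pure1": 0.05},
                },
            },
        },
        "analysis": {
            "exclude_species": [],
            "mantel_permutations": 999,
            "scale_permutations": 9999,
            "mcmc": {"sweeps": 100_000, "burn_in": 10_000},
            "parent0_cytotype": "4x",
            "focal_cytotype": "6x",
            "introgressed_classes": ["F2", "BC1"],
        },
    }


def run_all(config, outdir, seed=None, stages=None) -> RunReport:
    """Execute the pipeline; ``stages`` optionally restricts to a subset
    (the data stage always runs).  Any stage error aborts with the stage
    name and cause.
    """
    if isinstance(config, (str, Path)):
        config = czio.read_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    stages = set(STAGES if stages is None else stages)
    analysis = {**default_config()["analysis"], **config.get("analysis", {})}
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(STAGES, np.random.SeedSequence(seed).spawn(len(STAGES)))
    }
    report = RunReport(outdir=outdir)
    report.provenance = {
        "seed": seed,
        "stage_seeds": stage_seeds,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "versions": _versions(),
    }

    try:
        data = _stage_data(config, outdir, stage_seeds["data"], report)
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc

    niche = None
    posterior = None
    for name in ("niche", "spatial", "scaletest", "hybrids", "breadth"):
        if name not in stages:
            continue
        try:
            if name == "niche":
                niche = _stage_niche(data, analysis, outdir, report)
            elif name == "spatial":
                _stage_spatial(data, analysis, outdir, stage_seeds["spatial"], report)
            elif name == "scaletest":
                if niche is None:
                    niche = _stage_niche(data, analysis, outdir, report)
                _stage_scaletest(
                    data, niche, analysis, outdir, stage_seeds["scaletest"], report
                )
            elif name == "hybrids":
                posterior = _stage_hybrids(
                    data, analysis, outdir, stage_seeds["hybrids"], report
                )
            elif name == "breadth":
                if niche is None or posterior is None:
                    report.skipped.append(
                        "breadth: requires both the niche and hybrid stages"
                    )
                    continue
                _stage_breadth(data, niche, posterior, analysis, outdir, report)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    index = {
        "provenance": report.provenance,
        "tables": sorted(report.tables),
        "skipped": report.skipped,
    }
    czio.write_config(index, outdir / "report.yaml")
    return report


# ---------------------------------------------------------------------------
# stages

def _stage_data(config, outdir, seed, report):
    data = {}
    if "simulate" in config:
        sim = config["simulate"]
        sub = np.random.SeedSequence(seed).spawn(3)
        zone_kwargs = dict(sim["zone"])
        zone_kwargs.setdefault("seed", int(sub[0].generate_state(1)[0] % 2**31))
        zone_cfg = ZoneConfig(**zone_kwargs)
        individuals, plots, indicators, truth = _import_gen()["zone"](zone_cfg)
        data.update(individuals=individuals, plots=plots, indicators=indicators)
        czio.write_config(truth, outdir / "truth_zone.yaml")
        if "rangewide" in sim:
            rw_kwargs = dict(sim["rangewide"])
            rw_kwargs.setdefault("seed", int(sub[1].generate_state(1)[0] % 2**31))
            rw_cfg = ZoneConfig(**rw_kwargs)
            rw_ind, rw_plots, rw_indicators, rw_truth = _import_gen()["zone"](rw_cfg)
            data.update(
                rangewide_individuals=rw_ind,
                rangewide_plots=rw_plots,
                rangewide_indicators=rw_indicators,
            )
            czio.write_config(rw_truth, outdir / "truth_rangewide.yaml")
        if "markers" in sim:
            mcfg = dict(sim["markers"])
            class_mix = mcfg.pop("class_mix", None)
            rng = np.random.default_rng(int(sub[2].generate_state(1)[0] % 2**31))
            ids = class_labels = None
            if class_mix:
                ids, class_labels = [], []
                for _, row in individuals.iterrows():
                    mix = class_mix.get(row["cytotype"])
                    if not mix:
                        continue
                    classes = sorted(mix)
                    pvals = np.array([mix[c] for c in classes], dtype=float)
                    pvals /= pvals.sum()
                    ids.append(row["id"])
                    class_labels.append(str(rng.choice(classes, p=pvals)))
            mcfg.setdefault("seed", int(sub[2].generate_state(2)[1] % 2**31))
            marker_cfg = MarkerSimConfig(**mcfg)
            markers, mtruth = _import_gen()["markers"](
                marker_cfg, ids=ids, class_labels=class_labels
            )
            data["markers"] = markers
            czio.write_config(mtruth, outdir / "truth_markers.yaml")
        czio.write_individuals(individuals, outdir / "individuals.tsv")
        czio.write_plots(plots, outdir / "plots.tsv")
        czio.write_indicators(indicators, outdir / "indicators.tsv")
        if "markers" in data:
            czio.write_markers(data["markers"], outdir / "markers.csv")
    else:
        inputs = config.get("inputs", {})
        if "individuals" not in inputs:
            raise ValueError("config needs a 'simulate' section or 'inputs' paths")
        data["individuals"] = czio.read_individuals(inputs["individuals"])
        data["plots"] = czio.read_plots(inputs["plots"])
        data["indicators"] = czio.read_indicators(inputs["indicators"])
        if "markers" in inputs:
            data["markers"] = czio.read_markers(inputs["markers"])
        if "rangewide_plots" in inputs:
            data["rangewide_individuals"] = czio.read_individuals(
                inputs["rangewide_individuals"]
            )
            data["rangewide_plots"] = czio.read_plots(inputs["rangewide_plots"])
            data["rangewide_indicators"] = czio.read_indicators(
                inputs["rangewide_indicators"]
            )
    report.tables["individuals"] = data["individuals"]
    return data


def _stage_niche(data, analysis, outdir, report):
    individuals = data["individuals"]
    niche = compute_niche_matrix(
        data["plots"], data["indicators"], analysis.get("exclude_species", ())
    )
    cyt = individuals.set_index("id")["cytotype"]
    groups = cyt.loc[[i for i in niche.index if i in cyt.index]]
    niche = niche.loc[groups.index]
    out = niche.copy()
    out.index.name = "id"
    out.to_csv(outdir / "niche_matrix.tsv", sep="\t")

    rows = []
    for a, b in _pairs(groups):
        sub = groups[groups.isin([a, b])]
        try:
            res = pillai_manova(niche.loc[sub.index], sub)
            rows.append(
                {
                    "cytotype_a": a, "cytotype_b": b,
                    "n_a": int((sub == a).sum()), "n_b": int((sub == b).sum()),
                    "pillai": res.pillai, "F": res.F,
                    "df1": res.df1, "df2": res.df2, "p": res.p,
                }
            )
        except ValueError as exc:
            report.skipped.append(f"niche MANOVA {a}/{b}: {exc}")
    manova = pd.DataFrame(rows)
    manova.to_csv(outdir / "manova.tsv", sep="\t", index=False)
    report.tables["manova"] = manova

    pca = pca_niche(niche, groups)
    pca.scores.rename_axis("id").to_csv(outdir / "pca_scores.tsv", sep="\t")
    pca.loadings.rename_axis("variable").to_csv(outdir / "pca_loadings.tsv", sep="\t")
    pd.DataFrame(
        {"component": pca.scores.columns, "explained": pca.explained}
    ).to_csv(outdir / "pca_explained.tsv", sep="\t", index=False)
    breadth = niche_breadth(pca, groups)
    breadth.to_csv(outdir / "niche_breadth.tsv", sep="\t")
    report.tables["niche_breadth"] = breadth
    report.tables["niche_matrix"] = niche
    report.tables["pca_explained"] = pd.DataFrame({"explained": pca.explained})
    data["niche_groups"] = groups
    return niche


def _stage_spatial(data, analysis, outdir, seed, report):
    individuals = data["individuals"]
    rows = []
    rng = np.random.SeedSequence(seed).spawn(64)
    k = 0
    for a, b in _pairs(individuals["cytotype"]):
        sub = individuals[individuals["cytotype"].isin([a, b])].reset_index(drop=True)
        if sub["cytotype"].nunique() < 2:
            continue
        s = int(rng[k].generate_state(1)[0] % 2**31)
        k += 1
        res = mantel_kendall(
            geo_distances(sub),
            cytotype_distances(sub),
            n_perm=int(analysis.get("mantel_permutations", 999)),
            seed=s,
        )
        rows.append(
            {
                "cytotype_a": a, "cytotype_b": b, "n": res.n,
                "r": res.r, "p": res.p, "n_perm": res.n_perm, "seed": s,
            }
        )
    mantel = pd.DataFrame(rows)
    mantel.to_csv(outdir / "mantel.tsv", sep="\t", index=False)
    report.tables["mantel"] = mantel
    return mantel


def _stage_scaletest(data, niche, analysis, outdir, seed, report):
    if "rangewide_plots" not in data:
        report.skipped.append("scaletest: no range-wide dataset")
        return None
    rw_niche = compute_niche_matrix(
        data["rangewide_plots"],
        data["rangewide_indicators"],
        analysis.get("exclude_species", ()),
    )
    rw_cyt = data["rangewide_individuals"].set_index("id")["cytotype"]
    rw_groups = rw_cyt.loc[[i for i in rw_niche.index if i in rw_cyt.index]]
    rw_niche = rw_niche.loc[rw_groups.index]
    groups = data["niche_groups"]
    rows = []
    rng = np.random.SeedSequence(seed).spawn(64)
    k = 0
    for a, b in _pairs(groups):
        sub = groups[groups.isin([a, b])]
        rw_sub = rw_groups[rw_groups.isin([a, b])]
        s = int(rng[k].generate_state(1)[0] % 2**31)
        k += 1
        try:
            res = mc_scale_test(
                niche.loc[sub.index], sub,
                rw_niche.loc[rw_sub.index], rw_sub,
                n_perm=int(analysis.get("scale_permutations", 9999)),
                seed=s,
            )
        except ValueError as exc:
            report.skipped.append(f"scaletest {a}/{b}: {exc}")
            continue
        rows.append(
            {
                "cytotype_a": a, "cytotype_b": b,
                "empirical_F": res.empirical_F, "p": res.p,
                "n_perm": res.n_perm, "seed": s,
                **{f"n_{c}": v for c, v in res.n_per_cytotype.items()},
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "scaletest.tsv", sep="\t", index=False)
    report.tables["scaletest"] = table
    return table


def _stage_hybrids(data, analysis, outdir, seed, report):
    if "markers" not in data:
        report.skipped.append("hybrids: no marker data")
        logger.info("hybrid stage skipped: no marker data")
        return None
    markers = data["markers"]
    qc = {}
    if markers.replicate_links:
        rate, n_mis, n_cmp = error_rate(markers)
        qc.update(error_rate=rate, n_mismatches=n_mis, n_comparisons=n_cmp)
    markers = drop_replicate_rows(markers)
    markers, removed = filter_individuals(markers)
    qc["n_individuals_removed"] = len(removed)
    markers, frep = filter_markers(markers)
    qc.update(
        n_loci_total=frep.n_total,
        n_nonreproducible=frep.n_nonreproducible,
        n_monomorphic=frep.n_monomorphic,
        n_singleton=frep.n_singleton,
        n_loci_retained=frep.n_retained,
        n_individuals_retained=markers.df.shape[0],
    )
    qc_table = pd.DataFrame([qc])
    qc_table.to_csv(outdir / "marker_qc.tsv", sep="\t", index=False)
    report.tables["marker_qc"] = qc_table

    mcmc = analysis.get("mcmc", {})
    posterior = fit_hybrid_model(
        markers,
        n_sweeps=int(mcmc.get("sweeps", 100_000)),
        burn_in=int(mcmc.get("burn_in", 10_000)),
        seed=seed,
    )
    cyt = data["individuals"].set_index("id")["cytotype"]
    posterior = orient_posterior(posterior, cyt, analysis["parent0_cytotype"])
    posterior.probs.rename_axis("id").to_csv(outdir / "hybrid_posterior.tsv", sep="\t")
    pd.DataFrame(
        posterior.traces["pi"], columns=posterior.classes
    ).to_csv(outdir / "pi_trace.tsv", sep="\t", index=False)
    labelled = [i for i in posterior.modal.index if i in cyt.index]
    summary = summarize_classes(
        posterior.modal.loc[labelled], cyt, classes=posterior.classes
    )
    summary.to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
    report.tables["class_summary"] = summary
    report.tables["hybrid_posterior"] = posterior.probs
    data["posterior"] = posterior
    return posterior


def _stage_breadth(data, niche, posterior, analysis, outdir, report):
    cyt = data["individuals"].set_index("id")["cytotype"]
    breadth, tests = breadth_comparison(
        niche,
        posterior,
        cyt,
        focal_cytotype=analysis["focal_cytotype"],
        introgressed_classes=tuple(analysis.get("introgressed_classes", ("F2", "BC1"))),
    )
    breadth.to_csv(outdir / "breadth_comparison.tsv", sep="\t", index=False)
    tests.to_csv(outdir / "breadth_manova.tsv", sep="\t", index=False)
    report.tables["breadth_comparison"] = breadth
    report.tables["breadth_manova"] = tests
    return breadth, tests


# ---------------------------------------------------------------------------

def breadth_comparison(
    niche: pd.DataFrame,
    posterior,
    cytotypes: pd.Series,
    focal_cytotype: str,
    pure_class: str = "Pure1",
    introgressed_classes=("F2", "BC1"),
    other_parent_class: str = "Pure0",
):
    """Compare niche breadth of pure versus introgressed individuals of the
    focal cytotype.

    The focal cytotype's individuals (shared between the niche matrix and
    the posterior) are partitioned by modal class into 'pure'
    (``pure_class``) and 'introgressed' (``introgressed_classes``); niche
    breadth (distance to the partition centroid in PCA score space) is
    reported for each, plus Pillai MANOVAs pure-vs-introgressed and of each
    partition against the other parental class.  Empty partitions are
    reported as not-applicable, never raised.
    """
    modal = posterior.modal if hasattr(posterior, "modal") else pd.Series(posterior)
    shared = [i for i in niche.index if i in modal.index and i in cytotypes.index]
    sub = niche.loc[shared]
    modal = modal.loc[shared]
    cyt = cytotypes.loc[shared]
    focal = cyt == focal_cytotype
    parts = {
        "pure": list(sub.index[(focal & (modal == pure_class)).to_numpy()]),
        "introgressed": list(
            sub.index[(focal & modal.isin(introgressed_classes)).to_numpy()]
        ),
        "other_parent": list(sub.index[(modal == other_parent_class).to_numpy()]),
    }
    pca = pca_niche(sub) if len(sub) >= 2 else None
    rows = []
    for name in ("pure", "introgressed"):
        ids = parts[name]
        if not ids or pca is None:
            rows.append(
                {"partition": name, "n": len(ids), "mean_dist": np.nan,
                 "se": np.nan, "note": "not applicable: empty partition"}
            )
            continue
        b = niche_breadth(pca, pd.Series("g", index=pca.scores.index).where(
            ~pca.scores.index.isin(ids), "focal"
        ))
        row = b.loc["focal"]
        rows.append(
            {"partition": name, "n": int(row["n"]), "mean_dist": row["mean_dist"],
             "se": row["se"], "note": ""}
        )
    breadth = pd.DataFrame(rows)

    tests = []
    comparisons = [
        ("pure_vs_introgressed", parts["pure"], parts["introgressed"]),
        ("introgressed_vs_other_parent", parts["introgressed"], parts["other_parent"]),
        ("pure_vs_other_parent", parts["pure"], parts["other_parent"]),
    ]
    for name, a_ids, b_ids in comparisons:
        if len(a_ids) < 2 or len(b_ids) < 2:
            tests.append(
                {"comparison": name, "F": np.nan, "df1": np.nan, "df2": np.nan,
                 "p": np.nan, "note": "not applicable: partition too small"}
            )
            continue
        ids = list(a_ids) + list(b_ids)
        labels = pd.Series(["a"] * len(a_ids) + ["b"] * len(b_ids), index=ids)
        try:
            res = pillai_manova(sub.loc[ids], labels)
        except ValueError as exc:
            tests.append(
                {"comparison": name, "F": np.nan, "df1": np.nan, "df2": np.nan,
                 "p": np.nan, "note": str(exc)}
            )
            continue
        tests.append(
            {"comparison": name, "F": res.F, "df1": res.df1, "df2": res.df2,
             "p": res.p, "note": ""}
        )
    return breadth, pd.DataFrame(tests)


def _pairs(groups):
    levels = sorted(pd.Series(groups).unique())
    return list(itertools.combinations(levels, 2))


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "cytozone": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def _import_gen():
    # local import: synthetic imports hybrids/io which import config only
    from .synthetic import gen_contact_zone, gen_marker_matrix

    return {"zone": gen_contact_zone, "markers": gen_marker_matrix}
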