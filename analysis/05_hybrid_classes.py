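#!/usr/bin/env python
"""Marker QC and Bayesian hybrid-category inference.

Computes the replicate error rate, filters nonreproducible individuals
and nonreproducible/monomorphic/singleton fragments, runs the
dominant-marker Gibbs sampler and tabulates modal hybrid classes per
cytotype.  Tables land in results/hybrids/.
"""

from pathlib import Path

from cytozone.pipeline import default_config, run_all

OUT = Path(__file__).resolve().parents[1] / "results" / "hybrids"


def main() -> None:
    cfg = default_config()
    cfg["analysis"]["mcmc"] = {"sweeps": 30_000, "burn_in": 3_000}
    report = run_all(cfg, OUT, seed=1, stages=("data", "hybrids"))
    qc = report.tables["marker_qc"].iloc[0]
    print(
        f"replicate error rate: {100 * qc['error_rate']:.2f}% "
        f"({int(qc['n_mismatches'])}/{int(qc['n_comparisons'])} comparisons)"
    )
    print(
        f"loci: {int(qc['n_loci_retained'])} retained of {int(qc['n_loci_total'])} "
        f"({int(qc['n_nonreproducible'])} nonreproducible, "
        f"{int(qc['n_monomorphic'])} monomorphic, {int(qc['n_singleton'])} singleton)"
    )
    print(f"individuals retained: {int(qc['n_individuals_retained'])}")
    print("\nmodal hybrid class by cytotype (% of cytotype):")
    print(
        report.tables["class_summary"]
        .pivot(index="hybrid_class", columns="cytotype", values="pct")
        .round(1)
        .to_string()
    )


if __name__ == "__main__":
    main()
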