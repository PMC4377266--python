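#!/usr/bin/env python
"""Microspatial clustering of cytotypes: Mantel tests per cytotype pair.

Correlates geographic distance with the binary same/different-ploidy
distance (Kendall's tau-b, 999 permutations).  Tables land in
results/spatial/.
"""

from pathlib import Path

from cytozone.pipeline import default_config, run_all

OUT = Path(__file__).resolve().parents[1] / "results" / "spatial"


def main() -> None:
    report = run_all(default_config(), OUT, seed=1, stages=("data", "spatial"))
    print("Mantel tests (tau-b, joint row/column permutations):")
    print(report.tables["mantel"].to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
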