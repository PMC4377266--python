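#!/usr/bin/env python
"""Generate the synthetic contact-zone datasets used by the later steps.

Writes the individual table, plot composition, species indicator values,
range-wide reference data and the dominant marker matrix (with truth
records) under results/data/.
"""

from pathlib import Path

from cytozone.pipeline import default_config, run_all

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    report = run_all(default_config(), OUT, seed=1, stages=("data",))
    ind = report.tables["individuals"]
    print(f"wrote synthetic contact zone to {OUT}")
    print(ind.groupby("cytotype").size().rename("individuals"))


if __name__ == "__main__":
    main()
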