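#!/usr/bin/env python
"""Summarize the run against the simulation's ground truth: regulated-gene
and called-event counts by category, plus TP/FP/FN confusion and
sensitivity for both genes and events.

Reads results/, writes results/report.md and prints it.
"""

import shutil
from pathlib import Path

from splicearray import report

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    # report() looks for truth tables next to the result files
    for name in ("truth_genes.tsv", "truth_events.tsv"):
        if not (ROOT / name).exists():
            shutil.copy(ROOT / "sim" / name, ROOT / name)
    text = report(ROOT)
    (ROOT / "report.md").write_text(text)
    print(text)
    print(f"wrote {ROOT}/report.md")


if __name__ == "__main__":
    main()
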