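#!/usr/bin/env python
"""Call regulated genes: expressed (mean index >= 500 in >= 1 condition),
fold change >= 1.5 and unpaired t-test p <= 0.05 on log2 indices.

Reads results/gene_index.tsv, writes results/genes.tsv.
"""

from pathlib import Path

import pandas as pd

from splicearray import call_regulated_genes

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    index = pd.read_csv(ROOT / "gene_index.tsv", sep="\t", index_col=0)
    conditions = {s: ("control" if s.startswith("control") else "treated")
                  for s in index.columns}
    genes = call_regulated_genes(index, conditions)
    genes.to_csv(ROOT / "genes.tsv", sep="\t", index=False)
    expressed = (genes["expressed_control"] | genes["expressed_treated"]).sum()
    up = ((genes["regulated"]) & (genes["direction"] > 0)).sum()
    down = ((genes["regulated"]) & (genes["direction"] < 0)).sum()
    print(f"{expressed} of {len(genes)} genes expressed in >= 1 condition")
    print(f"{int(genes['regulated'].sum())} regulated genes "
          f"({up} up, {down} down in treated)")
    print(f"wrote {ROOT}/genes.tsv")


if __name__ == "__main__":
    main()
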