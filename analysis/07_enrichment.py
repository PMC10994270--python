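#!/usr/bin/env python
"""Gene-set over-representation of the hit drugs' annotated targets.

The query is the union of target genes of the hit drugs, restricted to
the expressed-gene background; each packaged gene set is tested with the
hypergeometric upper tail, BH-corrected, with enrichment strength
log10(observed/expected)."""

from pathlib import Path

import pandas as pd

from morphoscreen.enrich import (
    filter_by_expression,
    hypergeometric_enrichment,
    read_gene_list,
    read_gmt,
    write_enrichment_tsv,
)
from morphoscreen.pipeline import _packaged

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"


def main() -> None:
    drugs = pd.read_csv(OUT / "drug_hits.csv")
    targets = pd.read_csv(_packaged("drug_targets.csv"))
    collection = read_gmt(_packaged("genesets.gmt"))
    expressed = read_gene_list(_packaged("expressed_genes.txt"))

    query = set(targets.loc[targets["parent_drug"].isin(drugs["parent_drug"]),
                            "target_gene"])
    print(f"query: {len(query)} annotated target genes of "
          f"{len(drugs)} hit drugs")
    query = filter_by_expression(query, expressed)
    print(f"after expressed-gene background correction: {len(query)} genes "
          f"against a background of {len(expressed)}")

    rows = hypergeometric_enrichment(query, collection, expressed)
    write_enrichment_tsv(rows, OUT / "enrichment.tsv")
    print(f"tested {len(rows)} gene sets; "
          f"{int((rows['q'] < 0.05).sum())} significant at q < 0.05")
    for _, r in rows.head(5).iterrows():
        print(f"  {r['set_id']}: x={r['x']} (expected {r['expected']:.2f}), "
              f"strength={r['strength']:.2f}, p={r['p']:.3g}, q={r['q']:.3g}")


if __name__ == "__main__":
    main()
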