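#!/usr/bin/env python
"""GO over-representation of SSD transcripts against each cross's focal set.

Uses the toy GO annotation written by 01_simulate.py, in which two terms
were planted as enriched among genes with sex-specific dominance; those
terms should surface with small q-values while the remaining terms stay
null.  Also reports the overlap of significant term sets between crosses.
"""

from itertools import combinations
from pathlib import Path

import pandas as pd

from ssdom import data_io
from ssdom.enrichment import (compare_term_sets, go_overrepresentation,
                              significant_terms)

SIM = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    res = data_io.read_results(RESULTS / "pipeline" / "results.tsv")
    go_map = data_io.read_go_map(SIM / "go_map.tsv")
    sig = {}
    for cross, sub in res.groupby("cross_id"):
        aut = sub[(sub["chrom_class"] == "autosome") & sub["focal"]]
        study = list(aut.loc[aut["ssd"].astype(bool), "gene_id"])
        if not study:
            continue
        enr = go_overrepresentation(study, list(aut["gene_id"]), go_map)
        enr.to_csv(RESULTS / f"enrichment_{cross}.tsv", sep="\t", index=False)
        sig[str(cross)] = significant_terms(enr)
        top = enr.head(3)[["go_id", "term_size", "study_count", "q"]]
        print(f"cross {cross}: {len(sig[str(cross)])} significant terms; top:")
        print(top.to_string(index=False))
    for a, b in combinations(sorted(sig), 2):
        ov = compare_term_sets(sig[a], sig[b])
        print(f"overlap {a} vs {b}: jaccard={ov['jaccard']:.2f} "
              f"shared={ov['shared']}")


if __name__ == "__main__":
    main()
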