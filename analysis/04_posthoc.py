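#!/usr/bin/env python
"""Post-hoc statistics over the dominance results.

Per cross: the male-female dominance major-axis regression, tallies of
sex-specific dominance (SSD) and reversals, the greater-vs-lesser sex
bias in heterozygotes proportion test, the directional KS comparison of
|sex bias| between SSD and non-SSD focal transcripts, Fisher's test of
SSD against the direction of sex bias, and the X vs. autosome comparison
of female nonadditivity.  Writes results/posthoc_summary.json.
"""

import json
from pathlib import Path

from ssdom import data_io
from ssdom.pipeline import _jsonable
from ssdom.posthoc import summarize_cross

RESULTS = Path("results")


def main() -> None:
    res = data_io.read_results(RESULTS / "pipeline" / "results.tsv")
    out = {}
    for cross, sub in res.groupby("cross_id"):
        out[str(cross)] = summarize_cross(sub)
    (RESULTS / "posthoc_summary.json").write_text(
        json.dumps(_jsonable(out), indent=2))
    for cross, s in out.items():
        ma = s.get("ma", {})
        print(f"cross {cross}: focal={s['n_focal_autosome']} "
              f"ssd={s['n_ssd']} reversal={s['n_reversal']} "
              f"MA slope={ma.get('slope', float('nan')):.2f} "
              f"r={ma.get('r', float('nan')):.2f}")
        if "sb_change_chisq" in s:
            c = s["sb_change_chisq"]
            print(f"  greater/lesser SB in hets: {s['n_sb_greater']}/"
                  f"{s['n_sb_lesser']} (chi2={c['chi2']:.2f}, p={c['p']:.3f})")
        if "ks_sb" in s:
            print(f"  KS |SB| SSD vs non-SSD: D+={s['ks_sb']['d_plus']:.3f} "
                  f"p={s['ks_sb']['p']:.2g}; Fisher sex-bias x SSD "
                  f"p={s['fisher_sexbias_ssd']['p']:.2g}")


if __name__ == "__main__":
    main()
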