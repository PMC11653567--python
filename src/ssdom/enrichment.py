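"""GO over-representation of study gene sets against a focal universe.

Classic per-term hypergeometric upper-tail test of a study set (e.g.
transcripts with sex-specific dominance) against a universe (the cross's
focal set), with Storey q-values over the tested terms.  If an ontology
edge list (child, parent) is supplied, annotations are propagated to
ancestor terms first; otherwise the gene -> term map is used as-is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .posthoc import qvalues_with_na


def propagate_annotations(go_map: pd.DataFrame, edges: pd.DataFrame) -> pd.DataFrame:
    """Extend a gene -> term map with all ancestor terms.

    `edges` has columns (child, parent); annotation of a term implies
    annotation of every ancestor.  Cycles are ignored defensively.
    """
    parents: dict[str, set[str]] = {}
    for child, parent in zip(edges.iloc[:, 0], edges.iloc[:, 1]):
        parents.setdefault(str(child), set()).add(str(parent))
    rows = set()
    for gene, term in zip(go_map["gene_id"], go_map["go_id"]):
        stack, seen = [term], set()
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            rows.add((gene, t))
            stack.extend(parents.get(t, ()))
    out = pd.DataFrame(sorted(rows), columns=["gene_id", "go_id"])
    return out


def go_overrepresentation(study, universe, go_map: pd.DataFrame,
                          min_size: int = 5,
                          edges: pd.DataFrame | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of `study` within `universe`.

    Per term: p = P(overlap >= observed) drawing |study| genes from a
    universe of size |universe| containing `term_size` annotated genes.
    Terms annotating fewer than `min_size` universe genes are skipped.
    The result is invariant to gene order and to duplicated map lines.
    """
    study = set(study)
    universe = set(universe)
    if not study <= universe:
        extra = sorted(study - universe)[:5]
        raise ValidationError(f"study set is not a subset of the universe, e.g. {extra}")
    gmap = go_map.drop_duplicates()
    gmap = gmap[gmap["gene_id"].isin(universe)]
    if gmap.empty:
        raise ValidationError("GO map covers no universe gene")
    n_univ = len(universe)
    n_study = len(study)
    rows = []
    for term, sub in gmap.groupby("go_id"):
        term_genes = set(sub["gene_id"])
        k_univ = len(term_genes)
        if k_univ < min_size:
            continue
        k_study = len(term_genes & study)
        expected = n_study * k_univ / n_univ
        p = float(stats.hypergeom.sf(k_study - 1, n_univ, k_univ, n_study))
        rows.append({"go_id": term, "term_size": k_univ, "study_count": k_study,
                     "expected": expected, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["go_id", "term_size", "study_count",
                                      "expected", "p"])
    if len(out):
        out = out.sort_values(["p", "go_id"], kind="mergesort").reset_index(drop=True)
        out["q"] = qvalues_with_na(out["p"])
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def significant_terms(enrich: pd.DataFrame, q_cutoff: float = 0.05) -> set[str]:
    if enrich.empty:
        return set()
    return set(enrich.loc[enrich["q"] <= q_cutoff, "go_id"])


def compare_term_sets(set_a, set_b) -> dict:
    """Jaccard overlap and shared terms of two significant-term sets."""
    a, b = set(set_a), set(set_b)
    union = a | b
    shared = sorted(a & b)
    return {
        "n_a": len(a), "n_b": len(b), "n_shared": len(shared),
        "jaccard": len(shared) / len(union) if union else 1.0,
        "shared": shared,
    }
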