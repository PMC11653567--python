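"""Pre-filtering, normalization, PCA and mis-sexed sample detection.

The order of operations mirrors the analysis workflow: Y-linked
transcripts are dropped first, then transcripts whose mean raw count per
sample falls below a threshold within every sex, then per-sample size
factors are computed by the median-of-ratios method, counts are
transformed for inspection, and samples whose position in PC space
contradicts their annotated sex are flagged for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CountMatrix
from .errors import ValidationError

log = logging.getLogger("ssdom")


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized and variance-stabilized expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    size_factors: np.ndarray
    normalized: np.ndarray = field(repr=False)   # count / size factor
    transformed: np.ndarray = field(repr=False)  # log2(normalized + 1)


@dataclass
class PCAResult:
    coords: np.ndarray        # samples x components
    pct_variance: np.ndarray  # percent of total variance per component
    components: np.ndarray    # components x genes (orthonormal rows)
    sample_ids: list[str]


def filter_y_linked(counts: CountMatrix, genes: pd.DataFrame) -> CountMatrix:
    """Drop Y-linked transcripts, preserving row order."""
    cls = genes.set_index("gene_id")["chrom_class"]
    missing = [g for g in counts.gene_ids if g not in cls.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} genes missing from the gene table, e.g. {missing[:5]}"
        )
    keep = np.array([cls[g] != "Y" for g in counts.gene_ids])
    removed = int((~keep).sum())
    log.info("filter_y_linked: removed %d Y-linked transcripts, %d remain",
             removed, int(keep.sum()))
    return counts.subset_genes(keep)


def filter_low_expression(counts: CountMatrix, samples: pd.DataFrame,
                          threshold: float = 3.0,
                          scope: str = "all_sexes") -> CountMatrix:
    """Remove transcripts with mean raw count below `threshold` per sex.

    With scope="all_sexes" (default) a transcript is removed only when its
    mean raw count per sample is below the threshold within *every* sex,
    so strongly sex-limited transcripts expressed in one sex survive.
    scope="any_sex" removes a transcript as soon as one sex falls below
    the threshold.  The comparison is strict (<), so a mean of exactly
    `threshold` is kept.
    """
    if scope not in ("all_sexes", "any_sex"):
        raise ValidationError(f"unknown low-count scope {scope!r}")
    use = ~samples["excluded"].to_numpy()
    below = []
    for sex in ("female", "male"):
        cols = ((samples["sex"] == sex) & use).to_numpy()
        if cols.sum() == 0:
            continue
        means = counts.counts[:, cols].mean(axis=1)
        below.append(means < threshold)
    if not below:
        return counts
    below = np.column_stack(below)
    drop = below.all(axis=1) if scope == "all_sexes" else below.any(axis=1)
    log.info("filter_low_expression: removed %d transcripts (mean < %g per sex, %s), "
             "%d remain", int(drop.sum()), threshold, scope, int((~drop).sum()))
    return counts.subset_genes(~drop)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, using only
    genes with strictly positive counts in every sample; each sample's
    factor is the median across reference genes of count / geometric
    mean.
    """
    c = counts.counts.astype(float)
    allpos = (c > 0).all(axis=1)
    if not allpos.any():
        raise ValidationError(
            "no transcript has positive counts in every sample; a pseudo-reference "
            "(e.g. mean of positives) would be needed for these data"
        )
    ref = c[allpos]
    geo = np.exp(np.mean(np.log(ref), axis=1))
    ratios = ref / geo[:, None]
    f = np.median(ratios, axis=0)
    f = f / np.exp(np.mean(np.log(f)))
    return f


def size_factors_design_aware(counts: CountMatrix, samples: pd.DataFrame,
                              fc_threshold: float = 0.25,
                              min_control: int = 50) -> np.ndarray:
    """Median-of-ratios restricted to parentally line-stable control genes.

    In a cross design, heterozygotes genuinely express line-different
    genes near the arithmetic midparent, which exceeds the parental
    geometric mean; plain median-of-ratios absorbs part of that real
    signal into the heterozygote size factors and biases the dominance
    coefficient downward.  A second pass therefore re-estimates factors
    using only genes whose parental homozygote fold change (pooled over
    sexes, first-pass normalized) is below `fc_threshold` log2 units --
    the control-gene idiom of standard DE frameworks.  Falls back to the
    plain estimate when fewer than `min_control` control genes exist.
    """
    sf0 = size_factors(counts)
    c = counts.counts.astype(float)
    norm0 = c / sf0[None, :]
    homo = samples["homozygous"].to_numpy() & ~samples["excluded"].to_numpy()
    dams = samples["dam"].to_numpy()
    lines = sorted(set(dams[homo]))
    if len(lines) != 2:
        return sf0
    m1 = norm0[:, homo & (dams == lines[0])].mean(axis=1)
    m2 = norm0[:, homo & (dams == lines[1])].mean(axis=1)
    allpos = (c > 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.abs(np.log2(m1 / m2))
    control = allpos & np.isfinite(fc) & (fc < fc_threshold)
    if control.sum() < min_control:
        log.info("size_factors_design_aware: only %d control genes, using plain "
                 "median-of-ratios", int(control.sum()))
        return sf0
    ref = c[control]
    geo = np.exp(np.mean(np.log(ref), axis=1))
    f = np.median(ref / geo[:, None], axis=0)
    return f / np.exp(np.mean(np.log(f)))


def vst(counts: CountMatrix, factors: np.ndarray) -> NormalizedMatrix:
    """Normalize by size factors and apply log2(x + 1).

    The transform is monotone in counts per sample and maps zero counts
    to zero; it is used for sample-level inspection (PCA, outlier
    detection), never for the inference itself.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValidationError("size factors must be positive")
    norm = counts.counts / factors[None, :]
    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        size_factors=factors,
        normalized=norm,
        transformed=np.log2(norm + 1.0),
    )


def pca(norm: NormalizedMatrix, top_n_genes: int | None = None) -> PCAResult:
    """Gene-centered PCA of the transformed matrix (samples as points)."""
    X = norm.transformed
    if X.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if top_n_genes is not None and top_n_genes < X.shape[0]:
        order = np.argsort(X.var(axis=1))[::-1][:top_n_genes]
        X = X[np.sort(order)]
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x genes
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S ** 2
    total = var.sum()
    pct = 100.0 * var / total if total > 0 else np.zeros_like(var)
    return PCAResult(coords=U * S, pct_variance=pct, components=Vt,
                     sample_ids=list(norm.sample_ids))


def detect_mis_sexed(norm: NormalizedMatrix, samples: pd.DataFrame,
                     n_components: int = 2) -> list[str]:
    """Flag samples whose PC position contradicts their annotated sex.

    Each sample is assigned to the nearer sex centroid in the top PC
    space, with the centroid of its own annotated sex computed leaving
    the sample out; a disagreement between assignment and annotation
    flags the sample.  Samples are flagged, never auto-removed -- the
    caller records the exclusion.  With fewer than 2 samples of either
    sex, detection is skipped with a warning.
    """
    sex = samples.set_index("sample_id").loc[norm.sample_ids, "sex"].to_numpy()
    for s in ("female", "male"):
        if (sex == s).sum() < 2:
            log.warning("detect_mis_sexed: <2 %s samples, detection skipped", s)
            return []
    res = pca(norm)
    Z = res.coords[:, :n_components]
    flagged = []
    for i, sid in enumerate(norm.sample_ids):
        own = sex[i]
        other = "male" if own == "female" else "female"
        own_mask = (sex == own)
        own_mask[i] = False
        c_own = Z[own_mask].mean(axis=0)
        c_other = Z[sex == other].mean(axis=0)
        if np.linalg.norm(Z[i] - c_other) < np.linalg.norm(Z[i] - c_own):
            flagged.append(sid)
    if flagged:
        log.info("detect_mis_sexed: flagged %d sample(s): %s", len(flagged), flagged)
    return flagged


def mark_excluded(samples: pd.DataFrame, sample_ids: list[str],
                  reason: str) -> pd.DataFrame:
    """Return a copy of the sample table with the given samples excluded."""
    out = samples.copy()
    hit = out["sample_id"].isin(sample_ids)
    out.loc[hit, "excluded"] = True
    out.loc[hit, "exclude_reason"] = reason
    return out
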