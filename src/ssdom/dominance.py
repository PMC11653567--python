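"""Per-cross dominance analysis.

For one cross between two homozygous lines this module
(1) orients each transcript so the higher-expressed parental line is the
"high" allele, (2) applies the two-step focal filter -- keep transcripts
with a significant parental line difference, then drop transcripts whose
parental line difference interacts with sex -- (3) estimates the per-sex
dominance coefficient delta_s = ln(observed heterozygote mean / arithmetic
midparent) from size-factor-normalized group means, pooling the two
reciprocal heterozygote directions, (4) tests the sex x dominance
interaction, per-sex nonadditivity and per-sex parent-of-origin effects by
likelihood-ratio tests in the NB GLM, and (5) classifies transcripts
(dominant / recessive / additive per sex; sex-specific dominance; full
reversal; greater vs. lesser sex bias in heterozygotes).

Autosomal and X-linked transcripts are handled separately: males are
hemizygous on the X, so X-linked dominance is assessed in females only
and no male delta is produced; male heterozygote X data serve only as a
dam-clustering diagnostic.  All q-value families are computed within a
cross and chromosome class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CountMatrix
from .errors import ValidationError
from .nbglm import (DesignSpec, build_design, encode_covariates,
                    estimate_dispersion, fit_nb, group_design, lrt_f)
from .posthoc import qvalues_with_na

log = logging.getLogger("ssdom")

LN2 = float(np.log(2.0))


@dataclass
class CrossAnalysis:
    """Results bundle for one cross: per-transcript table plus tallies."""

    results: pd.DataFrame
    report: dict
    size_factors: np.ndarray = field(repr=False)


def genotype_sex_means(norm: np.ndarray, samples: pd.DataFrame) -> dict:
    """Mean normalized expression per (genotype, sex) cell; genes x 1 each."""
    out = {}
    geno = samples["genotype"].to_numpy()
    sex = samples["sex"].to_numpy()
    for g in np.unique(geno):
        for s in ("female", "male"):
            cols = (geno == g) & (sex == s)
            if cols.any():
                out[(g, s)] = norm[:, cols].mean(axis=1)
    return out


def dominance_coefficient(het_mean, parent1_mean, parent2_mean):
    """delta = ln(observed heterozygote / arithmetic midparent).

    Zero under complete additivity; positive when the heterozygote
    exceeds the midparent (the high-expression allele is dominant),
    negative when it falls below (the high allele is recessive).
    """
    het = np.asarray(het_mean, dtype=float)
    mid = 0.5 * (np.asarray(parent1_mean, dtype=float)
                 + np.asarray(parent2_mean, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where((mid > 0) & (het > 0), np.log(het / mid), np.nan)


def orient_alleles(means: dict, lines: tuple[str, str]) -> pd.Series | np.ndarray:
    """Per-gene label of the higher-expressed parental line.

    The pooled-sex mean of each parental homozygote decides; exact ties
    break to the lexicographically first line.  Orientation is pure
    bookkeeping: the dominance coefficient and every LRT are invariant to
    which line is called high, and re-orienting an oriented gene is a
    no-op.
    """
    l1, l2 = sorted(lines)
    m1 = _pooled_parent(means, l1)
    m2 = _pooled_parent(means, l2)
    return np.where(m2 > m1, l2, l1)


def _pooled_parent(means: dict, line: str) -> np.ndarray:
    geno = line + line
    parts = [means[(geno, s)] for s in ("female", "male") if (geno, s) in means]
    if not parts:
        raise ValidationError(f"no parental samples for line {line!r}")
    return np.mean(parts, axis=0)


def sb_change_in_hets(mid_f, mid_m, het_f, het_m) -> np.ndarray:
    """Greater / lesser / equal sex bias among heterozygotes.

    Compares D_het = |log2(het_f / het_m)| against
    D_mid = |log2(mid_f / mid_m)|; zero means are flagged as missing.
    """
    mid_f, mid_m, het_f, het_m = (np.atleast_1d(np.asarray(v, dtype=float))
                                  for v in (mid_f, mid_m, het_f, het_m))
    out = np.full(mid_f.shape, "", dtype=object)
    ok = (mid_f > 0) & (mid_m > 0) & (het_f > 0) & (het_m > 0)
    d_het = np.abs(np.log2(np.where(ok, het_f / het_m, 1.0)))
    d_mid = np.abs(np.log2(np.where(ok, mid_f / mid_m, 1.0)))
    out[ok & (d_het > d_mid)] = "greater"
    out[ok & (d_het < d_mid)] = "lesser"
    out[ok & (d_het == d_mid)] = "equal"
    return out


def classify(results: pd.DataFrame, q_cutoff: float = 0.05) -> pd.DataFrame:
    """Attach per-sex dominance classes and SSD / reversal calls.

    Per sex: "dominant" if delta > 0 with nonadditivity q <= cutoff,
    "recessive" if delta < 0 with q <= cutoff, else "additive".  SSD is a
    sex x dominance interaction q <= cutoff; a reversal additionally
    requires oppositely signed nonzero deltas.
    """
    out = results.copy()
    for sex in ("f", "m"):
        d = out[f"delta_{sex}"]
        q = out[f"q_nonadd_{sex}"]
        cls = np.full(len(out), "", dtype=object)
        tested = d.notna() & q.notna()
        sig = tested & (q <= q_cutoff)
        cls[tested.to_numpy()] = "additive"
        cls[(sig & (d > 0)).to_numpy()] = "dominant"
        cls[(sig & (d < 0)).to_numpy()] = "recessive"
        out[f"class_{sex}"] = cls
    ssd = (out["q_sexdom"] <= q_cutoff) & out["q_sexdom"].notna()
    out["ssd"] = ssd.fillna(False)
    rev = (out["ssd"]
           & (np.sign(out["delta_f"]) * np.sign(out["delta_m"]) < 0))
    out["reversal"] = rev.fillna(False)
    return out


def male_x_dam_clustering(norm: np.ndarray, samples: pd.DataFrame,
                          x_mask: np.ndarray) -> float:
    """Fraction of (male het sample, X gene) pairs nearer the dam line.

    A hemizygosity diagnostic: male heterozygote X expression should
    track the maternally inherited allele, so each male heterozygote
    sample's X-linked values should sit closer (in log space) to the
    male mean of its dam's line than to the sire's.
    """
    males = samples[(samples["sex"] == "male")]
    het = males[~males["homozygous"]]
    if len(het) == 0 or x_mask.sum() == 0:
        return float("nan")
    sidx = {s: i for i, s in enumerate(samples["sample_id"])}
    hits = 0
    total = 0
    logn = np.log2(norm[x_mask] + 1.0)
    for _, row in het.iterrows():
        dam_g, sire_g = row["dam"] * 2, row["sire"] * 2
        dam_cols = [sidx[s] for s in samples.loc[
            (samples["genotype"] == dam_g) & (samples["sex"] == "male"), "sample_id"]]
        sire_cols = [sidx[s] for s in samples.loc[
            (samples["genotype"] == sire_g) & (samples["sex"] == "male"), "sample_id"]]
        if not dam_cols or not sire_cols:
            continue
        v = logn[:, sidx[row["sample_id"]]]
        d_dam = np.abs(v - logn[:, dam_cols].mean(axis=1))
        d_sire = np.abs(v - logn[:, sire_cols].mean(axis=1))
        informative = d_dam != d_sire
        hits += int((d_dam[informative] < d_sire[informative]).sum())
        total += int(informative.sum())
    return hits / total if total else float("nan")


def _fit_chain(y, designs: list[DesignSpec], phi):
    """Fit a nested chain (smallest first); returns list of fits.

    Each larger model is warm-started from the previous one so the
    likelihood chain is monotone.
    """
    fits = []
    prev = None
    for d in designs:
        beta0 = None
        if prev is not None:
            beta0 = np.zeros(d.matrix.shape[1])
            pidx = {c: i for i, c in enumerate(prev.columns)}
            for i, c in enumerate(d.columns):
                if c in pidx:
                    beta0[i] = prev.beta[pidx[c]]
        fit = fit_nb(y, d, phi, beta0=beta0)
        if prev is not None and fit.loglik < prev.loglik - 1e-6:
            # nested chain must be monotone; retry cold
            alt = fit_nb(y, d, phi)
            if alt.loglik > fit.loglik:
                fit = alt
        fits.append(fit)
        prev = fit
    return fits


def analyze_cross(counts: CountMatrix, samples: pd.DataFrame,
                  genes: pd.DataFrame, size_factors: np.ndarray,
                  q_cutoff: float = 0.05) -> CrossAnalysis:
    """Run the full dominance stage for one cross.

    `counts` must already be Y-filtered and low-count filtered, with
    excluded samples dropped, and `samples` aligned to its columns.
    """
    samples = samples.reset_index(drop=True)
    if list(samples["sample_id"]) != list(counts.sample_ids):
        raise ValidationError("sample table is not aligned with the count matrix")
    crosses = samples["cross"].unique()
    if len(crosses) != 1:
        raise ValidationError(f"analyze_cross expects one cross, got {list(crosses)}")
    cross_id = crosses[0]
    lines = tuple(sorted(set(samples["dam"]) | set(samples["sire"])))

    sf = np.asarray(size_factors, dtype=float)
    norm = counts.counts / sf[None, :]
    cls = genes.set_index("gene_id")["chrom_class"].reindex(counts.gene_ids)
    if cls.isna().any():
        raise ValidationError("gene table does not cover all transcripts")
    chrom = cls.to_numpy()

    cov = encode_covariates(samples)
    d_sat = group_design(samples, sf)
    d_full = build_design(cov, sf, ("1", "sex", "a", "h", "p",
                                    "sex:a", "sex:h", "sex:p"))
    d_nosh = d_full.drop("sex:h")

    par = samples["homozygous"].to_numpy()
    cov_par, sf_par = cov[par], sf[par]
    d_par0 = build_design(cov_par, sf_par, ("1", "sex"))
    d_par1 = build_design(cov_par, sf_par, ("1", "sex", "a"))
    d_par2 = build_design(cov_par, sf_par, ("1", "sex", "a", "sex:a"))

    sex_idx = {s: (samples["sex"] == s).to_numpy() for s in ("female", "male")}
    d_sex_full, d_sex_noh, d_sex_nop = {}, {}, {}
    for s in ("female", "male"):
        m = sex_idx[s]
        d_sex_full[s] = build_design(cov[m], sf[m], ("1", "a", "h", "p"))
        d_sex_noh[s] = d_sex_full[s].drop("h")
        d_sex_nop[s] = d_sex_full[s].drop("p")

    ng = counts.n_genes
    Y = counts.counts.astype(float)
    # residual df of the saturated dispersion model; all of a gene's tests
    # share it as the F denominator df (see nbglm.lrt_f)
    resid_df = len(samples) - d_sat.matrix.shape[1]
    cols = dict(
        phi=np.full(ng, np.nan), p_step1=np.full(ng, np.nan),
        p_step2=np.full(ng, np.nan), lfc_sex=np.full(ng, np.nan),
        beta_h=np.full(ng, np.nan), beta_sh=np.full(ng, np.nan),
        p_sexdom=np.full(ng, np.nan), p_nonadd_f=np.full(ng, np.nan),
        p_nonadd_m=np.full(ng, np.nan), p_poe_f=np.full(ng, np.nan),
        p_poe_m=np.full(ng, np.nan), converged=np.ones(ng, dtype=bool),
    )

    # ---- dispersion + parental filter for every transcript -------------
    for g in range(ng):
        y = Y[g]
        phi = estimate_dispersion(y, d_sat)
        cols["phi"][g] = phi
        yp = y[par]
        f0, f1, f2 = _fit_chain(yp, [d_par0, d_par1, d_par2], phi)
        _, cols["p_step1"][g] = lrt_f(f1, f0, 1, resid_df)
        _, cols["p_step2"][g] = lrt_f(f2, f1, 1, resid_df)
        if not (f0.converged and f1.converged and f2.converged):
            cols["converged"][g] = False

    # q-value families are per chromosome class within the cross
    res = pd.DataFrame({"gene_id": counts.gene_ids, "cross_id": cross_id,
                        "chrom_class": chrom, **{k: v for k, v in cols.items()
                                                 if k in ("phi", "p_step1", "p_step2")}})
    res["q_step1"] = np.nan
    res["q_step2"] = np.nan
    for cc in ("autosome", "X"):
        fam = res["chrom_class"] == cc
        res.loc[fam, "q_step1"] = qvalues_with_na(res.loc[fam, "p_step1"])
        step1_pass = fam & (res["q_step1"] <= q_cutoff)
        res.loc[step1_pass, "q_step2"] = qvalues_with_na(res.loc[step1_pass, "p_step2"])
    res["parental_de_pass"] = (res["q_step1"] <= q_cutoff).fillna(False)
    res["sex_concordance_pass"] = res["parental_de_pass"] & ~(
        (res["q_step2"] <= q_cutoff).fillna(False))
    res["focal"] = res["parental_de_pass"] & res["sex_concordance_pass"]

    # ---- group means, orientation, delta --------------------------------
    means = genotype_sex_means(norm, samples)
    l1, l2 = lines
    het_labels = [g for g in samples.loc[~samples["homozygous"], "genotype"].unique()]
    high = orient_alleles(means, lines)
    res["high_line"] = high

    het_f = np.mean([means[(g, "female")] for g in het_labels], axis=0)
    het_m = np.mean([means[(g, "male")] for g in het_labels], axis=0)
    mid_f = 0.5 * (means[(l1 + l1, "female")] + means[(l2 + l2, "female")])
    mid_m = 0.5 * (means[(l1 + l1, "male")] + means[(l2 + l2, "male")])
    delta_f = dominance_coefficient(het_f, means[(l1 + l1, "female")],
                                    means[(l2 + l2, "female")])
    delta_m = dominance_coefficient(het_m, means[(l1 + l1, "male")],
                                    means[(l2 + l2, "male")])

    is_x = chrom == "X"
    res["delta_f"] = np.where(res["focal"], delta_f, np.nan)
    res["delta_m"] = np.where(res["focal"] & ~is_x, delta_m, np.nan)

    # ---- model battery for focal transcripts ----------------------------
    focal_idx = np.flatnonzero(res["focal"].to_numpy())
    for g in focal_idx:
        y = Y[g]
        phi = cols["phi"][g]
        if is_x[g]:
            m = sex_idx["female"]
            fits = _fit_chain(y[m], [d_sex_noh["female"], d_sex_full["female"]], phi)
            _, cols["p_nonadd_f"][g] = lrt_f(fits[1], fits[0], 1, resid_df)
            fnop = fit_nb(y[m], d_sex_nop["female"], phi)
            _, cols["p_poe_f"][g] = lrt_f(fits[1], fnop, 1, resid_df)
            # sex-bias from the parental model (male heterozygotes are
            # hemizygous, so the full cross model does not apply on the X)
            fpar = fit_nb(y[par], d_par2, phi)
            cols["lfc_sex"][g] = 2.0 * fpar.beta[list(fpar.columns).index("sex")] / LN2
            if not all(f.converged for f in fits):
                cols["converged"][g] = False
            continue
        red, full = _fit_chain(y, [d_nosh, d_full], phi)
        _, cols["p_sexdom"][g] = lrt_f(full, red, 1, resid_df)
        bcols = list(full.columns)
        cols["beta_h"][g] = full.beta[bcols.index("h")]
        cols["beta_sh"][g] = full.beta[bcols.index("sex:h")]
        cols["lfc_sex"][g] = 2.0 * full.beta[bcols.index("sex")] / LN2
        if not (red.converged and full.converged):
            cols["converged"][g] = False
        for s, tag in (("female", "f"), ("male", "m")):
            m = sex_idx[s]
            fits = _fit_chain(y[m], [d_sex_noh[s], d_sex_full[s]], phi)
            _, cols[f"p_nonadd_{tag}"][g] = lrt_f(fits[1], fits[0], 1, resid_df)
            fnop = fit_nb(y[m], d_sex_nop[s], phi)
            _, cols[f"p_poe_{tag}"][g] = lrt_f(fits[1], fnop, 1, resid_df)
            if not all(f.converged for f in fits):
                cols["converged"][g] = False

    for name in ("p_sexdom", "p_nonadd_f", "p_nonadd_m", "p_poe_f", "p_poe_m",
                 "lfc_sex", "beta_h", "beta_sh"):
        res[name] = cols[name]
    res["converged"] = cols["converged"]
    # non-converged fits are excluded from every q family (and so from
    # SSD tallies) rather than contributing unstable p-values
    for name in ("p_sexdom", "p_nonadd_f", "p_nonadd_m", "p_poe_f", "p_poe_m"):
        res.loc[~res["converged"], name] = np.nan

    for cc in ("autosome", "X"):
        fam = (res["chrom_class"] == cc) & res["focal"]
        for name in ("sexdom", "nonadd_f", "nonadd_m", "poe_f", "poe_m"):
            res.loc[fam, f"q_{name}"] = qvalues_with_na(res.loc[fam, f"p_{name}"])
    for name in ("sexdom", "nonadd_f", "nonadd_m", "poe_f", "poe_m"):
        if f"q_{name}" not in res.columns:
            res[f"q_{name}"] = np.nan

    res["poe_consistent"] = ((res["q_poe_f"] <= q_cutoff)
                             & (res["q_poe_m"] <= q_cutoff)).fillna(False)

    res = classify(res, q_cutoff)
    sbc = sb_change_in_hets(mid_f, mid_m, het_f, het_m)
    res["sb_change"] = np.where(res["focal"] & ~is_x, sbc, "")

    x_diag = male_x_dam_clustering(norm, samples, is_x & res["focal"].to_numpy())

    report = {"cross": str(cross_id), "n_transcripts": int(ng)}
    for cc in ("autosome", "X"):
        fam = res["chrom_class"] == cc
        n = int(fam.sum())
        step1_removed = int((fam & ~res["parental_de_pass"]).sum())
        step2_removed = int((fam & res["parental_de_pass"] & ~res["focal"]).sum())
        focal = int((fam & res["focal"]).sum())
        sub = {"n_tested": n, "step1_removed": step1_removed,
               "step2_removed": step2_removed, "n_focal": focal}
        if cc == "autosome":
            sub["n_ssd"] = int((fam & res["ssd"]).sum())
            sub["n_reversal"] = int((fam & res["reversal"]).sum())
            for sex in ("f", "m"):
                vc = res.loc[fam & res["focal"], f"class_{sex}"].value_counts()
                sub[f"class_{sex}"] = {k: int(v) for k, v in vc.items()}
            npoe = int((fam & res["poe_consistent"]).sum())
            sub["n_poe_sex_consistent"] = npoe
            sub["frac_poe_sex_consistent"] = npoe / focal if focal else float("nan")
        else:
            sub["n_female_nonadditive"] = int(
                (fam & (res["q_nonadd_f"] <= q_cutoff)).fillna(False).sum())
            sub["male_dam_clustering"] = x_diag
        report[cc] = sub
        log.info("cross %s %s: tested %d, step1 removed %d, step2 removed %d, "
                 "focal %d", cross_id, cc, n, step1_removed, step2_removed, focal)

    column_order = [
        "gene_id", "cross_id", "chrom_class", "high_line", "focal",
        "parental_de_pass", "sex_concordance_pass", "p_step1", "q_step1",
        "p_step2", "q_step2", "delta_f", "delta_m", "beta_h", "beta_sh",
        "p_nonadd_f", "q_nonadd_f", "p_nonadd_m", "q_nonadd_m",
        "p_sexdom", "q_sexdom", "p_poe_f", "q_poe_f", "p_poe_m", "q_poe_m",
        "poe_consistent", "lfc_sex", "class_f", "class_m", "ssd", "reversal",
        "sb_change", "phi", "converged",
    ]
    res = res[column_order]
    return CrossAnalysis(results=res, report=report, size_factors=sf)
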