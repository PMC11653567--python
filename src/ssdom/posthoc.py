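"""Summary statistics over per-transcript dominance results.

Major-axis (type II) regression of male vs. female dominance, chi-square
tests of equal proportions, Fisher's exact 2x2 test, the one-sided
(directional) Kolmogorov-Smirnov statistic D+, and Storey q-values with
pi0 estimated at a fixed lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class MAFit:
    """Major-axis regression fit of y on x."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r: float
    n: int


def ma_regression(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> MAFit:
    """Major-axis (type II) regression: leading eigenvector of the
    2x2 covariance matrix of (x, y).

    Appropriate when both variables carry error, as with dominance
    coefficients estimated in the two sexes.  The confidence interval
    rotates the axis by the angle whose squared sine is
    H = t^2 * l1 * l2 / ((n - 2) * (l1 - l2)^2), with l1 >= l2 the
    eigenvalues (Jolicoeur's method); H >= 1 gives an unbounded interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d arrays")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValidationError("major-axis regression needs n >= 3 finite points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("major-axis regression undefined with zero variance")
    cov = np.cov(x, y)
    evals, evecs = np.linalg.eigh(cov)
    l2, l1 = evals  # ascending
    v = evecs[:, 1]
    if v[0] == 0:
        raise ValidationError("major axis is vertical; slope undefined")
    slope = v[1] / v[0]
    intercept = float(np.mean(y) - slope * np.mean(x))
    r = float(np.corrcoef(x, y)[0, 1])
    t2 = stats.t.ppf(1 - alpha / 2, n - 2) ** 2
    if l1 == l2:
        lo, hi = -np.inf, np.inf
    else:
        H = t2 * l1 * l2 / ((n - 2) * (l1 - l2) ** 2)
        if H >= 1:
            lo, hi = -np.inf, np.inf
        else:
            rot = math.asin(math.sqrt(H))
            theta = math.atan(slope)
            t_lo, t_hi = theta - rot, theta + rot
            lo = math.tan(t_lo) if t_lo > -math.pi / 2 else -np.inf
            hi = math.tan(t_hi) if t_hi < math.pi / 2 else np.inf
    return MAFit(slope=float(slope), intercept=intercept,
                 ci_low=float(lo), ci_high=float(hi), r=r, n=n)


def chisq_equal_proportions(k: int, n: int) -> tuple[float, float]:
    """1-df goodness-of-fit of k out of n against 0.5/0.5.

    No continuity correction: chi2 = (k - n/2)^2/(n/2) + ((n-k) - n/2)^2/(n/2).
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if k < 0 or k > n:
        raise ValidationError(f"k={k} outside [0, {n}]")
    e = n / 2.0
    chi2 = (k - e) ** 2 / e + ((n - k) - e) ** 2 / e
    p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return float(chi2), p


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed one (relative
    tie tolerance 1e-12).  An empty margin returns p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("table must be 2x2 with non-negative integer counts")
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def ks_plus(reference: np.ndarray, test: np.ndarray) -> tuple[float, float]:
    """Directional Kolmogorov-Smirnov statistic D+ and asymptotic p.

    D+ = sup_t [ECDF_reference(t) - ECDF_test(t)], the one-sided
    alternative that the test sample is stochastically larger than the
    reference; p = exp(-2 D+^2 m n / (m + n)).
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    tst = np.sort(np.asarray(test, dtype=float))
    m, n = len(ref), len(tst)
    if m == 0 or n == 0:
        raise ValidationError("both samples must be non-empty")
    grid = np.concatenate([ref, tst])
    e_ref = np.searchsorted(ref, grid, side="right") / m
    e_tst = np.searchsorted(tst, grid, side="right") / n
    d_plus = float(max(np.max(e_ref - e_tst), 0.0))
    p = float(min(1.0, math.exp(-2.0 * d_plus ** 2 * m * n / (m + n))))
    return d_plus, p


def storey_pi0(pvals: np.ndarray, lam: float = 0.5) -> float:
    """pi0 estimate #{p > lambda} / ((1 - lambda) m), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return 1.0
    return min(1.0, float((p > lam).sum()) / ((1.0 - lam) * m))


def storey_qvalue(pvals: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single fixed lambda.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the sorted p-values
    (step-up), mapped back to the input order.  With pi0 = 1 this equals
    the Benjamini-Hochberg adjusted p-value.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be a 1-d array")
    if len(p) == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    pi0 = storey_pi0(p, lam)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def qvalues_with_na(pvals: pd.Series, lam: float = 0.5) -> pd.Series:
    """Storey q-values over the non-missing entries of a Series."""
    out = pd.Series(np.nan, index=pvals.index, dtype=float)
    ok = pvals.notna()
    if ok.any():
        out[ok] = storey_qvalue(pvals[ok].to_numpy(), lam)
    return out


def summarize_cross(results: pd.DataFrame, q_cutoff: float = 0.05) -> dict:
    """Headline statistics for one cross's dominance results.

    Expects the per-transcript result table (autosomes and X combined)
    and reports: the male-female dominance major-axis regression, SSD
    and reversal tallies, the greater/lesser sex-bias-in-heterozygotes
    proportion test, the directional KS comparison of |sex-bias|
    distributions, Fisher's test of SSD association with the direction
    of sex bias, and the X vs. autosome comparison of female
    nonadditivity.
    """
    aut = results[(results["chrom_class"] == "autosome") & results["focal"]]
    out: dict = {"n_focal_autosome": int(len(aut))}

    est = aut.dropna(subset=["delta_f", "delta_m"])
    if len(est) >= 3 and np.var(est["delta_m"]) > 0 and np.var(est["delta_f"]) > 0:
        fit = ma_regression(est["delta_m"].to_numpy(), est["delta_f"].to_numpy())
        r_p = stats.pearsonr(est["delta_m"], est["delta_f"]).pvalue if len(est) > 3 else np.nan
        out["ma"] = {"slope": fit.slope, "intercept": fit.intercept,
                     "ci": [fit.ci_low, fit.ci_high], "r": fit.r,
                     "r_pvalue": float(r_p), "n": fit.n}

    ssd = aut["ssd"].fillna(False).astype(bool)
    out["n_ssd"] = int(ssd.sum())
    out["n_reversal"] = int(aut["reversal"].fillna(False).astype(bool).sum())

    sbc = aut.loc[ssd, "sb_change"]
    n_greater = int((sbc == "greater").sum())
    n_lesser = int((sbc == "lesser").sum())
    out["n_sb_greater"] = n_greater
    out["n_sb_lesser"] = n_lesser
    if n_greater + n_lesser > 0:
        chi2, p = chisq_equal_proportions(n_greater, n_greater + n_lesser)
        out["sb_change_chisq"] = {"chi2": chi2, "p": p,
                                  "prop_greater": n_greater / (n_greater + n_lesser)}

    lfc = aut["lfc_sex"]
    if ssd.any() and (~ssd).any():
        d_plus, p = ks_plus(lfc[~ssd].abs().to_numpy(), lfc[ssd].abs().to_numpy())
        out["ks_sb"] = {"d_plus": d_plus, "p": p}

    fem = lfc > 0
    mal = lfc < 0
    table = [[int((fem & ssd).sum()), int((fem & ~ssd).sum())],
             [int((mal & ssd).sum()), int((mal & ~ssd).sum())]]
    out["fisher_sexbias_ssd"] = {"table": table, "p": fisher_exact_2x2(table)}

    x = results[(results["chrom_class"] == "X") & results["focal"]]
    out["n_focal_x"] = int(len(x))
    x_nonadd = (x["q_nonadd_f"] <= q_cutoff) & x["q_nonadd_f"].notna()
    aut_nonadd = (aut["q_nonadd_f"] <= q_cutoff) & aut["q_nonadd_f"].notna()
    out["n_x_female_nonadditive"] = int(x_nonadd.sum())
    out["n_autosome_female_nonadditive"] = int(aut_nonadd.sum())
    if len(x) > 0 and len(aut) > 0:
        table = [[int(aut_nonadd.sum()), int(len(aut) - aut_nonadd.sum())],
                 [int(x_nonadd.sum()), int(len(x) - x_nonadd.sum())]]
        out["fisher_aut_vs_x_nonadd"] = {"table": table, "p": fisher_exact_2x2(table)}
    return out
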