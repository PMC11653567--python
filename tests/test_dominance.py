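"""Dominance stage: delta arithmetic, orientation, filters, tests, classes."""

import numpy as np
import pandas as pd
import pytest

from ssdom import preprocess
from ssdom.dominance import (analyze_cross, classify, dominance_coefficient,
                             genotype_sex_means, male_x_dam_clustering,
                             orient_alleles, sb_change_in_hets)
from ssdom.nbglm import (build_design, encode_covariates, estimate_dispersion,
                         fit_nb, group_design, lrt_f)
from ssdom.simulate import SimConfig, simulate_cross

from conftest import make_samples

LN2 = np.log(2.0)


class TestDominanceCoefficient:
    def test_additive_gene_zero(self):
        assert dominance_coefficient(20.0, 10.0, 30.0) == pytest.approx(0.0)

    def test_hand_value(self):
        # AA = 10, BB = 30, het at 30 -> delta = ln(30/20) = ln 1.5
        assert dominance_coefficient(30.0, 10.0, 30.0) == pytest.approx(
            np.log(1.5), abs=1e-12)

    def test_het_below_midparent_negative(self):
        assert dominance_coefficient(15.0, 10.0, 30.0) < 0

    def test_zero_midparent_flagged_nan(self):
        assert np.isnan(dominance_coefficient(5.0, 0.0, 0.0))

    def test_invariant_to_line_swap(self):
        a = dominance_coefficient(25.0, 10.0, 30.0)
        b = dominance_coefficient(25.0, 30.0, 10.0)
        assert a == b


class TestOrientation:
    def _means(self, m1, m2):
        ones = np.ones(3)
        return {("AA", "female"): m1 * ones, ("AA", "male"): m1 * ones,
                ("BB", "female"): m2 * ones, ("BB", "male"): m2 * ones}

    def test_higher_line_designated_high(self):
        high = orient_alleles(self._means(10.0, 30.0), ("A", "B"))
        assert (high == "B").all()
        high = orient_alleles(self._means(30.0, 10.0), ("A", "B"))
        assert (high == "A").all()

    def test_tie_breaks_lexicographic(self):
        high = orient_alleles(self._means(10.0, 10.0), ("A", "B"))
        assert (high == "A").all()

    def test_idempotent(self):
        m = self._means(10.0, 30.0)
        assert (orient_alleles(m, ("A", "B"))
                == orient_alleles(m, ("B", "A"))).all()


class TestSbChange:
    def test_additive_gene_equal(self):
        assert sb_change_in_hets(20.0, 40.0, np.array([20.0]),
                                 np.array([40.0]))[0] == "equal"

    def test_hand_value_lesser(self):
        # mid_f 20 / mid_m 40 -> D_mid = 1; het 30/40 -> D_het ~ 0.415
        assert sb_change_in_hets(np.array([20.0]), np.array([40.0]),
                                 np.array([30.0]), np.array([40.0]))[0] == "lesser"

    def test_sex_swap_symmetric(self):
        a = sb_change_in_hets(np.array([20.0]), np.array([40.0]),
                              np.array([35.0]), np.array([40.0]))
        b = sb_change_in_hets(np.array([40.0]), np.array([20.0]),
                              np.array([40.0]), np.array([35.0]))
        assert a[0] == b[0]

    def test_zero_mean_flagged(self):
        assert sb_change_in_hets(np.array([0.0]), np.array([40.0]),
                                 np.array([30.0]), np.array([40.0]))[0] == ""


class TestClassify:
    def _row(self, **kw):
        base = dict(delta_f=np.nan, delta_m=np.nan, q_nonadd_f=np.nan,
                    q_nonadd_m=np.nan, q_sexdom=np.nan)
        base.update(kw)
        return pd.DataFrame([base])

    def test_reversal_pattern(self):
        out = classify(self._row(delta_f=0.4, q_nonadd_f=0.01, delta_m=-0.3,
                                 q_nonadd_m=0.02, q_sexdom=0.001))
        r = out.iloc[0]
        assert r["class_f"] == "dominant" and r["class_m"] == "recessive"
        assert r["ssd"] and r["reversal"]

    def test_ssd_without_reversal(self):
        out = classify(self._row(delta_f=0.4, q_nonadd_f=0.01, delta_m=0.1,
                                 q_nonadd_m=0.4, q_sexdom=0.01))
        r = out.iloc[0]
        assert r["class_f"] == "dominant" and r["class_m"] == "additive"
        assert r["ssd"] and not r["reversal"]

    def test_interaction_not_significant_never_ssd(self):
        out = classify(self._row(delta_f=0.5, q_nonadd_f=0.001, delta_m=-0.5,
                                 q_nonadd_m=0.001, q_sexdom=0.2))
        assert not out.iloc[0]["ssd"] and not out.iloc[0]["reversal"]


def _simulate_counts(mu_by_cell, samples, phi, rng, n_genes):
    """NB counts for an explicit per-(genotype, sex) mean table."""
    mu = np.zeros((n_genes, len(samples)))
    for j, row in samples.iterrows():
        mu[:, j] = mu_by_cell[(row["genotype"], row["sex"])]
    lam = rng.gamma(1 / phi, mu * phi)
    return rng.poisson(lam).astype(float)


class TestSexDominanceTest:
    def _power(self, delta_f, delta_m, n_genes=120, phi=0.01, seed=0):
        samples = make_samples(n_reps=3)
        rng = np.random.default_rng(seed)
        mid = 400.0
        cells = {}
        for geno in ("AA", "BB"):
            for sex in ("female", "male"):
                cells[(geno, sex)] = mid + (200.0 if geno == "BB" else -200.0)
        for geno in ("AB", "BA"):
            cells[(geno, "female")] = mid * np.exp(delta_f)
            cells[(geno, "male")] = mid * np.exp(delta_m)
        Y = _simulate_counts(cells, samples, phi, rng, n_genes)
        cov = encode_covariates(samples)
        sf = np.ones(len(samples))
        d_sat = group_design(samples, sf)
        full = build_design(cov, sf)
        red = full.drop("sex:h")
        rdf = len(samples) - d_sat.matrix.shape[1]
        ps = []
        for g in range(n_genes):
            phi_hat = estimate_dispersion(Y[g], d_sat)
            f, r = fit_nb(Y[g], full, phi_hat), fit_nb(Y[g], red, phi_hat)
            ps.append(lrt_f(f, r, 1, rdf)[1])
        return np.mean(np.array(ps) < 0.05)

    def test_equal_deltas_power_near_alpha(self):
        assert self._power(0.4, 0.4) < 0.15

    def test_opposite_deltas_high_power(self):
        # delta_f = +0.5, delta_m = -0.5 at depth 400, low dispersion
        assert self._power(0.5, -0.5) >= 0.8

    def test_statistic_invariant_to_line_relabeling(self, small_sim):
        _, cm, samples, genes, _ = small_sim
        sf = preprocess.size_factors(cm)
        res1 = analyze_cross(cm, samples, genes, sf).results
        relabeled = samples.copy()
        swap = {"A": "B", "B": "A"}
        relabeled["dam"] = relabeled["dam"].map(swap)
        relabeled["sire"] = relabeled["sire"].map(swap)
        relabeled["genotype"] = relabeled["dam"] + relabeled["sire"]
        res2 = analyze_cross(cm, relabeled, genes, sf).results
        ok = res1["p_sexdom"].notna()
        assert np.allclose(res1.loc[ok, "p_sexdom"], res2.loc[ok, "p_sexdom"],
                           rtol=1e-6)
        assert np.allclose(res1.loc[ok, "delta_f"], res2.loc[ok, "delta_f"],
                           rtol=1e-9)


class TestFocalFilter:
    def test_no_parental_difference_fails_step1(self, small_pipeline):
        out, truth = small_pipeline
        m = out.results.merge(truth, on=["gene_id", "cross_id"],
                              suffixes=("", "_t"))
        stable = m[~m["line_diff"] & (m["chrom_class"] == "autosome")]
        assert (stable["parental_de_pass"].mean()) < 0.12

    def test_strong_line_effects_recovered(self, small_pipeline):
        """Focal membership matches truth for clearly line-different,
        sexually concordant genes (|additive effect| >= 1 log2)."""
        out, truth = small_pipeline
        m = out.results.merge(truth, on=["gene_id", "cross_id"],
                              suffixes=("", "_t"))
        strong = m[(m["chrom_class"] == "autosome") & m["line_diff"]
                   & ~m["line_discordant"]
                   & (m["additive_f_ln"].abs() >= LN2)]
        assert len(strong) >= 20
        assert strong["focal"].mean() >= 0.9

    def test_sex_discordant_line_effect_fails_step2(self):
        """A strong line effect pointing opposite ways in the two sexes
        passes step 1 only via its (null) marginal effect and is removed
        by the sex-concordance step."""
        samples = make_samples(n_reps=3)
        rng = np.random.default_rng(7)
        cells = {}
        for sex, sign in (("female", 1.0), ("male", -1.0)):
            cells[("AA", sex)] = 300.0 * np.exp(-sign * 0.7)
            cells[("BB", sex)] = 300.0 * np.exp(sign * 0.7)
            cells[("AB", sex)] = 300.0
            cells[("BA", sex)] = 300.0
        Y = _simulate_counts(cells, samples, 0.01, rng, 60).astype(int)
        from ssdom.data_io import CountMatrix
        cm = CountMatrix([f"g{i}" for i in range(60)],
                         list(samples["sample_id"]), Y)
        genes = pd.DataFrame({"gene_id": cm.gene_ids, "chrom_class": "autosome"})
        res = analyze_cross(cm, samples, genes, np.ones(len(samples))).results
        assert res["sex_concordance_pass"].mean() < 0.2


class TestXLinked:
    def test_no_male_delta_on_x(self, small_pipeline):
        out, _ = small_pipeline
        x = out.results[out.results["chrom_class"] == "X"]
        assert x["delta_m"].isna().all()
        assert x["q_sexdom"].isna().all()
        assert x["p_nonadd_f"].notna().sum() > 0  # females are tested

    def test_male_het_x_clusters_with_dam(self, small_sim):
        """Informative (line-different) X transcripts place male
        heterozygotes with their dam's line, reflecting hemizygosity."""
        _, cm, samples, genes, truth = small_sim
        kept = samples[samples["sex"] == samples["generated_sex"]]
        kept = kept.reset_index(drop=True)
        cm2 = cm.subset_samples(list(kept["sample_id"]))
        sf = preprocess.size_factors(cm2)
        norm = cm2.counts / sf[None, :]
        informative = set(truth.loc[truth["line_diff"]
                                    & (truth["chrom_class"] == "X")
                                    & (truth["additive_f_ln"].abs() >= LN2),
                                    "gene_id"])
        x_mask = np.array([g in informative for g in cm2.gene_ids])
        assert x_mask.sum() >= 5
        frac = male_x_dam_clustering(norm, kept, x_mask)
        assert frac >= 0.8


class TestResultInvariants:
    def test_reversal_implies_ssd_and_q_bounds(self, small_pipeline):
        out, _ = small_pipeline
        res = out.results
        assert (~res["reversal"] | res["ssd"]).all()
        for col in [c for c in res.columns if c.startswith("q_")]:
            vals = res[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_classes_consistent_with_thresholds(self, small_pipeline):
        out, _ = small_pipeline
        res = out.results
        dom = res[res["class_f"] == "dominant"]
        assert (dom["delta_f"] > 0).all()
        assert (dom["q_nonadd_f"] <= 0.05).all()
        rec = res[res["class_m"] == "recessive"]
        assert (rec["delta_m"] < 0).all()

    def test_poe_consistency_definition(self, small_pipeline):
        out, _ = small_pipeline
        res = out.results
        pc = res[res["poe_consistent"]]
        assert ((pc["q_poe_f"] <= 0.05) & (pc["q_poe_m"] <= 0.05)).all()

    def test_report_counts_sum(self, small_pipeline):
        out, _ = small_pipeline
        for crep in out.report["crosses"].values():
            for cc in ("autosome", "X"):
                sub = crep[cc]
                assert (sub["step1_removed"] + sub["step2_removed"]
                        + sub["n_focal"] == sub["n_tested"])
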