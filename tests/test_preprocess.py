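"""Filtering, normalization, PCA and mis-sexed detection."""

import numpy as np
import pandas as pd
import pytest

from ssdom.data_io import CountMatrix
from ssdom.errors import ValidationError
from ssdom import preprocess
from ssdom.simulate import SimConfig, simulate_cross

from conftest import make_samples


def _cm(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    g = genes or [f"g{i}" for i in range(counts.shape[0])]
    s = samples or [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(g, s, counts)


def _gene_table(cm, classes):
    return pd.DataFrame({"gene_id": cm.gene_ids, "chrom_class": classes})


class TestFilterYLinked:
    def test_no_y_identity(self, tiny_counts):
        genes = _gene_table(tiny_counts, ["autosome", "X", "autosome", "X"])
        out = preprocess.filter_y_linked(tiny_counts, genes)
        assert out.gene_ids == tiny_counts.gene_ids
        assert (out.counts == tiny_counts.counts).all()

    def test_removes_only_y_preserving_order(self):
        cm = _cm(np.arange(500).reshape(100, 5))
        classes = ["Y" if i % 20 == 0 else "autosome" for i in range(100)]
        out = preprocess.filter_y_linked(cm, _gene_table(cm, classes))
        assert out.n_genes == 95
        assert out.gene_ids == [g for g, c in zip(cm.gene_ids, classes) if c != "Y"]

    def test_unannotated_gene_errors(self, tiny_counts):
        genes = pd.DataFrame({"gene_id": ["g1"], "chrom_class": ["autosome"]})
        with pytest.raises(ValidationError):
            preprocess.filter_y_linked(tiny_counts, genes)


class TestLowExpressionFilter:
    def _design(self):
        # 10 samples: 5 female then 5 male
        return pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(10)],
            "sex": ["female"] * 5 + ["male"] * 5,
            "excluded": [False] * 10,
        })

    def test_kept_if_either_sex_reaches_threshold(self):
        # female mean 3.2, male mean 2.8 -> kept under the all_sexes rule
        cm = _cm([[5, 3, 3, 3, 2, 4, 3, 3, 3, 1]])
        out = preprocess.filter_low_expression(cm, self._design(), 3.0)
        assert out.n_genes == 1

    def test_removed_when_below_in_every_sex(self):
        cm = _cm([[0] * 10, [2, 2, 2, 2, 2, 2, 2, 2, 2, 2]])
        out = preprocess.filter_low_expression(cm, self._design(), 3.0)
        assert out.n_genes == 0

    def test_boundary_mean_exactly_threshold_kept(self):
        # female mean exactly 3.0, male mean 0 -> strict < keeps it
        cm = _cm([[3, 3, 3, 3, 3, 0, 0, 0, 0, 0]])
        out = preprocess.filter_low_expression(cm, self._design(), 3.0)
        assert out.n_genes == 1

    def test_any_sex_scope_removes_sex_limited(self):
        cm = _cm([[9, 9, 9, 9, 9, 0, 0, 0, 0, 0]])
        out = preprocess.filter_low_expression(cm, self._design(), 3.0,
                                               scope="any_sex")
        assert out.n_genes == 0

    def test_commutes_with_y_filter(self, small_sim):
        _, cm, samples, genes, _ = small_sim
        a = preprocess.filter_low_expression(
            preprocess.filter_y_linked(cm, genes), samples)
        b = preprocess.filter_y_linked(
            preprocess.filter_low_expression(cm, samples), genes)
        assert a.gene_ids == b.gene_ids
        assert (a.counts == b.counts).all()


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        cm = _cm(np.tile([[10], [20], [30]], (1, 4)))
        assert np.allclose(preprocess.size_factors(cm), 1.0)

    def test_doubled_sample_hand_value(self):
        base = np.array([[10], [20], [400]])
        cm = _cm(np.hstack([base, 2 * base]))
        f = preprocess.size_factors(cm)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 1000, size=(50, 6))
        cm = _cm(counts)
        f = preprocess.size_factors(cm)
        perm = [3, 0, 5, 1, 4, 2]
        f2 = preprocess.size_factors(_cm(counts[:, perm]))
        assert np.allclose(f2, f[perm])

    def test_scale_equivariance_before_rescaling(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 1000, size=(80, 4))
        f = preprocess.size_factors(_cm(counts))
        scaled = counts.copy()
        scaled[:, 0] *= 8
        f2 = preprocess.size_factors(_cm(scaled))
        # ratios between factors: sample 0's factor grows 8-fold
        assert np.allclose((f2[0] / f2[1]) / (f[0] / f[1]), 8.0, rtol=1e-9)

    def test_no_allpositive_gene_errors(self):
        cm = _cm([[0, 5], [5, 0]])
        with pytest.raises(ValidationError, match="pseudo-reference"):
            preprocess.size_factors(cm)

    def test_design_aware_matches_plain_on_line_stable_data(self):
        """Without parental DE, the control-gene pass changes nothing much."""
        cfg = SimConfig(n_genes=600, crosses=(("A", "B"),), prop_line_diff=0.0,
                        prop_x_linked=0.0, prop_y_linked=0.0, n_mis_sexed=0,
                        seed=2)
        cm, samples, _, _ = simulate_cross(cfg)
        plain = preprocess.size_factors(cm)
        aware = preprocess.size_factors_design_aware(cm, samples)
        assert np.allclose(plain, aware, rtol=0.05)


class TestVst:
    def test_closed_forms(self):
        cm = _cm([[0, 7]])
        nm = preprocess.vst(cm, np.ones(2))
        assert nm.transformed[0, 0] == 0.0
        assert nm.transformed[0, 1] == pytest.approx(3.0)

    def test_monotone_in_counts(self):
        cm = _cm([[int(v)] for v in [0, 1, 5, 50, 500]])
        nm = preprocess.vst(cm, np.ones(1))
        assert (np.diff(nm.transformed[:, 0]) > 0).all()

    def test_rejects_nonpositive_factors(self, tiny_counts):
        with pytest.raises(ValidationError):
            preprocess.vst(tiny_counts, np.array([1, 0, 1, 1.0]))


class TestPCA:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(40, 3))
        cm = _cm(np.hstack([counts, counts[:, [0]]]))
        nm = preprocess.vst(cm, np.ones(4))
        res = preprocess.pca(nm)
        assert np.allclose(res.coords[0], res.coords[3], atol=1e-8)

    def test_components_orthonormal(self, small_sim):
        _, cm, samples, genes, _ = small_sim
        nm = preprocess.vst(cm, preprocess.size_factors(cm))
        res = preprocess.pca(nm)
        G = res.components @ res.components.T
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-8)
        assert res.pct_variance.sum() <= 100.0 + 1e-9
        assert (np.diff(res.pct_variance) <= 1e-9).all()

    def test_needs_two_samples(self):
        nm = preprocess.vst(_cm([[5]]), np.ones(1))
        with pytest.raises(ValidationError):
            preprocess.pca(nm)

    def test_no_sex_effect_no_pc1_separation(self):
        """Negative control: without sex effects PC1 does not split sexes."""
        cfg = SimConfig(n_genes=300, crosses=(("A", "B"),), prop_sex_biased=0.0,
                        prop_x_linked=0.0, prop_y_linked=0.0, n_mis_sexed=0,
                        seed=8)
        cm, samples, genes, _ = simulate_cross(cfg)
        nm = preprocess.vst(cm, preprocess.size_factors(cm))
        res = preprocess.pca(nm)
        sex = samples["sex"].to_numpy()
        pc1 = res.coords[:, 0]
        separated = (pc1[sex == "female"].min() > pc1[sex == "male"].max()
                     or pc1[sex == "male"].min() > pc1[sex == "female"].max())
        assert not separated


class TestMisSexedDetection:
    def _sim(self, n_mis):
        cfg = SimConfig(n_genes=300, crosses=(("A", "B"),), n_mis_sexed=n_mis,
                        prop_y_linked=0.0, seed=4)
        cm, samples, genes, _ = simulate_cross(cfg)
        nm = preprocess.vst(cm, preprocess.size_factors(cm))
        return nm, samples

    def test_clean_data_no_flags(self):
        nm, samples = self._sim(0)
        assert preprocess.detect_mis_sexed(nm, samples) == []

    def test_swapped_sample_flagged(self):
        nm, samples = self._sim(1)
        truly = samples.loc[samples["sex"] != samples["generated_sex"],
                            "sample_id"].tolist()
        assert preprocess.detect_mis_sexed(nm, samples) == truly

    def test_flagging_invariant_to_sample_order(self):
        nm, samples = self._sim(1)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(nm.sample_ids))
        from ssdom.preprocess import NormalizedMatrix
        nm2 = NormalizedMatrix(
            gene_ids=nm.gene_ids,
            sample_ids=[nm.sample_ids[i] for i in perm],
            size_factors=nm.size_factors[perm],
            normalized=nm.normalized[:, perm],
            transformed=nm.transformed[:, perm],
        )
        samples2 = samples.iloc[perm].reset_index(drop=True)
        assert (set(preprocess.detect_mis_sexed(nm2, samples2))
                == set(preprocess.detect_mis_sexed(nm, samples)))

    def test_single_sex_skips_with_warning(self, caplog):
        nm, samples = self._sim(0)
        fem = samples[samples["sex"] == "female"].reset_index(drop=True)
        from ssdom.preprocess import NormalizedMatrix
        idx = [nm.sample_ids.index(s) for s in fem["sample_id"]]
        nm_f = NormalizedMatrix(nm.gene_ids, list(fem["sample_id"]),
                                nm.size_factors[idx], nm.normalized[:, idx],
                                nm.transformed[:, idx])
        with caplog.at_level("WARNING", logger="ssdom"):
            out = preprocess.detect_mis_sexed(nm_f, fem)
        assert out == [] and "skipped" in caplog.text
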