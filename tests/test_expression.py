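import math

import numpy as np
import pandas as pd
import pytest

import xeprof as xp
from xeprof.expression import SampleTable


def table_from(values: dict, genes=None, meta=None):
    df = pd.DataFrame(values)
    if genes is not None:
        df.index = genes
    return SampleTable(df.astype(float), meta if meta is not None
                       else pd.DataFrame(columns=["study", "state", "sex"]))


def annotation_for(gene_lengths: dict, chrom="chr1"):
    return xp.GeneAnnotation([
        xp.GeneModel(g, chrom, i * 1000, i * 1000 + 500, L)
        for i, (g, L) in enumerate(gene_lengths.items())])


class TestComputeTpm:
    def test_single_gene_gets_the_whole_million(self):
        t = table_from({"s1": [7]}, genes=["g1"])
        tpm = xp.compute_tpm(t, annotation_for({"g1": 100}))
        assert tpm.values.loc["g1", "s1"] == pytest.approx(1e6)

    def test_hand_computed_two_gene_example(self):
        # counts 10,10 with lengths 100,200: rates 0.1, 0.05
        t = table_from({"s1": [10, 10]}, genes=["g1", "g2"])
        tpm = xp.compute_tpm(t, annotation_for({"g1": 100, "g2": 200}))
        assert tpm.values.loc["g1", "s1"] == pytest.approx(666666.67, rel=1e-6)
        assert tpm.values.loc["g2", "s1"] == pytest.approx(333333.33, rel=1e-6)

    def test_columns_conserve_one_million(self, standard_tpm):
        sums = standard_tpm.values.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_scale_invariance_per_sample(self, rng):
        counts = rng.integers(1, 500, size=(30, 2)).astype(float)
        genes = [f"g{i}" for i in range(30)]
        ann = annotation_for({g: int(L) for g, L in
                              zip(genes, rng.integers(100, 5000, 30))})
        t1 = table_from({"a": counts[:, 0], "b": counts[:, 1]}, genes=genes)
        t2 = table_from({"a": counts[:, 0] * 17, "b": counts[:, 1]}, genes=genes)
        pd.testing.assert_frame_equal(xp.compute_tpm(t1, ann).values,
                                      xp.compute_tpm(t2, ann).values)

    def test_all_zero_sample_is_error_naming_it(self):
        t = table_from({"bad": [0, 0]}, genes=["g1", "g2"])
        with pytest.raises(ValueError, match="bad"):
            xp.compute_tpm(t, annotation_for({"g1": 100, "g2": 100}))


class TestCallXist:
    def make_tpm(self, xist_value):
        t = table_from({"s1": [xist_value, 1e6 - xist_value]},
                       genes=["XIST", "other"])
        t.kind = "tpm"
        return t

    @pytest.mark.parametrize("tpm_value,status", [
        (1.3, "XIST_pos"),   # lower end of the observed expressed range
        (23.0, "XIST_pos"),
        (1.0, "XIST_neg"),   # exactly at threshold: strict inequality
        (0.2, "XIST_neg"),
    ])
    def test_threshold_is_strict(self, tpm_value, status):
        (call,) = xp.call_xist(self.make_tpm(tpm_value))
        assert call.status == status
        assert call.xist_tpm == pytest.approx(tpm_value)

    def test_missing_xist_gene_is_error(self):
        t = table_from({"s1": [5.0]}, genes=["g1"])
        t.kind = "tpm"
        with pytest.raises(KeyError, match="XIST"):
            xp.call_xist(t)

    def test_depends_only_on_the_xist_row(self, rng):
        genes = ["XIST"] + [f"g{i}" for i in range(9)]
        base = rng.uniform(0, 100, size=(10, 3))
        base[0] = [0.5, 1.5, 30.0]
        t1 = table_from({f"s{j}": base[:, j] for j in range(3)}, genes=genes)
        t1.kind = "tpm"
        other = base.copy()
        other[1:] = rng.uniform(0, 100, size=(9, 3))
        t2 = table_from({f"s{j}": other[:, j] for j in range(3)}, genes=genes)
        t2.kind = "tpm"
        assert [c.status for c in xp.call_xist(t1)] == \
               [c.status for c in xp.call_xist(t2)]

    def test_recovers_simulated_xist_status(self, standard_cohort, standard_tpm):
        calls = {c.sample_id: c.status for c in xp.call_xist(standard_tpm)}
        for sample, level in standard_cohort.truth["xist_level"].items():
            if 0.5 <= level <= 2:
                continue  # too close to the threshold to demand recovery
            expected = "XIST_pos" if level > 1 else "XIST_neg"
            assert calls[sample] == expected, sample


class TestFilterGenes:
    def random_tpm(self, rng, n_genes=100, n_samples=6):
        genes = [f"g{i:03d}" for i in range(n_genes)]
        vals = rng.uniform(0, 50, size=(n_genes, n_samples))
        vals[rng.random(n_genes) < 0.1] = 0.0  # some never-expressed genes
        t = table_from({f"s{j}": vals[:, j] for j in range(n_samples)}, genes=genes)
        t.kind = "tpm"
        return t

    def test_never_expressed_gene_removed(self, rng):
        t = self.random_tpm(rng)
        t.values.loc["g000"] = 0.0
        assert "g000" not in xp.filter_genes(t, "expressed_only")

    def test_exactly_ten_percent_of_expressed_removed(self, rng):
        t = self.random_tpm(rng)
        t.values[:] = np.abs(t.values) + 2.0  # all 100 genes expressed
        survivors = xp.filter_genes(t, "expressed_and_variable")
        assert len(survivors) == 90

    def test_ceil_rounding_of_variable_count(self, rng):
        t = self.random_tpm(rng, n_genes=11)
        t.values[:] = np.abs(t.values) + 2.0
        # ceil(0.1 * 11) = 2 removed
        assert len(xp.filter_genes(t, "expressed_and_variable")) == 9

    def test_matches_brute_force_recomputation(self, rng):
        t = self.random_tpm(rng, n_genes=137)
        survivors = xp.filter_genes(t, "expressed_and_variable")
        expressed = [g for g in t.genes if (t.values.loc[g] > 1).any()]
        logv = np.log2(t.values.loc[expressed] + 1)
        var = logv.var(axis=1, ddof=1)
        order = sorted(expressed, key=lambda g: (-var[g], g))
        expected = set(order[math.ceil(0.1 * len(expressed)):])
        assert survivors == expected

    def test_variable_filter_is_subset_of_expressed(self, rng):
        t = self.random_tpm(rng)
        assert xp.filter_genes(t, "expressed_and_variable") <= \
               xp.filter_genes(t, "expressed_only")

    def test_all_filtered_is_error(self):
        t = table_from({f"s{j}": [0.1] * 10 for j in range(2)},
                       genes=[f"g{i}" for i in range(10)])
        t.kind = "tpm"
        with pytest.raises(ValueError, match="filtered"):
            xp.filter_genes(t, "expressed_only")


class TestXlinkedSummary:
    def test_single_gene_mean_is_that_gene(self):
        ann = xp.GeneAnnotation([xp.GeneModel("xg", "chrX", 0, 10, 100)])
        t = table_from({"s1": [42.0]}, genes=["xg"])
        t.kind = "tpm"
        assert xp.xlinked_summary(t, ann)["s1"] == pytest.approx(42.0)

    def test_identical_samples_have_equal_state_means(self):
        ann = xp.GeneAnnotation([xp.GeneModel(f"xg{i}", "chrX", i, i + 1, 100)
                                 for i in range(3)])
        meta = pd.DataFrame({"study": ["A", "A"], "state": ["naive", "primed"],
                             "sex": ["female", "female"]},
                            index=["s1", "s2"])
        t = table_from({"s1": [1.0, 2, 3], "s2": [1.0, 2, 3]},
                       genes=["xg0", "xg1", "xg2"], meta=meta)
        t.kind = "tpm"
        by_state = xp.xlinked_summary(t, ann, group_by="state")
        assert by_state["naive"] == pytest.approx(by_state["primed"])

    def test_no_x_genes_is_error(self):
        ann = xp.GeneAnnotation([xp.GeneModel("a", "chr1", 0, 10, 100)])
        t = table_from({"s1": [1.0]}, genes=["a"])
        t.kind = "tpm"
        with pytest.raises(ValueError):
            xp.xlinked_summary(t, ann)

    def test_naive_exceed_primed_on_simulated_cohort(self, standard_cohort, standard_tpm):
        from xeprof.report import paired_by_study_index
        expressed = xp.filter_genes(standard_tpm, "expressed_only")
        means = xp.xlinked_summary(standard_tpm, standard_cohort.annotation,
                                   gene_subset=expressed)
        a, b, keys = paired_by_study_index(means, standard_tpm.meta)
        result = xp.compare(a, b, paired=True, test="paired_t", keys=keys)
        assert result.mean_a > result.mean_b
        assert result.p_value < 0.05


class TestFgfRatio:
    def make(self, fgf4, fgf2):
        t = table_from({"s1": [fgf4, fgf2]}, genes=["FGF4", "FGF2"])
        t.kind = "tpm"
        return t

    def test_equal_expression_gives_unity(self):
        assert xp.fgf_ratio(self.make(5.0, 5.0))["s1"] == pytest.approx(1.0)

    def test_zero_denominator_stays_finite(self):
        r = xp.fgf_ratio(self.make(10.0, 0.0))["s1"]
        assert np.isfinite(r) and r == pytest.approx(10.01 / 0.01)

    def test_high_naive_exceed_low_naive(self):
        cohort = xp.simulate_cohort(xp.high_low_naive_config(seed=3))
        tpm = xp.compute_tpm(cohort.counts, cohort.annotation)
        ratios = xp.fgf_ratio(tpm)
        high = ratios[[s for s in ratios.index if "_high_" in s]]
        low = ratios[[s for s in ratios.index if "_low_" in s]]
        assert high.min() > low.max()
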