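"""Pattern profiles and classification, ANOVA, trait correlation, Fisher."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bxdnet.datamodel import ExpressionMatrix, GeneSetCollection, ModuleAssignment
from bxdnet.module_stats import (
    anova_pattern,
    classify_pattern,
    enrichment_fisher,
    enrichment_table,
    module_condition_profile,
    module_trait_correlation,
    summarize_patterns,
)
from bxdnet.datamodel import PhenotypeTable


def _expr(rows: dict, condition):
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, condition=condition)


class TestProfile:
    def test_one_gene_module_equals_gene_rows(self):
        exprs = {"NOS": _expr({"g1": [1, 2, 3], "g2": [9, 9, 9]}, "NOS")}
        assign = ModuleAssignment(pd.Series({"g1": "M1", "g2": "M2"}))
        prof = module_condition_profile(exprs, assign)
        assert prof["M1"]["NOS"].tolist() == [1, 2, 3]

    def test_module_average(self):
        exprs = {"NOS": _expr({"g1": [1, 1, 1], "g2": [3, 3, 3]}, "NOS")}
        assign = ModuleAssignment(pd.Series({"g1": "M1", "g2": "M1"}))
        prof = module_condition_profile(exprs, assign)
        assert (prof["M1"]["NOS"] == 2.0).all()

    def test_pattern3_ordering_on_synthetic(self, dataset):
        truth = dataset.truth
        m3 = [m for m, p in truth.module_patterns.items() if p == 3][0]
        assign = ModuleAssignment(
            truth.module_labels[truth.module_labels == m3])
        prof = module_condition_profile(dataset.expression, assign)[m3]
        means = prof.mean()
        assert means["NOS"] < means["RSS"] < means["RSE"]
        assert means["NOS"] < means["NOE"] < means["RSE"]


def anova_oracle(groups):
    """Naive sums-of-squares one-way ANOVA."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return f, float(stats.f.sf(f, df1, df2))


class TestANOVA:
    def test_identical_groups_f_zero_p_one(self):
        f, p = anova_pattern([[1, 2], [1, 2]])
        assert f == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # groups (1,2,3), (4,5,6): SSB = 13.5, SSW = 4, F = 13.5/1 = 13.5
        f, p = anova_pattern([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(13.5)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sums_of_squares_oracle(self, seed):
        r = np.random.default_rng(seed)
        groups = [r.normal(size=r.integers(3, 12)) for _ in range(r.integers(2, 6))]
        f, p = anova_pattern(groups)
        f0, p0 = anova_oracle(groups)
        assert f == pytest.approx(f0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_type_one_error_calibration(self):
        """Null rejection rate at alpha = 0.05 over 10,000 simulations."""
        r = np.random.default_rng(123)
        data = r.normal(size=(10_000, 2, 10))
        rej = sum(anova_pattern([row[0], row[1]])[1] < 0.05 for row in data)
        assert rej / 10_000 == pytest.approx(0.05, abs=0.01)

    def test_zero_within_variance_boundary(self):
        f, p = anova_pattern([[1, 1, 1], [2, 2, 2]])
        assert p == 0.0 and np.isinf(f)


class TestClassifyPattern:
    def test_pattern1(self):
        means = {"NOS": 0, "RSS": 0, "NOE": 0.5, "RSE": 0.02}
        assert classify_pattern(means, 0.1) == 1

    def test_pattern2(self):
        means = {"NOS": 0, "RSS": 0.05, "NOE": -0.5, "RSE": 0.03}
        assert classify_pattern(means, 0.1) == 2

    def test_pattern3(self):
        means = {"NOS": 0, "RSS": 0.5, "NOE": 0.5, "RSE": 1.0}
        assert classify_pattern(means, 0.1) == 3

    def test_pattern4(self):
        means = {"NOS": 0, "RSS": 0.5, "NOE": -0.5, "RSE": -0.5}
        assert classify_pattern(means, 0.1) == 4

    def test_ambiguous_is_unclassified(self):
        # matches patterns 2 and 4 simultaneously -> no guess
        means = {"NOS": 0, "RSS": 0.5, "NOE": -0.5, "RSE": 0.0}
        assert classify_pattern(means, 0.1) == "unclassified"

    def test_flat_is_unclassified(self):
        means = {"NOS": 0, "RSS": 0.01, "NOE": -0.02, "RSE": 0.01}
        assert classify_pattern(means, 0.1) == "unclassified"

    def test_missing_condition_errors(self):
        with pytest.raises(ValueError, match="missing"):
            classify_pattern({"NOS": 0, "RSS": 1, "NOE": 1}, 0.1)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(-50, 50),
           st.tuples(*(st.floats(-1, 1) for _ in range(4))))
    def test_shift_invariance(self, shift, raw):
        means = dict(zip(("NOS", "RSS", "NOE", "RSE"), raw))
        shifted = {k: v + shift for k, v in means.items()}
        assert classify_pattern(means, 0.1) == classify_pattern(shifted, 0.1)

    def test_planted_labels_recovered(self, dataset):
        truth = dataset.truth
        assign = ModuleAssignment(
            truth.module_labels[truth.module_labels != "grey"])
        summary = summarize_patterns(dataset.expression, assign)
        hits = sum(summary.table.loc[m, "pattern"] == p
                   for m, p in truth.module_patterns.items())
        assert hits / len(truth.module_patterns) >= 0.9


class TestTraitCorrelation:
    def _mes(self, rng, n=10):
        return pd.DataFrame(
            rng.normal(size=(2, n)),
            index=["M1", "M2"], columns=[f"s{i}" for i in range(n)])

    def test_trait_equal_to_me(self, rng):
        mes = self._mes(rng)
        pheno = PhenotypeTable(pd.DataFrame(
            {"t": mes.loc["M1"]}, index=mes.columns))
        tab = module_trait_correlation(mes, pheno)
        row = tab[(tab.module == "M1") & (tab.trait == "t")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_trait_r_zero(self, rng):
        mes = self._mes(rng)
        me = mes.loc["M1"].to_numpy()
        me = me - me.mean()
        y = rng.normal(size=10)
        y = y - y.mean()
        y = y - (y @ me) / (me @ me) * me  # orthogonalized after centering
        pheno = PhenotypeTable(pd.DataFrame({"t": y}, index=mes.columns))
        tab = module_trait_correlation(mes, pheno)
        row = tab[(tab.module == "M1") & (tab.trait == "t")].iloc[0]
        assert abs(row.r) < 1e-10 and row.p > 0.99

    def test_t_distribution_quantile(self, rng):
        # r = 0.632, n = 10 -> t = 2.306 -> p ~ 0.05
        r, n = 0.632, 10
        t = r * np.sqrt((n - 2) / (1 - r * r))
        assert t == pytest.approx(2.306, abs=5e-3)
        p = 2 * stats.t.sf(t, n - 2)
        # construct data with this exact sample correlation
        base_z = stats.zscore(rng.normal(size=n))
        noise = rng.normal(size=n)
        noise = noise - noise.mean()
        noise -= (noise @ base_z) / (base_z @ base_z) * base_z
        y = r * base_z + np.sqrt(1 - r * r) * stats.zscore(noise)
        mes = pd.DataFrame([base_z], index=["M1"],
                           columns=[f"s{i}" for i in range(n)])
        pheno = PhenotypeTable(pd.DataFrame({"t": y}, index=mes.columns))
        row = module_trait_correlation(mes, pheno).iloc[0]
        assert row.r == pytest.approx(r, abs=1e-9)
        assert row.p == pytest.approx(p, abs=1e-9)
        assert row.display == (p < 0.1)

    def test_too_few_shared_strains_missing(self, rng):
        mes = self._mes(rng, n=3)
        pheno = PhenotypeTable(pd.DataFrame(
            {"t": [1.0, 2.0, 3.0]}, index=mes.columns))
        tab = module_trait_correlation(mes, pheno)
        assert tab["r"].isna().all()


def fisher_oracle_two_sided(a, b, c, d):
    """Exhaustive hypergeometric-sum two-sided Fisher p (math.comb only)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(k):
        return (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                / math.comb(n, row1))

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_hypergeometric_oracle(self, seed):
        r = np.random.default_rng(seed)
        while True:
            cells = r.integers(0, 20, 4)
            if cells.sum() <= 60 and cells.sum() >= 4:
                break
        a, b, c, d = map(int, cells)
        universe = {f"u{i}" for i in range(a + b + c + d)}
        ul = sorted(universe)
        module = set(ul[: a + b])
        gs = set(ul[:a]) | set(ul[a + b: a + b + c])
        res = enrichment_fisher(module, gs, universe)
        assert res["p"] == pytest.approx(
            fisher_oracle_two_sided(a, b, c, d), abs=1e-9)

    def test_maximal_overlap_significant(self):
        universe = {f"g{i}" for i in range(20)}
        half = {f"g{i}" for i in range(10)}
        res = enrichment_fisher(half, half, universe)
        assert res["p"] < 0.05 and res["significant"]

    def test_zero_overlap_tiny_sets_not_significant(self):
        universe = {f"g{i}" for i in range(1000)}
        res = enrichment_fisher({"g0"}, {"g1"}, universe)
        assert res["p"] == pytest.approx(1.0)

    def test_balanced_table_no_association(self):
        universe = {f"g{i}" for i in range(8)}
        module = {"g0", "g1", "g2", "g3"}
        gs = {"g0", "g1", "g4", "g5"}
        res = enrichment_fisher(module, gs, universe)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            enrichment_fisher({"a"}, {"a"}, set())

    def test_enrichment_table_on_planted_sets(self, small_dataset):
        truth = small_dataset.truth
        assign = ModuleAssignment(truth.module_labels)
        m1 = set(truth.module_labels[truth.module_labels == "M1"].index)
        marker_set = set(list(m1)[:20])  # cell-type markers drawn from M1
        coll = GeneSetCollection({"celltype1": marker_set})
        tab = enrichment_table(assign, coll)
        row = tab[(tab.module == "M1") & (tab.gene_set == "celltype1")].iloc[0]
        assert row.significant
        other = tab[(tab.module != "M1")]
        assert (other.p > 0.05).all()
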