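"""Marker regression, eQTL scan, SEM model fits and LEO scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from bxdnet import SyntheticDesign
from bxdnet.causality import (
    LOG10_FACTOR,
    LRS_CAP,
    SEMModelFit,
    eqtl_scan,
    fit_all_models,
    fit_sem_model,
    leo_score,
    marker_regression,
    qtl_scan,
    screen_causal_genes,
)
from bxdnet.datamodel import ExpressionMatrix, PhenotypeTable
from bxdnet.simulate import ModuleSpec, generate_genotypes


def gen_model(model, rng, n=200, b1=0.8, b2=0.8, noise=0.6):
    """Draw (G, X, Y) under one of the five single-anchor structures."""
    g = rng.integers(0, 2, n).astype(float)
    gc = g - g.mean()
    z = rng.standard_normal(n)
    e = rng.standard_normal(n) * noise
    if model == 1:
        x = z + b1 * gc
        y = b2 * x + e
    elif model == 2:
        y = b1 * gc + e
        x = z + b2 * y
    elif model == 3:
        x = z + b1 * gc
        y = b2 * gc + e
    elif model == 4:
        y = rng.standard_normal(n)
        x = z + b1 * gc + b2 * y
    else:
        x = z
        y = b1 * gc + b2 * x + e
    return g, x, y


class TestMarkerRegression:
    def test_null_lrs_mean_chi2(self):
        rng = np.random.default_rng(0)
        vals = [marker_regression(rng.standard_normal(1000),
                                  rng.integers(0, 2, 1000).astype(float)).lrs
                for _ in range(2000)]
        # LRS ~ chi2(1) under the null: mean 1
        assert np.mean(vals) == pytest.approx(1.0, abs=0.12)

    def test_perfect_fit_capped_and_flagged(self):
        g = np.array([0.0, 1, 0, 1, 0, 1, 0, 1])
        res = marker_regression(g.copy(), g)
        assert res.capped and res.lrs == LRS_CAP

    def test_lod_lrs_identity(self):
        rng = np.random.default_rng(1)
        res = marker_regression(rng.standard_normal(50),
                                rng.integers(0, 2, 50).astype(float))
        assert res.lod == pytest.approx(res.lrs / LOG10_FACTOR, abs=1e-12)
        # LRS 15 corresponds to LOD ~ 3 (the conventional threshold pairing)
        assert 15 / LOG10_FACTOR == pytest.approx(3.257, abs=1e-3)

    def test_monomorphic_marker_skipped(self):
        assert marker_regression(np.arange(10.0), np.zeros(10)) is None

    def test_too_few_strains_skipped(self):
        assert marker_regression(np.arange(5.0), np.array([0, 1, 0, 1, 0.0])) is None


@pytest.fixture(scope="module")
def sparse_geno():
    d = SyntheticDesign(n_strains=100, n_genes=10, n_markers=20,
                        marker_spacing_cm=25.0,
                        modules=[ModuleSpec(5, 1)], causal_triplets=[],
                        seed=2)
    return generate_genotypes(d)


class TestEQTL:
    def test_peak_at_or_adjacent_to_true_marker(self, sparse_geno):
        """Causal gene (b1 = 0.8, n = 100) maps back to its marker on a
        sparse, weakly linked map in >= 90% of seeds."""
        true_idx = 10
        gc = sparse_geno.codes.iloc[true_idx].to_numpy()
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = 0.8 * (gc - gc.mean()) + r.standard_normal(100)
            expr = ExpressionMatrix(pd.DataFrame(
                [x, r.standard_normal(100)], index=["causal", "noise"],
                columns=sparse_geno.strains))
            tab = eqtl_scan(expr, sparse_geno)
            sub = tab[tab.gene == "causal"].reset_index(drop=True)
            hits += abs(int(sub["lrs"].idxmax()) - true_idx) <= 1
        assert hits >= 45

    def test_null_gene_rarely_exceeds_lrs_15(self, sparse_geno):
        # P(chi2(1) > 15) ~ 1.1e-4; allow a generous multiple
        rng = np.random.default_rng(3)
        n_tests, n_hits = 0, 0
        for _ in range(100):
            expr = ExpressionMatrix(pd.DataFrame(
                rng.standard_normal((10, 100)),
                index=[f"g{i}" for i in range(10)],
                columns=sparse_geno.strains))
            tab = eqtl_scan(expr, sparse_geno)
            n_tests += len(tab)
            n_hits += int((tab["lrs"] > 15).sum())
        assert n_hits / n_tests < 1.5e-3

    def test_cis_flag_requires_same_chromosome(self, sparse_geno):
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [0.0]}, index=["g"])
        rng = np.random.default_rng(4)
        expr = ExpressionMatrix(pd.DataFrame(
            rng.standard_normal((2, 100)), index=["g", "h"],
            columns=sparse_geno.strains))
        tab = eqtl_scan(expr, sparse_geno, gene_positions=pos, cis_window=1e9)
        sub = tab[tab.gene == "g"].merge(
            sparse_geno.marker_map, left_on="marker", right_index=True)
        assert (sub.loc[sub["cis"], "chrom"] == "chr1").all()
        assert not sub.loc[sub["chrom"] != "chr1", "cis"].any()
        # gene without position: trans-only, flagged
        assert not tab[tab.gene == "h"]["has_position"].any()


def fml_bruteforce(s, model_id, grid=161):
    """Independent minimizer of F_ML: grid + polish over the two free
    correlations (models 1-3) or Powell multi-start over the five-parameter
    covariance structure (models 4-5)."""
    from bxdnet.causality import _MODEL_CONSTRAINTS, _corr_matrix, _f_ml
    c_idx, kind = _MODEL_CONSTRAINTS[model_id]
    free_idx = [i for i in range(3) if i != c_idx]
    logdet_s = np.linalg.slogdet(s)[1]
    pairs = [(0, 1), (0, 2), (1, 2)]

    if kind == "product":
        def fml(free):
            r = np.empty(3)
            r[free_idx[0]], r[free_idx[1]] = free
            r[c_idx] = free[0] * free[1]
            return _f_ml(_corr_matrix(*r), s, logdet_s)

        vals = np.linspace(-0.99, 0.99, grid)
        best, bx = np.inf, None
        for u in vals:
            for v in vals:
                f = fml((u, v))
                if f < best:
                    best, bx = f, (u, v)
        res = optimize.minimize(fml, bx, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-13})
        return min(best, float(res.fun))

    parents = list(pairs[c_idx])
    collider = ({0, 1, 2} - set(parents)).pop()

    def fml5(theta):
        v1, v2, ve = np.abs(theta[:3]) + 1e-12
        a, b = theta[3], theta[4]
        sigma = np.zeros((3, 3))
        p1, p2 = parents
        sigma[p1, p1] = v1
        sigma[p2, p2] = v2
        sigma[p1, collider] = sigma[collider, p1] = a * v1
        sigma[p2, collider] = sigma[collider, p2] = b * v2
        sigma[collider, collider] = a * a * v1 + b * b * v2 + ve
        return _f_ml(sigma, s, logdet_s)

    rng = np.random.default_rng(0)
    a0, b0 = s[parents[0], collider], s[parents[1], collider]
    best = np.inf
    for k in range(8):
        x0 = np.array([1.0, 1.0, max(1 - a0 * a0 - b0 * b0, 0.1), a0, b0])
        if k:
            x0 = x0 + rng.normal(0, 0.2, 5)
        res = optimize.minimize(fml5, x0, method="Powell",
                                options={"xtol": 1e-10, "ftol": 1e-13})
        best = min(best, float(res.fun))
    return best


class TestSEMFit:
    def test_constraint_satisfied_at_optimum(self, rng):
        g, x, y = gen_model(1, rng)
        fit = fit_sem_model(g, x, y, 1)
        p = fit.params
        assert p["r_gy"] == pytest.approx(p["r_gx"] * p["r_xy"], abs=1e-6)

    @pytest.mark.parametrize("model_id", [1, 2, 3, 4, 5])
    def test_chi2_matches_bruteforce_profile_search(self, model_id):
        rng = np.random.default_rng(model_id)
        g, x, y = gen_model(model_id, rng, n=50)
        arr = np.column_stack([g, x, y])
        s = np.corrcoef(arr, rowvar=False)
        fit = fit_sem_model(g, x, y, model_id)
        chi2_bf = (len(g) - 1) * fml_bruteforce(s, model_id)
        assert fit.chi2 == pytest.approx(chi2_bf, abs=1e-4)

    def test_chain_chi2_equals_partial_correlation_lrt(self, rng):
        """Closed-form oracle: the chain constraint is a zero partial
        correlation, whose Gaussian LRT is -(n-1) ln(1 - r_GY.X^2)."""
        g, x, y = gen_model(1, rng, n=150)
        s = np.corrcoef(np.column_stack([g, x, y]), rowvar=False)
        r = ((s[0, 2] - s[0, 1] * s[1, 2])
             / np.sqrt((1 - s[0, 1] ** 2) * (1 - s[1, 2] ** 2)))
        oracle = -(len(g) - 1) * np.log(1 - r**2)
        fit = fit_sem_model(g, x, y, 1)
        assert fit.chi2 == pytest.approx(oracle, abs=1e-6)

    def test_collider_bounded_by_marginal_correlation_lrt(self, rng):
        """The covariance-graph fit of a zero-covariance model never exceeds
        the naive marginal-correlation LRT (variances free vs pinned), and
        the two agree when the nuisance correlations vanish."""
        g, x, y = gen_model(4, rng, n=150)
        s = np.corrcoef(np.column_stack([g, x, y]), rowvar=False)
        naive = -(len(g) - 1) * np.log(1 - s[0, 2] ** 2)
        fit = fit_sem_model(g, x, y, 4)
        assert fit.chi2 <= naive + 1e-6
        # nuisance-free case: x, y unrelated to anything else
        g2 = rng.integers(0, 2, 4000).astype(float)
        x2, y2 = rng.standard_normal(4000), rng.standard_normal(4000)
        s2 = np.corrcoef(np.column_stack([g2, x2, y2]), rowvar=False)
        naive2 = -(len(g2) - 1) * np.log(1 - s2[0, 2] ** 2)
        fit2 = fit_sem_model(g2, x2, y2, 4)
        assert fit2.chi2 == pytest.approx(naive2, abs=0.02)

    def test_independent_variables_all_models_fit(self, rng):
        g = rng.integers(0, 2, 500).astype(float)
        x, y = rng.standard_normal(500), rng.standard_normal(500)
        fits = fit_all_models(g, x, y)
        assert all(f.p > 0.01 for f in fits)
        assert abs(leo_score(fits).leo) < 1.5

    def test_df_is_one(self, rng):
        g, x, y = gen_model(2, rng)
        assert all(f.df == 1 for f in fit_all_models(g, x, y))

    def test_too_few_triples_errors(self, rng):
        with pytest.raises(ValueError, match=">= 10"):
            fit_sem_model([0, 1] * 4, range(8), range(8), 1)

    def test_zero_variance_errors(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fit_sem_model(np.ones(20), rng.standard_normal(20),
                          rng.standard_normal(20), 1)

    def test_calibration_under_true_model_quick(self, rng):
        # p3 is uniform when model 3 generated the data (light version)
        ps = []
        for _ in range(150):
            g, x, y = gen_model(3, rng)
            ps.append(fit_sem_model(g, x, y, 3).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestLEO:
    def _fits(self, p1, alts):
        return [SEMModelFit(1, 0.0, 1, p1)] + [
            SEMModelFit(m, 0.0, 1, p) for m, p in zip((2, 3, 4, 5), alts)]

    def test_ten_fold_ratio_gives_score_one(self):
        res = leo_score(self._fits(0.4, [0.04, 0.01, 0.003, 0.0001]))
        assert res.leo == pytest.approx(1.0)
        assert res.passes

    def test_threshold_is_three_point_two_fold(self):
        # LEO 0.5 <=> p1 / p_alt = 10^0.5 ~ 3.2
        assert 10 ** 0.5 == pytest.approx(3.16, abs=0.01)
        res = leo_score(self._fits(0.32, [0.1, 0.01, 0.01, 0.01]))
        assert res.leo == pytest.approx(np.log10(3.2), abs=0.01)
        assert res.passes  # 0.505 >= 0.5

    def test_equal_best_alternative_scores_zero(self):
        res = leo_score(self._fits(0.2, [0.2, 0.1, 0.05, 0.01]))
        assert res.leo == 0.0 and not res.passes

    def test_log_ratio_antisymmetry(self):
        a = leo_score(self._fits(0.4, [0.04, 0.01, 0.01, 0.01]))
        b = leo_score(self._fits(0.04, [0.4, 0.01, 0.01, 0.01]))
        assert a.leo == pytest.approx(-b.leo)

    def test_zero_p_floored(self, rng):
        res = leo_score(self._fits(0.5, [0.0, 0.0, 0.0, 0.0]))
        assert np.isfinite(res.leo) and res.leo > 0

    def test_needs_five_fits(self):
        with pytest.raises(ValueError):
            leo_score(self._fits(0.5, [0.1, 0.1, 0.1, 0.1])[:4])

    def test_stored_invariant(self):
        res = leo_score(self._fits(0.3, [0.03, 0.02, 0.01, 0.005]))
        recomputed = np.log10(res.fits[0].p / max(f.p for f in res.fits[1:]))
        assert res.leo == pytest.approx(recomputed, abs=1e-9)


class TestScreen:
    def test_true_gene_ranks_first(self):
        """Marker-driven causal gene vs factor-driven decoys, 12 seeds."""
        hits = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = 100
            g = rng.integers(0, 2, n).astype(float)
            gc = g - g.mean()
            f = rng.standard_normal(n)  # module factor, independent of G
            true = np.sqrt(0.7) * f + np.sqrt(0.3) * rng.standard_normal(n) + 0.8 * gc
            y = 0.8 * true + 0.6 * rng.standard_normal(n)
            rows = {"true_gene": true}
            for j in range(30):
                rows[f"decoy{j:02d}"] = (np.sqrt(0.7) * f
                                         + np.sqrt(0.3) * rng.standard_normal(n))
            expr = ExpressionMatrix(pd.DataFrame(
                rows, index=[f"s{i}" for i in range(n)]).T)
            pheno = PhenotypeTable(pd.DataFrame({"t": y}, index=expr.strains))
            df = screen_causal_genes(g, expr, pheno)
            hits += df.iloc[0]["gene"] == "true_gene"
        assert hits >= 10  # >= 80%

    def test_empty_phenotypes_empty_ranking(self, rng):
        expr = ExpressionMatrix(pd.DataFrame(
            rng.standard_normal((3, 20)),
            index=list("abc"), columns=[f"s{i}" for i in range(20)]))
        pheno = PhenotypeTable(pd.DataFrame(index=expr.strains))
        df = screen_causal_genes(rng.integers(0, 2, 20).astype(float),
                                 expr, pheno)
        assert df.empty


def test_qtl_scan_finds_planted_marker(small_dataset):
    qtl = qtl_scan(small_dataset.phenotypes, small_dataset.genotypes)
    truth = small_dataset.truth.causal_triplets[0]
    sub = qtl[qtl.trait == truth["phenotype"]]
    peak = sub.loc[sub["lrs"].idxmax(), "marker"]
    geno = small_dataset.genotypes
    # peak linked to the true marker (same chromosome, high correlation)
    r = np.corrcoef(geno.codes.loc[peak], geno.codes.loc[truth["marker"]])[0, 1]
    assert abs(r) > 0.5
    # every emitted record satisfies the LOD = LRS / (2 ln 10) identity
    assert np.allclose(qtl["lod"], qtl["lrs"] / LOG10_FACTOR, atol=1e-6)
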