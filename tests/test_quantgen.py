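"""GRM, weighted GBLUP/REML, RLRT, bivariate model, GWAS and contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from halfsibmap import popsim
from halfsibmap.maps import PhysicalMap
from halfsibmap.popsim import MISSING
from halfsibmap.quantgen import (
    anova_sex_breed,
    annotate_signals,
    benjamini_hochberg,
    build_grm,
    filter_missingness,
    fit_bivariate_gblup,
    fit_weighted_gblup,
    gwas_scan,
    region_variance,
    rlrt_genomic_variance,
    signal_regions,
)


@pytest.fixture(scope="module")
def parents_grm():
    rng = np.random.default_rng(99)
    founders = popsim.simulate_founders(120, 400, rng=rng)
    geno = founders.haplotypes.sum(axis=1)
    G, f, used = build_grm(geno)
    return geno, G


class TestFilterMissingness:
    def test_individual_then_marker_order(self):
        geno = np.zeros((4, 10), dtype=np.int8)
        geno[0, :] = MISSING          # individual 100% missing: dropped first
        geno[1:, 0] = MISSING         # marker 0 fully missing among the rest
        ids = np.array(list("abcd"), dtype=object)
        markers = PhysicalMap(
            np.array([f"m{k}" for k in range(10)], dtype=object), np.ones(10),
            np.arange(1, 11),
        )
        g2, ids2, m2 = filter_missingness(geno, ids, markers)
        assert list(ids2) == ["b", "c", "d"]
        assert list(m2.marker_id) == [f"m{k}" for k in range(1, 10)]

    def test_thresholds_inclusive(self):
        geno = np.zeros((10, 5), dtype=np.int8)
        geno[0, 0] = MISSING  # individual a: 20% missing -> kept (<= 0.20)
        geno[1, 1] = MISSING
        geno[2, 1] = MISSING  # marker 1: 20% missing -> kept
        ids = np.array([f"i{k}" for k in range(10)], dtype=object)
        markers = PhysicalMap(np.array(list("abcde"), dtype=object), np.ones(5),
                              np.arange(1, 6))
        g2, ids2, m2 = filter_missingness(geno, ids, markers)
        assert ids2.size == 10 and m2.n_markers == 5


class TestGRM:
    def test_symmetric_unit_diagonal(self, parents_grm):
        geno, G = parents_grm
        np.testing.assert_allclose(G, G.T, atol=1e-12)
        assert abs(G.diagonal().mean() - 1.0) < 0.05

    def test_duplicate_rows_fully_related(self):
        rng = np.random.default_rng(1)
        founders = popsim.simulate_founders(30, 200, rng=rng)
        geno = founders.haplotypes.sum(axis=1)
        geno = np.vstack([geno, geno[:1]])  # duplicate the first individual
        G, _, _ = build_grm(geno)
        assert G[0, -1] == pytest.approx(G[0, 0])

    def test_monomorphic_excluded(self):
        geno = np.array([[0, 1], [0, 2], [0, 1]], dtype=np.int8)
        G, f, used = build_grm(geno)
        assert list(used) == [1]


class TestWeightedGBLUP:
    def test_equal_weights_match_unweighted(self, parents_grm):
        """Constant weights only rescale sigma_e2; the fit itself is unchanged."""
        _, G = parents_grm
        rng = np.random.default_rng(2)
        y = rng.standard_normal(G.shape[0])
        a = fit_weighted_gblup(y, G)
        b = fit_weighted_gblup(y, G, weights=np.full(y.size, 3.0))
        assert b.sigma_g2 == pytest.approx(a.sigma_g2, rel=1e-3)
        assert b.sigma_e2 == pytest.approx(3.0 * a.sigma_e2, rel=1e-3)
        assert b.mu[0] == pytest.approx(a.mu[0], abs=1e-6)
        np.testing.assert_allclose(b.blup, a.blup, atol=1e-5)

    def test_matches_mixed_model_equations(self, parents_grm):
        """BLUP solutions equal a direct Henderson MME solve (<= 50 parents)."""
        _, G = parents_grm
        n = 40
        rng = np.random.default_rng(3)
        Gs = G[:n, :n] + 1e-6 * np.eye(n)
        w = rng.integers(1, 10, n).astype(float)
        y = rng.standard_normal(n)
        sg2, se2 = 0.4, 0.6
        fit = fit_weighted_gblup(y, Gs, weights=w, fix_lambda=sg2 / se2)
        Dinv = np.diag(w)
        X = np.ones((n, 1))
        A = np.block(
            [
                [X.T @ Dinv @ X, X.T @ Dinv],
                [Dinv @ X, Dinv + se2 / sg2 * np.linalg.inv(Gs)],
            ]
        )
        rhs = np.concatenate([X.T @ Dinv @ y, Dinv @ y])
        sol = np.linalg.solve(A, rhs)
        assert fit.mu[0] == pytest.approx(sol[0], abs=1e-8)
        np.testing.assert_allclose(fit.blup, sol[1:], atol=1e-6)

    def test_h2_recovery(self, parents_grm):
        _, G = parents_grm
        n = G.shape[0]
        L = np.linalg.cholesky(G + 1e-6 * np.eye(n))
        rng = np.random.default_rng(4)
        ests = []
        for _ in range(10):
            u = L @ rng.standard_normal(n) * np.sqrt(0.5)
            e = rng.standard_normal(n) * np.sqrt(0.5)
            ests.append(fit_weighted_gblup(u + e, G).h2)
        assert abs(np.mean(ests) - 0.5) < 0.12

    def test_negative_weights_rejected(self, parents_grm):
        _, G = parents_grm
        with pytest.raises(ValueError):
            fit_weighted_gblup(np.zeros(G.shape[0]), G, weights=np.zeros(G.shape[0]))


class TestRLRT:
    def test_boundary_and_quantile_values(self, parents_grm):
        _, G = parents_grm

        class F:  # minimal stand-ins with known log-likelihoods
            def __init__(self, ll):
                self.loglik = ll

        assert rlrt_genomic_variance(F(1.0), F(1.0)) == 0.5
        assert rlrt_genomic_variance(F(2.706 / 2), F(0.0)) == pytest.approx(0.05, abs=1e-3)

    def test_negative_lrt_clamped(self):
        class F:
            def __init__(self, ll):
                self.loglik = ll

        with pytest.warns(UserWarning):
            p = rlrt_genomic_variance(F(0.0), F(1.0))
        assert p == 0.5


class TestBivariate:
    def test_shared_effect_high_correlation(self):
        rng = np.random.default_rng(11)
        founders = popsim.simulate_founders(200, 300, rng=rng)
        geno = founders.haplotypes.sum(axis=1)
        G, _, _ = build_grm(geno)
        L = np.linalg.cholesky(G + 1e-6 * np.eye(200))
        u = L @ rng.standard_normal(200)
        y_s = 1.0 + u[:100] + 0.6 * rng.standard_normal(100)
        y_d = 2.5 + u[100:] + 0.6 * rng.standard_normal(100)
        fit = fit_bivariate_gblup(y_s, y_d, G)
        assert fit.correlation > 0.5
        # sex fixed effect recovered
        assert fit.b[1] == pytest.approx(1.5, abs=0.6)

    def test_independent_effects_low_correlation(self):
        """Independent genetic effects per sex: mean |corr| well below the
        shared-effect recovery level (single-rep estimates are noisy at
        n = 100 per sex, so average over repetitions)."""
        rng = np.random.default_rng(12)
        founders = popsim.simulate_founders(200, 300, rng=rng)
        geno = founders.haplotypes.sum(axis=1)
        G, _, _ = build_grm(geno)
        L = np.linalg.cholesky(G + 1e-6 * np.eye(200))
        corrs = []
        for _ in range(3):
            us = L @ rng.standard_normal(200)
            ud = L @ rng.standard_normal(200)
            y_s = us[:100] + 0.6 * rng.standard_normal(100)
            y_d = ud[100:] + 0.6 * rng.standard_normal(100)
            corrs.append(fit_bivariate_gblup(y_s, y_d, G).correlation)
        assert abs(np.mean(corrs)) < 0.4

    def test_one_sex_absent_rejected(self, parents_grm):
        _, G = parents_grm
        with pytest.raises(ValueError):
            fit_bivariate_gblup(np.array([]), np.zeros(3), G[:3, :3])


class TestGWAS:
    def test_planted_snp_top_ranked(self, parents_grm):
        geno, G = parents_grm
        n = geno.shape[0]
        markers = PhysicalMap(
            np.array([f"s{j}" for j in range(geno.shape[1])], dtype=object),
            np.ones(geno.shape[1]),
            np.arange(geno.shape[1]) * 1000 + 1,
        )
        rng = np.random.default_rng(13)
        hits = 0
        for rep in range(3):
            planted = 50 + rep
            y = 1.0 * geno[:, planted] + rng.standard_normal(n)
            res = gwas_scan(y, geno, markers, G)
            top5 = res.nsmallest(5, "P")["snp"].tolist()
            hits += f"s{planted}" in top5
        assert hits >= 2

    def test_missing_genotypes_excluded_not_imputed(self, parents_grm):
        geno, G = parents_grm
        g = geno.copy()
        g[:5, 10] = MISSING
        markers = PhysicalMap(
            np.array([f"s{j}" for j in range(g.shape[1])], dtype=object),
            np.ones(g.shape[1]), np.arange(g.shape[1]) * 1000 + 1,
        )
        rng = np.random.default_rng(14)
        y = rng.standard_normal(g.shape[0])
        res = gwas_scan(y, g[:, :20], markers.subset(np.arange(20)), G)
        assert "s10" in set(res["snp"])  # still tested, on the reduced subset

    def test_monomorphic_skipped(self, parents_grm):
        geno, G = parents_grm
        g = geno[:, :10].copy()
        g[:, 0] = 2
        markers = PhysicalMap(
            np.array([f"s{j}" for j in range(10)], dtype=object),
            np.ones(10), np.arange(10) * 1000 + 1,
        )
        res = gwas_scan(np.zeros(g.shape[0]) + np.random.default_rng(0).standard_normal(g.shape[0]),
                        g, markers, G)
        assert "s0" not in set(res["snp"])


class TestRegionsAndAnnotation:
    def _results(self):
        return pd.DataFrame(
            {
                "snp": ["a", "b", "c"],
                "chrom": [1, 1, 1],
                "bp": [10_000_000, 10_400_000, 30_000_000],
                "freq": [0.5, 0.1, 0.25],
                "effect": [1.0, 2.0, 1.0],
                "se": [0.1, 0.1, 0.1],
                "T": [3.0, 4.0, 1.0],
                "P": [1e-6, 1e-7, 0.3],
            }
        )

    def test_region_variance_hand_computed(self):
        res = self._results()
        out = region_variance(res, 1, 0, 50_000_000)
        # 2*0.5*0.5*1 + 2*0.1*0.9*4 + 2*0.25*0.75*1 = 0.5 + 0.72 + 0.375
        assert out["sigma_x2"] == pytest.approx(0.5 + 0.72 + 0.375)
        assert out["min_P"] == pytest.approx(1e-7)

    def test_single_snp_region(self):
        res = self._results()
        out = region_variance(res, 1, 9_000_000, 11_000_000)
        assert out["n_snps"] == 2

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_variance(self._results(), 2, 0, 1)

    def test_signal_regions_min_support(self):
        res = self._results()
        assert len(signal_regions(res, min_signals=3)) == 0
        assert len(signal_regions(res, min_signals=2)) == 1

    def test_annotation_window(self):
        res = self._results().iloc[:1]
        genes = pd.DataFrame(
            {
                "chrom": [1, 1],
                "start": [10_400_000, 10_600_000],
                "end": [10_450_000, 10_700_000],
                "name": ["inside", "outside"],
            }
        )
        out = annotate_signals(res, genes, window_bp=500_000)
        assert list(out["gene"]) == ["inside"]

    def test_empty_gene_table_warns(self):
        with pytest.warns(UserWarning):
            out = annotate_signals(self._results(), None)
        assert len(out) == 0


class TestBenjaminiHochberg:
    def test_textbook_case(self):
        np.testing.assert_allclose(
            benjamini_hochberg(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)


class TestAnova:
    def _table(self, rng, interaction=0.0):
        rows = []
        for sex, s_eff in (("M", 1.0), ("F", 0.0)):
            for breed, b_eff in (("X", 0.0), ("Y", 0.5), ("Z", -0.3)):
                for _ in range(15):
                    y = 20 + s_eff + b_eff + interaction * (sex == "M") * (breed == "Y")
                    rows.append((sex, breed, 10, y + 0.3 * rng.standard_normal()))
        return pd.DataFrame(rows, columns=["sex", "breed", "n_progeny", "nco"])

    def test_balanced_lsmeans_equal_cell_means(self):
        rng = np.random.default_rng(1)
        df = self._table(rng)
        out = anova_sex_breed(df)
        for _, row in out["lsmeans_sex"].iterrows():
            cell = df[df["sex"] == row["sex"]]["nco"].mean()
            assert row["lsmean"] == pytest.approx(cell, abs=1e-9)

    def test_two_groups_tukey_equals_t_test(self):
        rng = np.random.default_rng(2)
        df = self._table(rng)
        out = anova_sex_breed(df)
        pw = out["pairwise_sex"].iloc[0]
        dfres = out["model"].df_resid
        p_t = 2 * stats.t.sf(abs(pw["t"]), dfres)
        assert pw["P_tukey"] == pytest.approx(p_t, rel=1e-6)

    def test_weights_equal_record_replication(self):
        rng = np.random.default_rng(3)
        df = self._table(rng)
        df["n_progeny"] = rng.integers(1, 6, len(df))
        out_w = anova_sex_breed(df)
        rep = df.loc[df.index.repeat(df["n_progeny"])].copy()
        rep["n_progeny"] = 1
        out_r = anova_sex_breed(rep)
        np.testing.assert_allclose(
            out_w["model"].params.to_numpy(), out_r["model"].params.to_numpy(),
            atol=1e-10,
        )

    def test_global_f_detects_sex_effect(self):
        rng = np.random.default_rng(4)
        out = anova_sex_breed(self._table(rng))
        assert out["anova"].loc["C(sex)", "PR(>F)"] < 0.01
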