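"""Association models, kinship, eigenMT and hierarchical FDR machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ptqtl import qtlmap, syndata


class TestCisPairs:
    def _phen(self, pos, gene="G1"):
        return pd.DataFrame(
            {"id": ["p1"], "chrom": ["chr1"], "pos": [pos], "gene_id": [gene]}
        )

    def test_window_boundary_inclusive(self):
        variants = pd.DataFrame(
            {"id": ["a", "b"], "chrom": "chr1", "pos": [1_100_000, 1_100_001],
             "ref": "A", "alt": "G", "gene_id": ["G1", "G1"]}
        )
        geno = qtlmap.GenotypeMatrix(
            ["d1", "d2"], variants, np.array([[0, 1], [1, 2]], float)
        )
        pairs = qtlmap.cis_pairs(self._phen(1_000_000), geno, window=100_000)
        assert list(pairs["p1"]) == [0]

    def test_same_gene_rule(self, toy_geno):
        pairs = qtlmap.cis_pairs(
            self._phen(60_000), toy_geno, window=100_000, same_gene=True
        )
        # v4 is inside the window but has no gene assignment
        assert set(pairs["p1"]) == {0, 1, 2}

    def test_utr_end_anchor(self):
        variants = pd.DataFrame(
            {"id": ["a"], "chrom": "chr1", "pos": [70_000], "ref": "A",
             "alt": "G"}
        )
        geno = qtlmap.GenotypeMatrix(["d1", "d2"], variants,
                                     np.array([[0], [1]], float))
        phen = pd.DataFrame(
            {"id": ["p1"], "chrom": ["chr1"], "start": [10_000], "end": [50_000]}
        )
        pairs = qtlmap.cis_pairs(phen, geno, window=25_000)
        assert list(pairs["p1"]) == [0]  # 20 kb downstream of the end anchor


class TestGenotypeClassFilter:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([0, 0, 0, 0, 1, 1], True),    # het=2, hom-minor=0
            ([0, 0, 0, 1, 1, 2], False),   # het=2, hom-minor=1
            ([2, 2, 2, 2, 2, 1], False),   # het=1 (minor allele is REF here)
            ([0, 0, 1, 1, 2, 2], True),    # het=2, hom-minor=2
        ],
    )
    def test_rules(self, column, expected):
        variants = pd.DataFrame(
            {"id": ["v"], "chrom": "chr1", "pos": [1], "ref": "A", "alt": "G"}
        )
        geno = qtlmap.GenotypeMatrix(
            [f"d{i}" for i in range(6)], variants,
            np.array(column, float)[:, None],
        )
        mask = qtlmap.filter_variants_by_genotype_class(geno)
        assert bool(mask[0]) is expected


class TestBinomialEdqtl:
    def test_exact_null(self):
        dosage = np.array([0, 0, 1, 1, 2, 2], float)
        edited = np.full(6, 5)
        total = np.full(6, 10)
        res = qtlmap.fit_binomial_edqtl(edited, total, dosage, min_donors=5)
        assert res.beta == pytest.approx(0.0, abs=1e-10)
        assert res.p_nominal == pytest.approx(1.0, abs=1e-8)

    def test_monomorphic_skipped(self):
        res = qtlmap.fit_binomial_edqtl(
            np.full(12, 5), np.full(12, 10), np.ones(12), min_donors=5
        )
        assert res.flag == "monomorphic"
        assert np.isnan(res.p_nominal)

    def test_matches_independent_irls_oracle(self):
        """Newton/IRLS oracle via statsmodels GLM on a fixed small dataset."""
        rng = np.random.default_rng(1)
        n = 20
        dosage = rng.integers(0, 3, n).astype(float)
        total = rng.integers(20, 60, n)
        cov = rng.standard_normal((n, 2))
        logit = -1 + 0.8 * dosage + 0.3 * cov[:, 0]
        edited = rng.binomial(total, 1 / (1 + np.exp(-logit)))
        res = qtlmap.fit_binomial_edqtl(edited, total, dosage, cov, min_donors=5)
        X = sm.add_constant(np.column_stack([dosage, cov]))
        oracle = sm.GLM(np.column_stack([edited, total - edited]), X,
                        family=sm.families.Binomial()).fit()
        assert res.beta == pytest.approx(oracle.params[1], abs=1e-6)
        assert res.se == pytest.approx(oracle.bse[1], abs=1e-6)

    def test_zero_coverage_donors_dropped(self):
        dosage = np.array([0, 0, 1, 1, 2, 2, 0], float)
        edited = np.array([2, 3, 2, 3, 2, 3, 0])
        total = np.array([10, 10, 10, 10, 10, 10, 0])
        res = qtlmap.fit_binomial_edqtl(edited, total, dosage, min_donors=5)
        assert res.n_donors == 6

    def test_separation_flagged_not_crashed(self):
        dosage = np.array([0.0] * 10 + [2.0] * 10)
        edited = np.array([0] * 10 + [30] * 10)
        total = np.full(20, 30)
        res = qtlmap.fit_binomial_edqtl(edited, total, dosage, min_donors=5)
        assert np.isnan(res.p_nominal)
        assert res.flag in ("separation", "nonconverged")


class TestKinship:
    def test_identical_and_opposite_donors(self):
        variants = pd.DataFrame(
            {"id": [f"v{i}" for i in range(4)], "chrom": "chr1",
             "pos": range(1, 5), "ref": "A", "alt": "G"}
        )
        dosage = np.array([[0, 2, 1, 0], [0, 2, 1, 0], [2, 0, 1, 2]], float)
        K = qtlmap.compute_ibs_kinship(
            qtlmap.GenotypeMatrix(["a", "b", "c"], variants, dosage),
            min_variants=1,
        ).values
        assert K[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(K), 1.0)
        # donors differing by 2 at every non-shared variant
        dos2 = np.array([[0, 0, 0], [2, 2, 2]], float)
        var2 = variants.iloc[:3].reset_index(drop=True)
        K2 = qtlmap.compute_ibs_kinship(
            qtlmap.GenotypeMatrix(["a", "b"], var2, dos2), min_variants=1
        ).values
        assert K2[0, 1] == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        n, m = 15, 60
        dosage = rng.integers(0, 3, (n, m)).astype(float)
        variants = pd.DataFrame(
            {"id": [f"v{i}" for i in range(m)], "chrom": "chr1",
             "pos": range(1, m + 1), "ref": "A", "alt": "G"}
        )
        geno = qtlmap.GenotypeMatrix([f"d{i}" for i in range(n)], variants, dosage)
        K = qtlmap.compute_ibs_kinship(geno).values
        oracle = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                oracle[i, j] = np.mean((2 - np.abs(dosage[i] - dosage[j])) / 2)
        np.testing.assert_allclose(K, oracle, atol=1e-12)

    def test_loco_excludes_chromosome(self, small_geno):
        full = qtlmap.compute_ibs_kinship(small_geno)
        loco = qtlmap.compute_ibs_kinship(small_geno, loco_chrom="chr1")
        mask = (small_geno.variants["chrom"] != "chr1").to_numpy()
        d = np.round(small_geno.dosage[:, mask])
        manual = np.mean(
            (2 - np.abs(d[:, None, :] - d[None, :, :])) / 2, axis=2
        )
        np.testing.assert_allclose(loco.values, manual, atol=1e-12)
        assert not np.allclose(full.values, loco.values)


class TestLmm:
    def test_identity_kinship_reproduces_ols(self):
        rng = np.random.default_rng(1)
        n = 50
        y = rng.standard_normal(n)
        g = rng.integers(0, 3, n).astype(float)
        C = rng.standard_normal((n, 2))
        I = qtlmap.KinshipMatrix([f"d{i}" for i in range(n)], np.eye(n))
        res, _ = qtlmap.fit_lmm_apaqtl(y, g, C, I)
        fit = sm.OLS(y, sm.add_constant(np.column_stack([C, g]))).fit()
        assert res.beta == pytest.approx(fit.params[-1], abs=1e-8)
        assert res.se == pytest.approx(fit.bse[-1], abs=1e-8)
        assert res.p_nominal == pytest.approx(fit.pvalues[-1], abs=1e-8)

    def test_gls_matches_matrix_inverse_oracle(self):
        rng = np.random.default_rng(4)
        n = 12
        K = np.eye(n) * 0.5 + 0.5
        y = rng.standard_normal(n)
        g = rng.integers(0, 3, n).astype(float)
        Km = qtlmap.KinshipMatrix([f"d{i}" for i in range(n)], K)
        res, vc = qtlmap.fit_lmm_apaqtl(y, g, None, Km)
        V = vc.sigma_g2 * K + vc.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.column_stack([np.ones(n), g])
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert res.beta == pytest.approx(beta[1], abs=1e-8)

    def test_iid_noise_gives_boundary_genetic_variance(self):
        """Under an iid phenotype the REML genetic variance sits at or near
        its zero boundary: the estimate is the classic half-mixture of an
        exact zero and a small positive value, so roughly half the
        replicates are (numerically) zero and the typical share of variance
        assigned to kinship stays small."""
        fractions = []
        for s in range(40):
            rng = np.random.default_rng(s)
            cfg = syndata.SimConfig(n_donors=80, n_variants=1000, seed=900 + s,
                                    frac_related_pairs=0.5)
            geno = syndata.simulate_genotypes(cfg)
            K = qtlmap.compute_ibs_kinship(geno)
            y = rng.standard_normal(80)
            ctx = qtlmap.fit_lmm_null(y, None, K)
            total = ctx.vc.sigma_g2 + ctx.vc.sigma_e2
            fractions.append(ctx.vc.sigma_g2 / total)
        fractions = np.array(fractions)
        assert (fractions < 0.05).mean() >= 0.35
        assert np.median(fractions) < 0.20
        assert fractions.mean() < 0.25

    def test_true_variance_fraction_recovered(self):
        fractions = []
        for s in range(20):
            rng = np.random.default_rng(s)
            cfg = syndata.SimConfig(n_donors=80, n_variants=1000, seed=900 + s,
                                    frac_related_pairs=0.5)
            geno = syndata.simulate_genotypes(cfg)
            K = qtlmap.compute_ibs_kinship(geno)
            w, U = np.linalg.eigh(K.values)
            g = U @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(80))
            y = g + rng.standard_normal(80)  # sigma_g2 = sigma_e2 = 1
            ctx = qtlmap.fit_lmm_null(y, None, K)
            fractions.append(ctx.vc.sigma_g2 / (ctx.vc.sigma_g2 + ctx.vc.sigma_e2))
        assert abs(np.mean(fractions) - 0.5) < 0.15

    def test_non_psd_kinship_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        Km = qtlmap.KinshipMatrix(["a", "b"], bad)
        with pytest.raises(ValueError):
            qtlmap.fit_lmm_null(np.array([0.1, -0.2]), None, Km)


class TestPhenotypePcs:
    def test_rank_one_matrix(self):
        u = np.arange(10, dtype=float)
        M = np.outer(u, np.ones(30)) + np.random.default_rng(0).normal(
            0, 1e-6, (10, 30)
        )
        pcs = qtlmap.phenotype_pcs(M, 2)
        var = pcs.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_k_zero_empty(self):
        assert qtlmap.phenotype_pcs(np.random.default_rng(1).random((5, 8)), 0).shape \
            == (5, 0)

    def test_scores_orthogonal(self):
        M = np.random.default_rng(2).random((30, 50))
        pcs = qtlmap.phenotype_pcs(M, 4)
        G = pcs.T @ pcs
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()


class TestOptimizeCovariates:
    def test_tie_breaks_to_smallest(self):
        k, counts = qtlmap.optimize_covariates(lambda k: 5, [2, 0, 1])
        assert k == 0 and counts == {0: 5, 1: 5, 2: 5}

    def test_single_grid_point(self):
        k, counts = qtlmap.optimize_covariates(lambda k: 3, [0])
        assert k == 0 and counts == {0: 3}

    def test_maximum_chosen(self):
        k, _ = qtlmap.optimize_covariates(lambda k: {0: 1, 1: 7, 2: 4}[k], [0, 1, 2])
        assert k == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            qtlmap.optimize_covariates(lambda k: 0, [])


class TestEigenMT:
    def test_duplicated_variant_collapses_to_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 100).astype(float)
        G = np.tile(col[:, None], (1, 8))
        assert qtlmap.eigenmt_meff(G) == 1

    def test_single_variant(self):
        g = np.random.default_rng(1).integers(0, 3, 50).astype(float)
        assert qtlmap.eigenmt_meff(g[:, None]) == 1

    def test_matches_direct_eigen_oracle(self):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, (200, 50)).astype(float)
        R = np.corrcoef(G, rowvar=False)
        ev = np.sort(np.linalg.eigvalsh(R))[::-1]
        cum = np.cumsum(ev) / ev.sum()
        oracle = int(np.searchsorted(cum, 0.99) + 1)
        assert qtlmap.eigenmt_meff(G) == oracle

    def test_bounds_and_duplication_stability(self, small_geno):
        G = small_geno.dosage[:, :150]
        m = qtlmap.eigenmt_meff(G)
        assert 1 <= m <= 150
        m_dup = qtlmap.eigenmt_meff(np.repeat(G, 2, axis=1))
        assert abs(m_dup - m) / m < 0.10

    def test_zero_variance_columns_dropped(self):
        rng = np.random.default_rng(5)
        G = rng.integers(0, 3, (60, 5)).astype(float)
        G[:, 2] = 1.0
        assert qtlmap.eigenmt_meff(G) <= 5


class TestHierarchicalFdr:
    def test_single_phenotype_arithmetic(self):
        rec = pd.DataFrame(
            {"phenotype_id": ["p"], "p_min": [0.001], "m_eff": [10]}
        )
        out = qtlmap.hierarchical_fdr(rec)
        assert out.loc[0, "p_local"] == pytest.approx(0.01)
        assert out.loc[0, "q_global"] == pytest.approx(0.01)
        assert bool(out.loc[0, "significant"])

    def test_local_p_clamped(self):
        rec = pd.DataFrame({"phenotype_id": ["p"], "p_min": [0.2], "m_eff": [10]})
        assert qtlmap.hierarchical_fdr(rec).loc[0, "p_local"] == 1.0

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(9)
        p = rng.random(40)
        rec = pd.DataFrame(
            {"phenotype_id": [f"p{i}" for i in range(40)], "p_min": p,
             "m_eff": 1}
        )
        out = qtlmap.hierarchical_fdr(rec)
        order = np.argsort(p)
        q_manual = np.empty(40)
        prev = 1.0
        for rank, idx in list(enumerate(order, start=1))[::-1]:
            prev = min(prev, p[idx] * 40 / rank)
            q_manual[idx] = prev
        np.testing.assert_allclose(out["q_global"], q_manual)


class TestSelectPrimary:
    def _assoc(self, ps, dists, poss):
        return pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(len(ps))],
             "p_nominal": ps, "distance": dists, "pos": poss}
        )

    def test_smallest_p_wins(self):
        best = qtlmap.select_primary(self._assoc([0.01, 0.001, 0.05],
                                                 [1, 2, 3], [10, 20, 30]))
        assert best["variant_id"] == "v1"

    def test_p_tie_breaks_by_distance(self):
        best = qtlmap.select_primary(self._assoc([0.01, 0.01], [50_000, 5_000],
                                                 [10, 20]))
        assert best["variant_id"] == "v1"

    def test_full_tie_breaks_by_position(self):
        best = qtlmap.select_primary(self._assoc([0.01, 0.01], [5_000, 5_000],
                                                 [200, 100]))
        assert best["variant_id"] == "v1"


def test_genotype_mds_shape_and_structure(small_geno):
    mds = qtlmap.genotype_mds(small_geno, 3)
    assert mds.shape == (small_geno.n_donors, 3)
    assert np.isfinite(mds).all()
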