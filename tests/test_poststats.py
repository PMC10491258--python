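"""Sharing, enrichment, colocalization, mediation and distance statistics."""

import numpy as np
import pandas as pd
import pytest

from ptqtl import poststats, qtlmap, syndata


def _geno_from_columns(cols):
    cols = {k: np.asarray(v, float) for k, v in cols.items()}
    ids = list(cols)
    n = len(next(iter(cols.values())))
    variants = pd.DataFrame(
        {"id": ids, "chrom": "chr1", "pos": np.arange(1, len(ids) + 1) * 1000,
         "ref": "A", "alt": "G"}
    )
    dosage = np.column_stack([cols[i] for i in ids])
    return qtlmap.GenotypeMatrix([f"d{i}" for i in range(n)], variants, dosage)


class TestPi1:
    def test_strong_replication(self):
        disc = pd.DataFrame({"phenotype_id": [f"p{i}" for i in range(200)],
                             "variant_id": "v"})
        repl = disc.assign(p_nominal=1e-8)
        assert poststats.pi1_overlap(disc, repl) >= 0.95

    def test_uniform_grid_is_null(self):
        n = 2000
        disc = pd.DataFrame({"phenotype_id": [f"p{i}" for i in range(n)],
                             "variant_id": "v"})
        repl = disc.assign(p_nominal=(np.arange(n) + 0.5) / n)
        assert poststats.pi1_overlap(disc, repl) <= 0.05

    def test_known_mixture_recovered(self):
        rng = np.random.default_rng(11)
        n, k = 5000, 1500
        p = np.concatenate([rng.beta(0.1, 1, k), rng.uniform(0, 1, n - k)])
        disc = pd.DataFrame({"phenotype_id": [f"p{i}" for i in range(n)],
                             "variant_id": "v"})
        repl = disc.assign(p_nominal=p)
        assert poststats.pi1_overlap(disc, repl) == pytest.approx(0.30, abs=0.07)

    def test_no_matches_is_missing(self):
        disc = pd.DataFrame({"phenotype_id": ["a"], "variant_id": ["v"]})
        repl = pd.DataFrame({"phenotype_id": ["b"], "variant_id": ["v"],
                             "p_nominal": [0.5]})
        with pytest.warns(UserWarning):
            assert np.isnan(poststats.pi1_overlap(disc, repl))


def _variant_frame(prefix, cats, rng):
    n = len(cats)
    return pd.DataFrame(
        {"variant_id": [f"{prefix}{i}" for i in range(n)], "structure": cats,
         "maf": rng.uniform(0.05, 0.5, n), "distance": rng.integers(1, 800, n)}
    )


class TestStructureEnrichment:
    def test_extreme_enrichment(self):
        rng = np.random.default_rng(0)
        sig = _variant_frame("s", ["stem"] * 20, rng)
        ns = _variant_frame("n", ["exterior"] * 200, rng)
        out = poststats.structure_enrichment(sig, ns, n_perm=100, seed=1)
        row = out.set_index("structure").loc["stem"]
        assert row["p"] == 0.0
        assert row["p_strict"] == 0.0
        assert row["p_add_one"] == pytest.approx(1 / 101)

    def test_identical_composition_gives_central_p(self):
        # the tested set has exactly the pool's stem proportion, so the
        # permutation counts are centered on the observed count
        rng = np.random.default_rng(1)
        sig_cats = ["stem"] * 10 + ["exterior"] * 30
        ns_cats = ["stem"] * 100 + ["exterior"] * 300
        sig = _variant_frame("s", sig_cats, rng)
        ns = _variant_frame("n", ns_cats, rng)
        out = poststats.structure_enrichment(sig, ns, n_perm=400, seed=2)
        row = out.set_index("structure").loc["stem"]
        assert 0.25 < row["p"] < 0.9
        assert 0.1 < row["p_strict"] < 0.75

    def test_invariant_to_relabeling_untested_categories(self):
        rng = np.random.default_rng(3)
        cats = list(rng.choice(["stem", "bulge", "exterior"], 200, p=[0.3, 0.3, 0.4]))
        sig = _variant_frame("s", cats[:30], rng)
        rng2 = np.random.default_rng(3)
        ns_cats = cats[30:]
        ns = _variant_frame("n", ns_cats, rng)
        out1 = poststats.structure_enrichment(sig, ns, n_perm=200, seed=5)
        relabel = {"bulge": "multiloop", "exterior": "hairpin loop", "stem": "stem"}
        sig2 = sig.assign(structure=sig["structure"].map(relabel))
        ns2 = ns.assign(structure=ns["structure"].map(relabel))
        out2 = poststats.structure_enrichment(sig2, ns2, n_perm=200, seed=5)
        p1 = out1.set_index("structure").loc["stem", "p"]
        p2 = out2.set_index("structure").loc["stem", "p"]
        assert p1 == pytest.approx(p2)

    def test_unmatchable_variant_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        sig = _variant_frame("s", ["stem"] * 3, rng)
        sig.loc[0, "maf"] = 0.499
        ns = _variant_frame("n", ["stem"] * 50, rng)
        ns["maf"] = 0.05  # nothing matches the 0.499 MAF at 50% tolerance
        with pytest.warns(UserWarning):
            poststats.structure_enrichment(sig, ns, n_perm=10, seed=0)

    def test_empty_sets_rejected(self):
        rng = np.random.default_rng(5)
        ns = _variant_frame("n", ["stem"] * 5, rng)
        with pytest.raises(ValueError):
            poststats.structure_enrichment(ns.iloc[:0], ns, n_perm=10, seed=0)


class TestLdR2:
    def test_identical_vectors(self):
        g = _geno_from_columns({"a": [0, 1, 2, 1, 0], "b": [0, 1, 2, 1, 0]})
        assert poststats.ld_r2(g, "a", "b") == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        g = _geno_from_columns({"a": [0, 2, 0, 2], "b": [0, 0, 2, 2]})
        assert poststats.ld_r2(g, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        a, b = rng.integers(0, 3, 40), rng.integers(0, 3, 40)
        g = _geno_from_columns({"a": a, "b": b})
        assert poststats.ld_r2(g, "a", "b") == pytest.approx(
            np.corrcoef(a, b)[0, 1] ** 2, abs=1e-12
        )

    def test_monomorphic_missing(self):
        g = _geno_from_columns({"a": [1, 1, 1, 1], "b": [0, 1, 2, 1]})
        assert np.isnan(poststats.ld_r2(g, "a", "b"))


class TestGwasIndexVariants:
    def _gwas(self, ids, ps):
        return pd.DataFrame(
            {"variant_id": ids, "chrom": "chr1",
             "pos": np.arange(1, len(ids) + 1) * 1000, "p": ps}
        )

    def test_perfect_ld_keeps_smaller_p(self):
        col = np.random.default_rng(0).integers(0, 3, 30)
        g = _geno_from_columns({"a": col, "b": col})
        kept = poststats.gwas_index_variants(
            self._gwas(["a", "b"], [1e-10, 1e-9]), g
        )
        assert kept == ["a"]

    def test_unlinked_both_kept(self):
        g = _geno_from_columns({"a": [0, 2, 0, 2] * 5, "b": [0, 0, 2, 2] * 5})
        kept = poststats.gwas_index_variants(
            self._gwas(["a", "b"], [1e-10, 1e-9]), g
        )
        assert set(kept) == {"a", "b"}

    def test_chain_prune_trace(self):
        # A-B r2 ~ 0.5, B-C r2 ~ 0.5, A-C r2 ~ 0.1 with p(A)<p(B)<p(C):
        # greedy keeps A, drops B, keeps C
        rng = np.random.default_rng(141)
        n = 60
        A = rng.integers(0, 3, n).astype(float)
        B = np.where(rng.random(n) < 0.55, A, rng.integers(0, 3, n))
        C = np.where(rng.random(n) < 0.55, B, rng.integers(0, 3, n))
        g = _geno_from_columns({"A": A, "B": B, "C": C})
        assert poststats.ld_r2(g, "A", "B") > 0.2
        assert poststats.ld_r2(g, "B", "C") > 0.2
        assert poststats.ld_r2(g, "A", "C") < 0.2
        kept = poststats.gwas_index_variants(
            self._gwas(["A", "B", "C"], [1e-12, 1e-10, 1e-9]), g
        )
        assert kept == ["A", "C"]

    def test_no_significant_variants(self):
        g = _geno_from_columns({"a": [0, 1, 2, 1]})
        assert poststats.gwas_index_variants(self._gwas(["a"], [0.5]), g) == []


class TestConditionalColocalization:
    def test_same_variant_is_collinear_colocalized(self):
        col = np.random.default_rng(1).integers(0, 3, 40)
        g = _geno_from_columns({"a": col, "b": col})
        qtl = pd.DataFrame({"phenotype_id": ["ph"], "variant_id": ["b"]})
        calls = poststats.conditional_colocalization(
            lambda pid, extra: 0.0, qtl, ["a"], g
        )
        assert len(calls) == 1
        assert calls[0].verdict == "colocalized" and calls[0].collinear

    def test_no_pair_passes_r2(self):
        g = _geno_from_columns({"a": [0, 2, 0, 2] * 10, "b": [0, 0, 2, 2] * 10})
        qtl = pd.DataFrame({"phenotype_id": ["ph"], "variant_id": ["b"]})
        calls = poststats.conditional_colocalization(
            lambda pid, extra: 0.0, qtl, ["a"], g
        )
        assert calls == []

    def test_verdict_follows_conditional_p(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 60).astype(float)
        b = np.where(rng.random(60) < 0.95, a, rng.integers(0, 3, 60))
        g = _geno_from_columns({"a": a, "b": b})
        assert poststats.ld_r2(g, "a", "b") > 0.8
        qtl = pd.DataFrame({"phenotype_id": ["ph"], "variant_id": ["b"]})
        calls = poststats.conditional_colocalization(
            lambda pid, extra: 0.5, qtl, ["a"], g
        )
        assert calls[0].verdict == "colocalized"
        calls = poststats.conditional_colocalization(
            lambda pid, extra: 1e-6, qtl, ["a"], g
        )
        assert calls[0].verdict == "not_colocalized"

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 60).astype(float)
        b = np.where(rng.random(60) < 0.95, a, rng.integers(0, 3, 60))
        g1 = _geno_from_columns({"a": a, "b": b})
        g2 = _geno_from_columns({"a": 2 - a, "b": b})  # re-harmonized flip
        qtl = pd.DataFrame({"phenotype_id": ["ph"], "variant_id": ["b"]})
        for g in (g1, g2):
            calls = poststats.conditional_colocalization(
                lambda pid, extra: 0.5, qtl, ["a"], g
            )
            assert calls[0].verdict == "colocalized"


class TestMediation:
    def test_weights_normalized(self):
        rng = np.random.default_rng(0)
        res = poststats.mediation_triplet(
            rng.integers(0, 3, 50).astype(float),
            rng.standard_normal(50),
            rng.standard_normal(50),
        )
        w = res.weights
        assert sum(w.values()) == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in w.values())

    def test_forward_generative_recovery(self):
        wins = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            X = rng.integers(0, 3, 80).astype(float)
            M = 0.8 * X + rng.standard_normal(80)
            Y = 0.8 * M + rng.standard_normal(80)
            res = poststats.mediation_triplet(X, M, Y)
            wins += res.best_model == "forward"
        assert wins >= 35  # 70%

    def test_independent_generative_recovery(self):
        weights = []
        for s in range(50):
            rng = np.random.default_rng(100 + s)
            X = rng.integers(0, 3, 80).astype(float)
            M = 0.8 * X + rng.standard_normal(80)
            Y = 0.8 * X + rng.standard_normal(80)
            weights.append(poststats.mediation_triplet(X, M, Y).weights)
        mean_ind = np.mean([w["independent"] for w in weights])
        mean_fwd = np.mean([w["forward"] for w in weights])
        mean_rev = np.mean([w["reactive"] for w in weights])
        assert mean_ind > mean_fwd and mean_ind > mean_rev

    def test_zero_variance_mediator(self):
        rng = np.random.default_rng(1)
        out = poststats.mediation_triplet(
            rng.integers(0, 3, 40).astype(float), np.zeros(40),
            rng.standard_normal(40)
        )
        assert out is None

    def test_too_few_cases_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            poststats.mediation_triplet(
                rng.random(10), rng.random(10), rng.random(10)
            )


class TestDistanceProfiles:
    def _genes(self):
        return pd.DataFrame(
            {"gene_id": ["G+", "G-"], "chrom": "chr1", "strand": ["+", "-"],
             "tss": [10_000, 90_000], "tts": [50_000, 60_000],
             "intron_starts": [15_000, 65_000], "intron_ends": [20_000, 70_000],
             "intron2_start": [30_000, 75_000], "intron2_end": [35_000, 80_000]}
        )

    def _primaries(self, pos, gene):
        return pd.DataFrame(
            {"phenotype_id": ["ph"], "variant_id": ["v"], "pos": [pos],
             "gene_id": [gene]}
        )

    def test_variant_at_tss(self):
        out = poststats.distance_profiles(self._primaries(10_000, "G+"),
                                          self._genes())
        assert out.loc[0, "dist_tss"] == 0

    def test_upstream_negative_on_forward_strand(self):
        out = poststats.distance_profiles(self._primaries(9_500, "G+"),
                                          self._genes())
        assert out.loc[0, "dist_tss"] == -500

    def test_upstream_negative_on_reverse_strand(self):
        out = poststats.distance_profiles(self._primaries(90_500, "G-"),
                                          self._genes())
        assert out.loc[0, "dist_tss"] == -500

    def test_splice_distance_is_exhaustive_minimum(self):
        pos = 26_000
        out = poststats.distance_profiles(self._primaries(pos, "G+"),
                                          self._genes())
        bounds = [15_000, 20_000, 30_000, 35_000]
        assert out.loc[0, "dist_splice"] == min(abs(pos - b) for b in bounds)
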