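"""Leave-one-genus-out importance and phenotype regression."""

import numpy as np
import pandas as pd
import pytest

from micetrans import dyadic, importance, similarity
from micetrans.importance import (DyadContext, ImportanceRecord,
                                  importance_correlations, phenotype_regression,
                                  phylo_cov, rank_cov, raw_importance,
                                  scale_importance)
from micetrans.mcmc import SamplerConfig

TEST_MCMC = SamplerConfig(chains=2, warmup=150, draws=300)


class TestRawImportance:
    def test_formula_example(self):
        assert raw_importance(0.10, 0.12, 4) == pytest.approx(0.10)

    def test_no_change_is_zero(self):
        assert raw_importance(0.08, 0.08, 9) == 0.0

    def test_sqrt_normalizer_identity(self):
        # splitting a genus into 4 pseudo-ASVs halves the score
        assert raw_importance(0.1, 0.15, 4) == pytest.approx(
            raw_importance(0.1, 0.15, 1) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            raw_importance(0.0, 0.1, 1)
        with pytest.raises(ValueError):
            raw_importance(0.1, 0.1, 0)

    def test_record_validation(self):
        with pytest.raises(ValueError):
            ImportanceRecord("g", "social", ciw_incl=-0.1, ciw_excl=0.1,
                             n_asv=1, raw=0.0)


class TestScaleImportance:
    def frame(self, raws, effect="social"):
        return pd.DataFrame({"genus": [f"g{k}" for k in range(len(raws))],
                             "effect": effect, "ciw_incl": 0.1,
                             "ciw_excl": 0.1, "n_asv": 1, "raw": raws,
                             "converged": True})

    def test_minmax(self):
        out = scale_importance(self.frame([-0.2, 0.3, 0.8]))
        np.testing.assert_allclose(out["scaled"], [0.0, 0.5, 1.0])

    def test_pair(self):
        out = scale_importance(self.frame([0.1, 0.4]))
        np.testing.assert_allclose(out["scaled"], [0.0, 1.0])

    def test_rank_preserving(self, rng):
        from scipy.stats import spearmanr
        raws = rng.standard_normal(12)
        out = scale_importance(self.frame(list(raws)))
        rho, _ = spearmanr(out["raw"], out["scaled"])
        assert rho == pytest.approx(1.0)

    def test_constant_maps_to_zero(self):
        out = scale_importance(self.frame([0.3, 0.3, 0.3]))
        np.testing.assert_allclose(out["scaled"], 0.0)

    def test_single_genus_rejected(self):
        with pytest.raises(ValueError):
            scale_importance(self.frame([0.3]))

    def test_per_effect_scaling(self):
        df = pd.concat([self.frame([0.0, 1.0], "social"),
                        self.frame([5.0, 6.0], "spatial")])
        out = scale_importance(df)
        for effect in ("social", "spatial"):
            sub = out[out["effect"] == effect]
            np.testing.assert_allclose(sorted(sub["scaled"]), [0.0, 1.0])


class TestPhyloCov:
    def test_star_tree_identity(self):
        c = phylo_cov("(A:1,B:1,C:1,D:1);")
        np.testing.assert_allclose(c.to_numpy(), np.eye(4), atol=1e-12)

    def test_sister_tips_limit(self):
        c = phylo_cov("((A:0.001,B:0.001):5,C:5.001);")
        assert c.loc["A", "B"] > 0.999
        assert c.loc["A", "C"] < 0.01

    def test_five_tip_manual_oracle(self):
        # depths: A,B = 1+2+1 = 4; C = 3+1 = 4; D,E = 2+2 = 4
        # shared: (A,B) = 3, (A,C) = 1, (A,D) = 0, (D,E) = 2
        tree = "(((A:1,B:1):2,C:3):1,(D:2,E:2):2);"
        c = phylo_cov(tree, ["A", "B", "C", "D", "E"])
        assert c.loc["A", "B"] == pytest.approx(3 / 4)
        assert c.loc["A", "C"] == pytest.approx(1 / 4)
        assert c.loc["A", "D"] == pytest.approx(0.0)
        assert c.loc["D", "E"] == pytest.approx(2 / 4)
        np.testing.assert_allclose(np.diag(c), 1.0)

    def test_positive_semidefinite(self):
        c = phylo_cov("(((A:1,B:1):2,C:3):1,(D:2,E:2):2);")
        vals = np.linalg.eigvalsh(c.to_numpy())
        assert vals.min() > -1e-10

    def test_missing_tips_listed(self):
        with pytest.raises(ValueError, match="gX"):
            phylo_cov("(A:1,B:1);", ["A", "gX"])

    def test_rank_fallback(self):
        ranks = pd.DataFrame({"family": ["f1", "f1", "f2"],
                              "phylum": ["p1", "p1", "p1"]},
                             index=["gA", "gB", "gC"])
        c = rank_cov(ranks)
        assert c.loc["gA", "gB"] == 0.5
        assert c.loc["gA", "gC"] == 0.25
        assert c.loc["gA", "gA"] == 1.0


def pheno_frame(n, rng, balanced=True):
    if balanced:
        aero = np.tile([0, 0, 1, 1], n // 4 + 1)[:n]
        spore = np.tile([0, 1, 0, 1], n // 4 + 1)[:n]
    else:
        aero = rng.integers(0, 2, n)
        spore = rng.integers(0, 2, n)
    return pd.DataFrame({"aerotolerant": aero, "spore_forming": spore,
                         "known": True}, index=[f"g{k:02d}" for k in range(n)])


class TestPhenotypeRegression:
    def test_null_simulation_covers_zero(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pheno = pheno_frame(16, rng)
            scores = pd.Series(rng.random(16), index=pheno.index)
            out = phenotype_regression(scores, pheno, mcmc=TEST_MCMC, seed=seed)
            lo, hi = out.fit.ci("aerotolerant")
            if lo < 0 < hi:
                hits += 1
        assert hits >= 9

    def test_aerotolerant_spore_signal_recovered(self):
        hits = 0
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            pheno = pheno_frame(20, rng)
            base = 0.1 * rng.random(20)
            lift = 0.7 * ((pheno["aerotolerant"] == 1)
                          & (pheno["spore_forming"] == 1)).to_numpy()
            scores = pd.Series(base + lift, index=pheno.index)
            out = phenotype_regression(scores, pheno, factorization="four_level",
                                       mcmc=TEST_MCMC, seed=seed)
            lo, _ = out.contrasts.loc["AE-SF", ["ci_low", "ci_high"]]
            if lo > 0:
                hits += 1
        assert hits >= 3

    def test_identity_cov_equals_default(self):
        rng = np.random.default_rng(5)
        pheno = pheno_frame(12, rng)
        scores = pd.Series(rng.random(12), index=pheno.index)
        eye = pd.DataFrame(np.eye(12), index=pheno.index, columns=pheno.index)
        f1 = phenotype_regression(scores, pheno, cov=None, mcmc=TEST_MCMC, seed=2)
        f2 = phenotype_regression(scores, pheno, cov=eye, mcmc=TEST_MCMC, seed=2)
        pd.testing.assert_frame_equal(f1.fit.summary, f2.fit.summary)

    def test_thin_cell_rejected(self):
        pheno = pd.DataFrame({"aerotolerant": [0, 0, 0, 1],
                              "spore_forming": [0, 0, 1, 1], "known": True},
                             index=["g0", "g1", "g2", "g3"])
        scores = pd.Series([0.1, 0.2, 0.3, 0.4], index=pheno.index)
        with pytest.raises(ValueError, match="AE-SF"):
            phenotype_regression(scores, pheno, factorization="four_level",
                                 mcmc=TEST_MCMC)

    def test_singular_cov_jittered(self, rng):
        pheno = pheno_frame(8, rng)
        c = np.ones((8, 8))  # rank-1, singular
        cov = pd.DataFrame(c, index=pheno.index, columns=pheno.index)
        scores = pd.Series(rng.random(8), index=pheno.index)
        out = phenotype_regression(scores, pheno, cov=cov, mcmc=TEST_MCMC, seed=0)
        assert np.isfinite(out.fit.summary["mean"]).all()


class TestImportanceCorrelations:
    def test_identical_vectors(self, rng):
        v = rng.random(10)
        scores = pd.DataFrame({"social": v, "spatial": v})
        out = importance_correlations(scores, n_perm=99, seed=0)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_vectors_small_r(self):
        rs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            scores = pd.DataFrame({"social": rng.random(60),
                                   "spatial": rng.random(60)})
            out = importance_correlations(scores, n_perm=49, seed=seed)
            rs.append(abs(out["r"].iloc[0]))
        assert np.median(rs) < 0.2

    def test_matches_direct_formula(self):
        scores = pd.DataFrame({"social": [0.1, 0.5, 0.3, 0.9],
                               "spatial": [0.2, 0.4, 0.1, 0.8],
                               "habitat": [0.9, 0.1, 0.5, 0.2]})
        out = importance_correlations(scores, n_perm=9, seed=0)
        for _, row in out.iterrows():
            expect = np.corrcoef(scores[row["effect_a"]], scores[row["effect_b"]])[0, 1]
            assert row["r"] == pytest.approx(expect)


@pytest.fixture(scope="module")
def loo_context():
    from micetrans import synthetic
    cfg = synthetic.WorldConfig(n_mice=10, n_asv=60, n_genera=6, n_nights=30,
                                samples_per_mouse=2, seed=17,
                                route_effects={"social": 5.0, "spatial": 5.0,
                                               "habitat": 0.0})
    world = synthetic.simulate_world(cfg)
    counts, meta = synthetic.simulate_microbiota(
        world, world.true_association, world.true_overlap)
    spec = dyadic.ModelSpec(mcmc=TEST_MCMC, seed=7)
    ctx = DyadContext(counts=counts, genus_map=world.asv_table["genus"],
                      metadata=meta, sri=world.true_association,
                      overlap=world.true_overlap,
                      habitat=(world.mouse_ids,
                               np.full((10, 10), 0.4) + 0.6 * np.eye(10)),
                      spec=spec)
    return world, ctx


class TestLooImportance:
    def test_unknown_genus_rejected(self, loo_context):
        world, ctx = loo_context
        baseline = ctx.fit_counts(ctx.counts)
        with pytest.raises(ValueError, match="nope"):
            importance.loo_importance(ctx, baseline, "nope")

    def test_entire_community_rejected(self, loo_context):
        world, ctx = loo_context
        one_genus = ctx.counts.copy()
        gmap = pd.Series("gALL", index=one_genus.columns)
        ctx_one = DyadContext(counts=one_genus, genus_map=gmap,
                              metadata=ctx.metadata, sri=ctx.sri,
                              overlap=ctx.overlap, habitat=ctx.habitat,
                              spec=ctx.spec)
        baseline = ctx_one.fit_counts(one_genus)
        with pytest.raises(ValueError, match="entire community"):
            importance.loo_importance(ctx_one, baseline, "gALL")

    def test_absent_genus_importance_exactly_zero(self, loo_context):
        # a genus with all-zero counts leaves the response unchanged, and
        # refits are seed-deterministic, so raw importance is exactly 0
        world, ctx = loo_context
        counts = ctx.counts.copy()
        counts["ghost1"] = 0
        counts["ghost2"] = 0
        gmap = pd.concat([ctx.genus_map,
                          pd.Series({"ghost1": "gGhost", "ghost2": "gGhost"})])
        ctx2 = DyadContext(counts=counts, genus_map=gmap, metadata=ctx.metadata,
                           sri=ctx.sri, overlap=ctx.overlap,
                           habitat=ctx.habitat, spec=ctx.spec)
        baseline = ctx2.fit_counts(counts)
        records = importance.loo_importance(ctx2, baseline, "gGhost")
        for rec in records:
            assert rec.raw == pytest.approx(0.0, abs=1e-12)
            assert rec.n_asv == 2

    def test_records_cover_three_effects(self, loo_context):
        world, ctx = loo_context
        genus = world.asv_table["genus"].iloc[0]
        baseline = ctx.fit_counts(ctx.counts)
        records = importance.loo_importance(ctx, baseline, genus)
        assert {r.effect for r in records} == {"social", "spatial", "habitat"}
        for rec in records:
            assert rec.raw == pytest.approx(
                raw_importance(rec.ciw_incl, rec.ciw_excl, rec.n_asv))
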