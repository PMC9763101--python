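import numpy as np
import pandas as pd
import pytest

from crdscan.causal import (
    bn_posteriors,
    bootstrap_accuracy,
    build_triplets,
    compare_mechanisms,
    cross_qtl_effect,
    map_gene_crd_pairs,
    pc1_pseudophenotype,
)
from crdscan.synthetic import simulate_triplet
from tests.conftest import make_genotypes, make_phenotypes

MODELS = ("causal", "reactive", "independent")


class TestPC1:
    def test_identical_series_full_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        _, var_expl, r = pc1_pseudophenotype(x, x.copy())
        assert var_expl == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_variance_explained_matches_eigenvalues(self):
        """For a standardized pair, PC1 variance = (1+|r|)/2, the larger
        eigenvalue of the 2x2 correlation matrix over the total."""
        rng = np.random.default_rng(1)
        n = 4000
        g = rng.normal(size=n)
        c = 0.5 * g + np.sqrt(1 - 0.25) * rng.normal(size=n)
        scores, var_expl, r = pc1_pseudophenotype(g, c)
        evals = np.linalg.eigvalsh(np.array([[1.0, r], [r, 1.0]]))
        assert var_expl == pytest.approx(evals.max() / evals.sum(), abs=1e-12)
        assert var_expl == pytest.approx((1 + abs(r)) / 2, abs=1e-12)
        assert np.corrcoef(scores, g)[0, 1] > 0  # sign aligned with the gene

    def test_anticorrelated_pair_sign_alignment(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=500)
        c = -0.8 * g + 0.6 * rng.normal(size=500)
        scores, _, r = pc1_pseudophenotype(g, c)
        assert r < 0
        assert np.corrcoef(scores, g)[0, 1] > 0


class TestBNPosteriors:
    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(3)
        v = rng.binomial(2, 0.3, 100).astype(float)
        post = bn_posteriors(v, rng.normal(size=100), rng.normal(size=100))
        assert sum(post) == pytest.approx(1.0, abs=1e-9)

    def test_affine_rescaling_invariance(self):
        v, c, g = simulate_triplet("causal", 200, 0.5, 0.7, seed=4)
        p1 = bn_posteriors(v, c, g)
        p2 = bn_posteriors(v, 3.0 * c - 7.0, -2.0 * g + 1.0)
        assert np.allclose(p1, p2, atol=1e-9)

    @pytest.mark.parametrize("model", MODELS)
    def test_generative_model_recovered(self, model):
        betas = (0.5, 0.9) if model == "reactive" else (0.5, 0.7)
        hits = 0
        for seed in range(100):
            v, c, g = simulate_triplet(model, 150, *betas, seed=seed)
            hits += MODELS[int(np.argmax(bn_posteriors(v, c, g)))] == model
        floor = 70 if model == "reactive" else 90
        assert hits >= floor

    def test_constant_inputs_rejected(self):
        rng = np.random.default_rng(5)
        v = rng.binomial(2, 0.3, 100).astype(float)
        with pytest.raises(ValueError, match="constant"):
            bn_posteriors(v, np.ones(100), rng.normal(size=100))
        with pytest.raises(ValueError, match="constant dosage"):
            bn_posteriors(np.ones(100), rng.normal(size=100),
                          rng.normal(size=100))

    def test_minimum_n_enforced(self):
        rng = np.random.default_rng(6)
        v = rng.binomial(2, 0.5, 20).astype(float)
        with pytest.raises(ValueError, match=">= 30"):
            bn_posteriors(v, rng.normal(size=20), rng.normal(size=20))


class TestBootstrap:
    def test_single_resample_binary_accuracy(self):
        v, c, g = simulate_triplet("causal", 100, 1.0, 1.0, seed=7)
        acc, _ = bootstrap_accuracy(v, c, g, B=1, seed=0)
        assert acc in (0.0, 1.0)

    def test_strong_signal_high_accuracy(self):
        v, c, g = simulate_triplet("causal", 300, 2.0, 2.0, seed=8)
        acc, passed = bootstrap_accuracy(v, c, g, B=100, seed=1)
        assert acc >= 0.95
        assert passed

    def test_seed_reproducible(self):
        v, c, g = simulate_triplet("independent", 120, 0.4, 0.4, seed=9)
        a1 = bootstrap_accuracy(v, c, g, B=50, seed=3)
        a2 = bootstrap_accuracy(v, c, g, B=50, seed=3)
        assert a1 == a2


class TestGeneCrdPairs:
    def _wired(self, seed=0, n=200, n_genes=15, coupled=True):
        rng = np.random.default_rng(seed)
        n_crds = 10
        factors = rng.normal(size=(n, n_crds))
        genes = rng.normal(size=(n, n_genes))
        wiring = {}
        if coupled:
            for j in range(min(n_genes, n_crds)):
                genes[:, j] = 0.577 * factors[:, j] + rng.normal(size=n)
                wiring[f"p{j:04d}"] = f"crd{j}"
        crd_feats = pd.DataFrame(
            {
                "feature_id": [f"crd{k}" for k in range(n_crds)],
                "chrom": "chr1",
                "start": np.arange(n_crds) * 200_000 + 10_000,
                "end": np.arange(n_crds) * 200_000 + 60_000,
                "strand": "+",
                "group_id": [f"crd{k}" for k in range(n_crds)],
            }
        )
        from crdscan.io_formats import PhenotypeMatrix

        act = PhenotypeMatrix([f"S{i:03d}" for i in range(n)], crd_feats,
                              factors, "quantified")
        expr = make_phenotypes(
            genes, starts=np.arange(n_genes) * 200_000 + 30_000, width=10_000
        )
        return expr, act, wiring

    def test_planted_pairs_recovered(self):
        expr, act, wiring = self._wired()
        pairs = map_gene_crd_pairs(expr, act, window=150_000, n_perm=300,
                                   seed=0)
        sig = pairs[pairs["q"] <= 0.05]
        recovered = {(r.gene_id, r.crd_id) for r in sig.itertuples()}
        assert sum((g, c) in recovered for g, c in wiring.items()) >= 9

    def test_null_genes_rarely_significant(self):
        hit_rates = []
        for seed in range(3):
            expr, act, _ = self._wired(seed=10 + seed, n_genes=40,
                                       coupled=False)
            pairs = map_gene_crd_pairs(expr, act, window=150_000, n_perm=200,
                                       seed=seed)
            hit_rates.append(
                (pairs["q"] <= 0.05).mean() if len(pairs) else 0.0
            )
        assert np.mean(hit_rates) <= 0.075

    def test_tss_inside_crd_distance_zero(self):
        expr, act, _ = self._wired()
        pairs = map_gene_crd_pairs(expr, act, window=150_000, n_perm=100,
                                   seed=1)
        inside = pairs[pairs["distance"] == 0]
        assert len(inside)
        assert ((inside["tss_relative_position"] >= 0)
                & (inside["tss_relative_position"] <= 1)).all()


class TestTriplets:
    def _cohort(self, model="causal", n=250, seed=0):
        rng = np.random.default_rng(seed)
        n_trip = 8
        doses, crds, genes = [], [], []
        for t in range(n_trip):
            v, c, g = simulate_triplet(model, n, 0.6, 0.7,
                                       seed=1000 * seed + t)
            doses.append(v)
            crds.append(c)
            genes.append(g)
        G = np.column_stack(doses)
        # one decoy null variant per triplet
        Gn = rng.binomial(2, 0.3, size=(n, n_trip)).astype(float)
        allG = np.empty((n, 2 * n_trip))
        allG[:, ::2] = G
        allG[:, 1::2] = Gn
        pos = np.repeat(np.arange(n_trip) * 300_000 + 50_000, 2)
        pos[1::2] += 10_000
        geno = make_genotypes(allG, positions=pos)
        from crdscan.io_formats import PhenotypeMatrix

        crd_feats = pd.DataFrame(
            {
                "feature_id": [f"crd{t}" for t in range(n_trip)],
                "chrom": "chr1",
                "start": np.arange(n_trip) * 300_000 + 40_000,
                "end": np.arange(n_trip) * 300_000 + 90_000,
                "strand": "+",
                "group_id": [f"crd{t}" for t in range(n_trip)],
            }
        )
        act = PhenotypeMatrix([f"S{i:03d}" for i in range(n)], crd_feats,
                              np.column_stack(crds), "quantified")
        expr = make_phenotypes(
            np.column_stack(genes),
            starts=np.arange(n_trip) * 300_000 + 60_000, width=5_000,
        )
        return expr, act, geno

    def test_planted_triplets_built_and_classified(self):
        expr, act, geno = self._cohort("causal", seed=1)
        pairs = map_gene_crd_pairs(expr, act, window=200_000, n_perm=300,
                                   seed=2)
        sig = pairs[pairs["q"] <= 0.05].reset_index(drop=True)
        assert len(sig) >= 6
        trips = build_triplets(sig, expr, act, geno, window=200_000,
                               n_perm=300, seed=3)
        assert len(trips) >= 6
        # the planted (even-indexed) variant should be the mapped eCRD-QTL
        planted = set(geno.variants["variant_id"][::2])
        assert (trips["variant_id"].isin(planted)).mean() >= 0.8

    def test_uncorrelated_pair_skipped(self):
        """A pair whose gene and CRD series are exactly orthogonal has an
        ill-defined PC1 for aggregation and is dropped."""
        expr, act, geno = self._cohort("causal", seed=4)
        gcol = expr.feature_index(["p0000"])[0]
        ccol = act.feature_index(["crd7"])[0]
        c = act.values[:, ccol]
        g = expr.values[:, gcol]
        cz = c - c.mean()
        expr.values[:, gcol] = g - (g @ cz) / (cz @ cz) * cz  # r(g, c) = 0
        fake = pd.DataFrame({"gene_id": ["p0000"], "crd_id": ["crd7"]})
        trips = build_triplets(fake, expr, act, geno, window=200_000,
                               n_perm=100, seed=5)
        assert len(trips) == 0


class TestCrossQtlEffect:
    def _setup(self, beta_cg, seed=0):
        rng = np.random.default_rng(seed)
        n, n_pairs = 300, 30
        G = rng.binomial(2, 0.3, size=(n, n_pairs)).astype(float)
        C = 0.8 * (G - G.mean(axis=0)) + rng.normal(size=(n, n_pairs))
        Gexpr = beta_cg * C + rng.normal(size=(n, n_pairs))
        geno = make_genotypes(G, positions=np.arange(n_pairs) * 1000 + 1)
        from crdscan.io_formats import PhenotypeMatrix

        feats = pd.DataFrame(
            {
                "feature_id": [f"crd{j}" for j in range(n_pairs)],
                "chrom": "chr1",
                "start": np.arange(n_pairs) * 1000,
                "end": np.arange(n_pairs) * 1000 + 500,
                "strand": "+",
                "group_id": [f"crd{j}" for j in range(n_pairs)],
            }
        )
        act = PhenotypeMatrix([f"S{i:03d}" for i in range(n)], feats, C,
                              "quantified")
        expr = make_phenotypes(Gexpr, starts=np.arange(n_pairs) * 1000)
        qtls = pd.DataFrame(
            {"phenotype_id": feats["feature_id"],
             "variant_id": geno.variants["variant_id"]}
        )
        pairs = pd.DataFrame(
            {"crd_id": feats["feature_id"],
             "gene_id": expr.features["feature_id"]}
        )
        return qtls, expr, pairs, geno

    def test_strong_chain_shares(self):
        qtls, expr, pairs, geno = self._setup(beta_cg=0.8)
        _, frac, pi1 = cross_qtl_effect(qtls, expr, pairs, geno, "crd")
        assert frac >= 0.8

    def test_severed_chain_null_rate(self):
        fracs = []
        for seed in range(5):
            qtls, expr, pairs, geno = self._setup(beta_cg=0.0, seed=seed)
            _, frac, _ = cross_qtl_effect(qtls, expr, pairs, geno, "crd")
            fracs.append(frac)
        assert np.mean(fracs) < 0.15

    def test_empty_link_returns_empty(self):
        qtls, expr, pairs, geno = self._setup(beta_cg=0.5)
        qtls["phenotype_id"] = "nonexistent"
        df, frac, pi1 = cross_qtl_effect(qtls, expr, pairs, geno, "crd")
        assert len(df) == 0 and np.isnan(frac)


class TestCompareMechanisms:
    def _frame(self, models, passed=True):
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(len(models))],
                "crd_id": [f"c{i}" for i in range(len(models))],
                "gene_id": [f"g{i}" for i in range(len(models))],
                "top_model": models,
                "passed": passed,
            }
        )

    def test_identical_inputs_all_same(self):
        a = self._frame(["causal", "reactive", "independent"])
        out = compare_mechanisms(a, a.copy())
        assert (out["change"] == "same").all()

    def test_direction_labels(self):
        cases = self._frame(["causal", "reactive"])
        controls = self._frame(["reactive", "causal"])
        out = compare_mechanisms(cases, controls).set_index("variant_id")
        assert out.loc["v0", "change"] == "different_to_causal"
        assert out.loc["v1", "change"] == "causal_to_different"

    def test_reactive_vs_independent_counts_as_same(self):
        cases = self._frame(["reactive"])
        controls = self._frame(["independent"])
        out = compare_mechanisms(cases, controls)
        assert list(out["change"]) == ["same"]

    def test_failed_triplets_excluded(self):
        cases = self._frame(["causal"], passed=False)
        controls = self._frame(["causal"])
        assert len(compare_mechanisms(cases, controls)) == 0

    def test_empty_intersection(self):
        cases = self._frame(["causal"])
        controls = self._frame(["causal"])
        controls["variant_id"] = ["other"]
        assert len(compare_mechanisms(cases, controls)) == 0

    def test_paired_simulation_recovers_change(self):
        """Cases generated causal, controls reactive: matched triplets are
        labelled different_to_causal."""
        rows_case, rows_ctrl = [], []
        from crdscan.causal import MODELS as M

        for t in range(20):
            vc, cc, gc = simulate_triplet("causal", 200, 0.8, 0.8, seed=t)
            vr, cr, gr = simulate_triplet("reactive", 200, 0.8, 0.8,
                                          seed=100 + t)
            rows_case.append(M[int(np.argmax(bn_posteriors(vc, cc, gc)))])
            rows_ctrl.append(M[int(np.argmax(bn_posteriors(vr, cr, gr)))])
        out = compare_mechanisms(self._frame(rows_case),
                                 self._frame(rows_ctrl))
        assert (out["change"] == "different_to_causal").mean() >= 0.8
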