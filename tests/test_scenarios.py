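"""Synthetic scenario generators: design counts, gene dropping, genotype PCA."""

import numpy as np
import pandas as pd
import pytest

from pedpca import (
    ImplicitOperator,
    PedigreeError,
    ScenarioConfig,
    build_precision_cholesky,
    dense_A_oracle,
    gene_drop,
    genotype_pca_reference,
    random_pedigree,
    realised_relationship,
    run_2pop,
    run_4pop,
    simulate_founders,
)
from pedpca.scenarios import default_map

SMALL_2POP = {"size_per_pop": 12, "n_select": 4, "nloci": 400, "nchrom": 4,
              "n_generations": 6, "hybrid_at": 3, "divergence_generations": 20}
SMALL_4POP = {"ancestral_size": 24, "ancestral_generations": 3, "npop": 4,
              "size_per_pop": 6, "split_generations": 4, "nloci": 400, "nchrom": 4}


class TestFounders:
    def test_no_divergence_means_identical_frequencies(self):
        _, freq, _, _ = simulate_founders(2, 10, nloci=200, nchrom=4,
                                          divergence_generations=0, seed=1)
        np.testing.assert_array_equal(freq[0], freq[1])

    def test_fst_grows_with_divergence_time(self):
        def mean_fst(t):
            _, freq, base, _ = simulate_founders(
                2, 10, nloci=2000, nchrom=4, divergence_generations=t, seed=3
            )
            num = np.var(freq, axis=0, ddof=1)
            den = base * (1 - base)
            return float(np.mean(num / den))

        f10, f100 = mean_fst(10), mean_fst(100)
        assert 0 < f10 < f100
        # Wright-Fisher expectation 1 - (1 - 1/2N)^t with N = 100
        assert f100 == pytest.approx(1 - (1 - 1 / 200) ** 100, rel=0.25)

    def test_locus_layout(self):
        _, _, _, lmap = simulate_founders(2, 5, nloci=11_000, nchrom=10,
                                          divergence_generations=1, seed=0)
        counts = lmap.groupby("chrom").size()
        assert (counts == 1100).all() and len(counts) == 10

    def test_all_loci_segregate(self):
        _, freq, _, _ = simulate_founders(2, 10, nloci=500, nchrom=5,
                                          divergence_generations=100, seed=5)
        fixed = np.all((freq == 0) | (freq == 1), axis=0)
        assert not fixed.any()


class TestGeneDrop:
    def test_monomorphic_founders_stay_monomorphic(self):
        ped = random_pedigree(30, seed=2, p_missing=0.0, n_founders=6)
        lmap = default_map(40, 2)
        zeros = np.zeros((6, 2, 40), dtype=np.uint8)
        dos = gene_drop(ped, zeros, lmap, seed=0)
        assert np.all(dos == 0)
        twos = np.ones((6, 2, 40), dtype=np.uint8)
        assert np.all(gene_drop(ped, twos, lmap, seed=0) == 2)

    def test_dosages_are_valid(self):
        ped = random_pedigree(50, seed=3, p_missing=0.0, n_founders=10)
        lmap = default_map(60, 3)
        rng = np.random.default_rng(0)
        fh = (rng.random((10, 2, 60)) < 0.5).astype(np.uint8)
        dos = gene_drop(ped, fh, lmap, seed=1)
        assert set(np.unique(dos)) <= {0, 1, 2}

    def test_zero_recombination_copies_whole_haplotypes(self):
        # one chromosome of map length zero: each gamete is an exact parental copy
        ped = random_pedigree(20, seed=4, p_missing=0.0, n_founders=4)
        nloci = 30
        lmap = pd.DataFrame({"chrom": np.ones(nloci, int), "pos": np.zeros(nloci)})
        rng = np.random.default_rng(1)
        fh = (rng.random((4, 2, nloci)) < 0.5).astype(np.uint8)
        dos, H = gene_drop(ped, fh, lmap, seed=2, return_haplotypes=True)
        for i in range(4, 20):
            s, d = ped.sire[i] - 1, ped.dam[i] - 1
            assert any(np.array_equal(H[i, 0], H[s, h]) for h in (0, 1))
            assert any(np.array_equal(H[i, 1], H[d, h]) for h in (0, 1))

    def test_founder_count_mismatch(self):
        ped = random_pedigree(10, seed=5, p_missing=0.0, n_founders=2)
        with pytest.raises(PedigreeError, match="founder"):
            gene_drop(ped, np.zeros((5, 2, 10), np.uint8), default_map(10, 1))

    def test_mean_realised_relationship_approaches_centred_A(self):
        ped = random_pedigree(40, seed=6, p_missing=0.0, n_founders=10)
        A = dense_A_oracle(ped)
        P = np.eye(40) - 1.0 / 40
        At = P @ A @ P
        nloci = 600
        lmap = default_map(nloci, 3)
        p = np.random.default_rng(7).uniform(0.1, 0.9, nloci)
        acc = np.zeros((40, 40))
        reps = 150
        for r in range(reps):
            rr = np.random.default_rng([11, r])
            fh = (rr.random((10, 2, nloci)) < p).astype(np.uint8)
            dos = gene_drop(ped, fh, lmap, seed=int(rr.integers(2**31)))
            acc += realised_relationship(dos, p)
        assert np.abs(acc / reps - At).max() < 0.06


class Test2pop:
    def test_default_design_counts(self):
        out = run_2pop(ScenarioConfig("2pop", seed=0))
        ped = out.ped
        assert ped.n == 2650
        pop = np.asarray(ped.metadata["population"])
        assert int(np.sum(pop == "hybrid")) == 11 * 50
        assert int(np.sum(ped.generation == 1)) == 100
        assert out.dosages.shape == (2650, 11_000)

    def test_hybrids_appear_at_the_tenth_breeding_cycle(self):
        out = run_2pop(ScenarioConfig("2pop", seed=1))
        pop = np.asarray(out.ped.metadata["population"])
        hyb_gen = out.ped.generation[pop == "hybrid"]
        # founders are generation 1, so the cohort bred in cycle 10 is
        # recorded as generation 11
        assert hyb_gen.min() == 11
        assert hyb_gen.max() == 21
        first = np.asarray(out.ped.metadata["population"])[
            np.nonzero(pop == "hybrid")[0].min()
        ]
        assert first == "hybrid"

    def test_first_hybrid_cohort_is_a_true_cross(self):
        out = run_2pop(ScenarioConfig("2pop", seed=2, overrides=SMALL_2POP))
        ped = out.ped
        pop = np.asarray(ped.metadata["population"])
        hyb_rows = np.nonzero(pop == "hybrid")[0]
        first_gen = ped.generation[hyb_rows].min()
        for i in hyb_rows[ped.generation[hyb_rows] == first_gen]:
            assert pop[ped.sire[i] - 1] == "1"
            assert pop[ped.dam[i] - 1] == "2"

    def test_design_counts_independent_of_seed(self):
        a = run_2pop(ScenarioConfig("2pop", seed=3, overrides=SMALL_2POP))
        b = run_2pop(ScenarioConfig("2pop", seed=4, overrides=SMALL_2POP))
        assert a.ped.n == b.ped.n
        assert list(a.ped.metadata["population"]) == list(b.ped.metadata["population"])
        assert a.ped.generation.tolist() == b.ped.generation.tolist()

    def test_founder_trait_architecture(self):
        out = run_2pop(ScenarioConfig("2pop", seed=5))
        founders = out.ped.generation == 1
        tgv = out.trait_values[founders]
        np.testing.assert_allclose(tgv.var(axis=0, ddof=1), 1.0, rtol=1e-9)
        corr = np.corrcoef(tgv.T)[0, 1]
        assert corr == pytest.approx(-0.3, abs=0.15)

    def test_infeasible_selection_raises(self):
        bad = dict(SMALL_2POP, n_select=20)  # top-20 from 12 candidates
        with pytest.raises(PedigreeError, match="infeasible"):
            run_2pop(ScenarioConfig("2pop", seed=0, overrides=bad))

    def test_genotype_pca_pc1_separates_the_populations(self):
        out = run_2pop(ScenarioConfig("2pop", seed=6))
        res = genotype_pca_reference(out.dosages, k=2)
        pop = np.asarray(out.ped.metadata["population"])
        m1 = res.scores[pop == "1", 0].mean()
        m2 = res.scores[pop == "2", 0].mean()
        assert m1 * m2 < 0


class Test4pop:
    def test_default_design_counts(self):
        out = run_4pop(ScenarioConfig("4pop", seed=0))
        ped = out.ped
        assert ped.n == 4000
        pop = np.asarray(ped.metadata["population"])
        assert int(np.sum(pop == "ancestral")) == 200 * 11
        for p in "1234":
            assert int(np.sum(pop == p)) == 50 * 9

    def test_no_gene_flow_after_the_split(self):
        out = run_4pop(ScenarioConfig("4pop", seed=1, overrides=SMALL_4POP))
        ped = out.ped
        pop = np.asarray(ped.metadata["population"])
        for i in range(ped.n):
            if pop[i] in "1234":
                for par in (ped.sire[i], ped.dam[i]):
                    assert pop[par - 1] in {pop[i], "ancestral"}

    def test_scaled_down_override_keeps_structure(self):
        out = run_4pop(ScenarioConfig("4pop", seed=2, overrides=SMALL_4POP))
        expect = 24 * (3 + 1) + 4 * 6 * 4
        assert out.ped.n == expect

    def test_infeasible_split_raises(self):
        bad = dict(SMALL_4POP, size_per_pop=10)  # 4 x 10 > 24
        with pytest.raises(PedigreeError, match="split"):
            run_4pop(ScenarioConfig("4pop", seed=0, overrides=bad))


class TestGenotypePCA:
    def test_identical_individuals_coincide(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(10, 50))
        X[3] = X[7]
        res = genotype_pca_reference(X, k=5)
        np.testing.assert_allclose(res.scores[3], res.scores[7], atol=1e-8)

    def test_rank_bounds_nonzero_components(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=(3, 40))
        X = base[rng.integers(0, 3, size=12)]  # rank <= 3 before centring
        res = genotype_pca_reference(X, k=12)
        assert np.sum(res.sdev > 1e-6 * res.sdev[0]) <= 3

    def test_monomorphic_columns_allowed(self):
        X = np.ones((6, 10))
        X[:, 0] = [0, 1, 2, 0, 1, 2]
        res = genotype_pca_reference(X, k=2)
        assert np.isfinite(res.scores).all()

    def test_writes_scenario_files(self, tmp_path):
        out = run_2pop(ScenarioConfig("2pop", seed=0, overrides=SMALL_2POP))
        out.write(tmp_path / "sim")
        for suffix in (".ped.csv", ".dosages.tsv", ".map.tsv"):
            assert (tmp_path / f"sim{suffix}").exists()


class TestFoundersIdenticalScores:
    def test_leading_scores_of_founders_coincide(self):
        # pedigree founders share no pedigree information, so the leading
        # components place them in a tight cluster relative to the rest
        out = run_2pop(ScenarioConfig("2pop", seed=7))
        from pedpca import RsvdConfig, rsvd_pca

        op = ImplicitOperator(build_precision_cholesky(out.ped))
        res = rsvd_pca(op, RsvdConfig(k=2, l=4, seed=0))
        founders = out.ped.generation == 1
        for j in range(2):
            assert res.scores[founders, j].std() < 0.25 * res.scores[:, j].std()
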