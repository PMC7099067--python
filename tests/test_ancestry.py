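import numpy as np
import pytest

from clinekit import (
    MISSING,
    ClineModel,
    GenotypeMatrix,
    SimConfig,
    align_replicates,
    classify_population,
    em_admixture,
    evanno_delta_k,
    hybrid_index_ml,
    simulate_dataset,
    weir_cockerham_fst,
)
from clinekit.ancestry import brute_force_alignment, pooled_frequencies


# ---------------------------------------------------------------------------
# EM admixture


class TestEmAdmixture:
    def test_k1_gives_unit_q_and_pooled_frequencies(self, two_pure_demes):
        gm = two_pure_demes.genotypes
        res = em_admixture(gm, K=1, n_restarts=2, seed=0)
        np.testing.assert_allclose(res.Q, 1.0, atol=1e-12)
        pooled = pooled_frequencies(gm)
        np.testing.assert_allclose(res.F[0], pooled, atol=1e-9)

    def test_loglik_trace_monotone(self, two_pure_demes):
        res = em_admixture(two_pure_demes.genotypes, K=2, n_restarts=3, seed=1)
        assert (np.diff(res.loglik_trace) >= -1e-8).all()

    def test_q_rows_and_f_rows_on_simplex(self, two_pure_demes):
        res = em_admixture(two_pure_demes.genotypes, K=2, n_restarts=2, seed=2)
        np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-9)
        for k in range(2):
            for l, na in enumerate(res.allele_counts):
                np.testing.assert_allclose(res.F[k, l, :na].sum(), 1.0, atol=1e-9)

    def test_recovers_pure_demes_on_diagnostic_loci(self, diagnostic_genotypes):
        res = em_admixture(diagnostic_genotypes, K=2, n_restarts=5, seed=3)
        truth = np.zeros((20, 2))
        truth[:10, 0] = 1.0
        truth[10:, 1] = 1.0
        err = min(
            np.abs(res.Q - truth).max(),
            np.abs(res.Q[:, ::-1] - truth).max(),
        )
        assert err < 0.01

    def test_fifty_fifty_hybrids_get_half_ancestry(self):
        # pure blocks plus F1-like heterozygotes at fully diagnostic loci
        n_loci, n_pure, n_hyb = 12, 15, 10
        calls = np.concatenate(
            [
                np.zeros((n_pure, n_loci, 2), dtype=np.int64),
                np.ones((n_pure, n_loci, 2), dtype=np.int64),
                np.tile(np.array([0, 1]), (n_hyb, n_loci, 1)),
            ]
        )
        gm = GenotypeMatrix(
            ids=[f"i{j}" for j in range(2 * n_pure + n_hyb)],
            pops=["a"] * n_pure + ["b"] * n_pure + ["h"] * n_hyb,
            loci=[f"L{l}" for l in range(n_loci)],
            calls=calls,
        )
        res = em_admixture(gm, K=2, n_restarts=5, seed=4)
        hyb_q = res.Q[2 * n_pure :, 0]
        np.testing.assert_allclose(hyb_q, 0.5, atol=0.05)

    def test_k_above_distinct_genotypes_warns(self):
        calls = np.zeros((4, 3, 2), dtype=np.int64)
        gm = GenotypeMatrix(
            ids=list("abcd"), pops=["p"] * 4, loci=["x", "y", "z"], calls=calls
        )
        with pytest.warns(UserWarning, match="distinct"):
            em_admixture(gm, K=3, n_restarts=1, max_iter=5, seed=0)

    def test_empty_matrix_errors(self):
        gm = GenotypeMatrix(ids=[], pops=[], loci=["L"], calls=np.zeros((0, 1, 2)))
        with pytest.raises(ValueError):
            em_admixture(gm, K=2)

    def test_supervised_and_unsupervised_agree_on_transect(self):
        cfg = SimConfig(
            n_loci=20,
            deme_positions=list(np.linspace(0, 600, 9)),
            n_per_deme=[8] * 9,
            true_cline=ClineModel(center=300.0, width=120.0),
            true_mt_cline=ClineModel(center=300.0, width=120.0),
            seed=6,
        )
        ds = simulate_dataset(cfg)
        gm = ds.genotypes
        res = em_admixture(gm, K=2, n_restarts=3, seed=6)
        mask_a = np.array([p in ds.reference_sets["A"] for p in gm.pops])
        mask_b = np.array([p in ds.reference_sets["B"] for p in gm.pops])
        h = hybrid_index_ml(
            gm, pooled_frequencies(gm, mask_a), pooled_frequencies(gm, mask_b)
        ).h
        q = res.Q[:, 0]
        r = abs(np.corrcoef(h, q)[0, 1])
        assert r > 0.98


# ---------------------------------------------------------------------------
# supervised hybrid index


def _diag_freqs(n_loci):
    fa = np.zeros((n_loci, 2))
    fb = np.zeros((n_loci, 2))
    fa[:, 0] = 1.0
    fb[:, 1] = 1.0
    return fa, fb


class TestHybridIndex:
    def test_all_b_alleles_gives_h_one(self):
        fa, fb = _diag_freqs(6)
        gm = GenotypeMatrix(
            ids=["x"], pops=["p"], loci=[f"L{l}" for l in range(6)],
            calls=np.ones((1, 6, 2), dtype=np.int64),
        )
        res = hybrid_index_ml(gm, fa, fb)
        assert res.h[0] == 1.0

    def test_f1_heterozygote_is_exactly_half(self):
        fa, fb = _diag_freqs(8)
        calls = np.tile(np.array([0, 1]), (1, 8, 1))
        gm = GenotypeMatrix(
            ids=["f1"], pops=["p"], loci=[f"L{l}" for l in range(8)], calls=calls
        )
        res = hybrid_index_ml(gm, fa, fb)
        assert res.h[0] == pytest.approx(0.5, abs=1e-6)
        lo, hi = res.ci_low[0], res.ci_high[0]
        assert lo < 0.5 < hi

    def test_boundary_mle_matches_grid_oracle(self):
        # one locus, both copies carry the allele with fA=0.2, fB=0.8:
        # likelihood increasing in h, so the MLE sits at the boundary h=1
        fa = np.array([[0.2, 0.8]])
        fb = np.array([[0.8, 0.2]])
        gm = GenotypeMatrix(
            ids=["x"], pops=["p"], loci=["L"], calls=np.zeros((1, 1, 2), dtype=np.int64)
        )
        res = hybrid_index_ml(gm, fa, fb)
        grid = np.linspace(0, 1, 10001)
        ll = 2 * np.log(grid * 0.8 + (1 - grid) * 0.2)
        assert res.h[0] == pytest.approx(grid[np.argmax(ll)], abs=1e-4)
        assert res.h[0] == 1.0

    def test_all_missing_individual_flagged(self):
        fa, fb = _diag_freqs(3)
        calls = np.full((1, 3, 2), MISSING, dtype=np.int64)
        gm = GenotypeMatrix(ids=["m"], pops=["p"], loci=["a", "b", "c"], calls=calls)
        with pytest.warns(UserWarning, match="undefined"):
            res = hybrid_index_ml(gm, fa, fb)
        assert np.isnan(res.h[0])


# ---------------------------------------------------------------------------
# replicate alignment


class TestAlignReplicates:
    def _result(self, Q, seed=0):
        from clinekit.ancestry import AncestryResult

        K = Q.shape[1]
        return AncestryResult(
            Q=Q, F=np.zeros((K, 2, 2)), loglik_trace=np.array([-1.0]),
            K=K, converged=True, seed=seed,
            ids=[f"i{j}" for j in range(Q.shape[0])],
            pops=["p"] * Q.shape[0], allele_counts=[2, 2],
        )

    def test_swapped_columns_are_unswapped(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet(np.ones(2), size=12)
        aligned, mean_q = align_replicates(
            [self._result(Q), self._result(Q[:, ::-1])]
        )
        np.testing.assert_allclose(aligned[1].Q, Q, atol=1e-12)
        np.testing.assert_allclose(mean_q, Q, atol=1e-12)

    def test_identical_replicates_identity(self):
        rng = np.random.default_rng(1)
        Q = rng.dirichlet(np.ones(3), size=9)
        aligned, mean_q = align_replicates([self._result(Q)] * 3)
        for rep in aligned:
            np.testing.assert_array_equal(rep.Q, Q)
        np.testing.assert_allclose(mean_q.sum(axis=1), 1.0, atol=1e-12)

    def test_k3_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        ref = rng.dirichlet(np.ones(3), size=30)
        for perm in [(2, 0, 1), (1, 2, 0), (2, 1, 0)]:
            noisy = np.clip(ref[:, perm] + rng.normal(0, 0.05, ref.shape), 1e-6, None)
            noisy /= noisy.sum(axis=1, keepdims=True)
            aligned, _ = align_replicates([self._result(ref), self._result(noisy)])
            best = brute_force_alignment(ref, noisy)
            np.testing.assert_allclose(aligned[1].Q, noisy[:, list(best)], atol=1e-12)

    def test_mismatched_k_rejected(self):
        r2 = self._result(np.full((5, 2), 0.5))
        r3 = self._result(np.full((5, 3), 1 / 3))
        with pytest.raises(ValueError):
            align_replicates([r2, r3])


# ---------------------------------------------------------------------------
# Evanno delta-K


class TestEvannoDeltaK:
    def test_linear_loglik_gives_zero(self):
        lls = {k: [-10.0 * k + 1.0, -10.0 * k - 1.0] for k in range(1, 5)}
        dk = evanno_delta_k(lls)
        for v in dk.values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_hand_arithmetic_example(self):
        # means -100, -50, -45 with sd(L(2)) = 2 -> delta-K(2) = 45/2
        s = np.sqrt(2.0)
        lls = {1: [-100.0, -100.0], 2: [-50.0 - s, -50.0 + s], 3: [-45.0, -45.0]}
        dk = evanno_delta_k(lls)
        assert dk[2] == pytest.approx(22.5, rel=1e-12)

    def test_zero_sd_reports_infinity_with_warning(self):
        lls = {1: [-9.0, -9.0], 2: [-5.0, -5.0], 3: [-4.5, -4.5]}
        with pytest.warns(UserWarning, match="zero"):
            dk = evanno_delta_k(lls)
        assert np.isinf(dk[2])

    def test_needs_three_k_values(self):
        with pytest.raises(ValueError):
            evanno_delta_k({1: [-1.0, -2.0], 2: [-1.0, -2.0]})

    def test_two_population_data_peaks_at_k2(self):
        """On clearly two-cluster data the second-difference statistic picks
        K=2 in the vast majority of replicates."""
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = SimConfig(
                n_loci=10,
                alleles_per_locus=4,
                deme_positions=[0.0, 1000.0],
                n_per_deme=[15, 15],
                true_cline=ClineModel(center=500.0, width=1.0),
                true_mt_cline=ClineModel(center=500.0, width=1.0),
                n_reference=0,
                parental_divergence=0.5,
                seed=100 + seed,
            )
            gm = simulate_dataset(cfg).genotypes
            lls = {}
            for K in (1, 2, 3, 4):
                lls[K] = [
                    em_admixture(
                        gm, K=K, n_restarts=1, max_iter=200, seed=1000 * seed + 10 * K + r
                    ).loglik
                    for r in range(3)
                ]
            dk = evanno_delta_k(lls)
            finite = {k: v for k, v in dk.items() if np.isfinite(v)}
            if finite and max(finite, key=finite.get) == 2:
                hits += 1
        assert hits >= 0.75 * n_seeds


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def wc_theta_oracle(pop_genotypes):
    """Independent brute-force Weir & Cockerham (1984) variance components.

    ``pop_genotypes``: list (per population) of lists of (a1, a2) tuples.
    Written directly from the published per-allele component definitions,
    without reuse of the library code.
    """
    r = len(pop_genotypes)
    n_i = np.array([len(p) for p in pop_genotypes], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted({a for pop in pop_genotypes for g in pop for a in g})
    num = den = 0.0
    for allele in alleles:
        p_i = np.array(
            [sum((g.count(allele)) for g in pop) / (2.0 * len(pop)) for pop in pop_genotypes]
        )
        h_i = np.array(
            [
                sum(1 for g in pop if (g[0] == allele) != (g[1] == allele)) / len(pop)
                for pop in pop_genotypes
            ]
        )
        pbar = float((n_i * p_i).sum() / (r * nbar))
        s2 = float((n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar))
        hbar = float((n_i * h_i).sum() / (r * nbar))
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWeirCockerham:
    def test_fixed_differences_give_theta_one(self, diagnostic_genotypes):
        mat = weir_cockerham_fst(diagnostic_genotypes, min_n=5)
        assert mat.pair("p1", "p2") == pytest.approx(1.0, abs=1e-12)

    def test_random_split_of_one_deme_is_near_zero(self):
        rng = np.random.default_rng(42)
        n, n_loci = 200, 15
        calls = rng.integers(0, 4, size=(n, n_loci, 2))
        pops = ["x"] * 100 + ["y"] * 100
        gm = GenotypeMatrix(
            ids=[f"i{j}" for j in range(n)], pops=pops,
            loci=[f"L{l}" for l in range(n_loci)], calls=calls,
        )
        theta = weir_cockerham_fst(gm).pair("x", "y")
        assert abs(theta) < 0.02

    def test_two_pop_toy_matches_brute_force_oracle(self):
        # pop1: 5 x AA, 5 x Aa; pop2: 10 x aa  (A=0, a=1)
        pop1 = [(0, 0)] * 5 + [(0, 1)] * 5
        pop2 = [(1, 1)] * 10
        expected = wc_theta_oracle([pop1, pop2])
        calls = np.array([list(g) for g in pop1 + pop2])[:, None, :]
        gm = GenotypeMatrix(
            ids=[f"i{j}" for j in range(20)],
            pops=["p1"] * 10 + ["p2"] * 10,
            loci=["L"],
            calls=calls,
        )
        theta = weir_cockerham_fst(gm).pair("p1", "p2")
        assert theta == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_multiallelic_multilocus_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2, n_loci = 12, 9, 5
        calls = np.concatenate(
            [
                rng.integers(0, 3, size=(n1, n_loci, 2)),
                rng.integers(1, 5, size=(n2, n_loci, 2)),
            ]
        )
        gm = GenotypeMatrix(
            ids=[f"i{j}" for j in range(n1 + n2)],
            pops=["p1"] * n1 + ["p2"] * n2,
            loci=[f"L{l}" for l in range(n_loci)],
            calls=calls,
        )
        mat = weir_cockerham_fst(gm)
        # oracle: per locus components accumulated over loci
        num = den = 0.0
        for l in range(n_loci):
            pops = [
                [tuple(row) for row in calls[:n1, l, :]],
                [tuple(row) for row in calls[n1:, l, :]],
            ]
            # reuse single-locus oracle internals by computing ratio parts
            r = 2
            n_i = np.array([n1, n2], dtype=float)
            nbar = n_i.mean()
            nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
            alleles = sorted({a for pop in pops for g in pop for a in g})
            for allele in alleles:
                p_i = np.array([sum(g.count(allele) for g in pop) / (2 * len(pop)) for pop in pops])
                h_i = np.array(
                    [sum(1 for g in pop if (g[0] == allele) != (g[1] == allele)) / len(pop) for pop in pops]
                )
                pbar = float((n_i * p_i).sum() / (r * nbar))
                s2 = float((n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar))
                hbar = float((n_i * h_i).sum() / (r * nbar))
                a = (nbar / nc) * (
                    s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
                )
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
                )
                c = hbar / 2
                num += a
                den += a + b + c
        assert mat.pair("p1", "p2") == pytest.approx(num / den, abs=1e-10)

    def test_monomorphic_pair_reported_undefined(self):
        calls = np.zeros((12, 2, 2), dtype=np.int64)
        gm = GenotypeMatrix(
            ids=[f"i{j}" for j in range(12)],
            pops=["p1"] * 6 + ["p2"] * 6,
            loci=["L1", "L2"],
            calls=calls,
        )
        with pytest.warns(UserWarning, match="undefined"):
            mat = weir_cockerham_fst(gm)
        assert np.isnan(mat.pair("p1", "p2"))

    def test_small_populations_excluded_by_min_n(self, diagnostic_genotypes):
        gm = diagnostic_genotypes
        gm2 = gm.subset(np.arange(13))  # p2 keeps only 3 individuals
        with pytest.warns(UserWarning, match="excluded"):
            mat = weir_cockerham_fst(gm2, min_n=5)
        assert list(mat.theta.index) == ["p1"]


# ---------------------------------------------------------------------------
# pure/mixed classification


class TestClassifyPopulation:
    def test_high_q_single_haplotype_is_pure(self):
        assert classify_population(0.95, (10, 0)) == "pure"

    def test_both_haplotypes_force_mixed(self):
        assert classify_population(0.95, (8, 2)) == "mixed"

    def test_q_below_threshold_is_mixed(self):
        assert classify_population(0.89, (10, 0)) == "mixed"

    def test_threshold_is_strict(self):
        assert classify_population(0.90, (10, 0)) == "pure"

    def test_no_data_unclassified(self):
        assert classify_population(None, None) == "unclassified"
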