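"""Tests of the Gibbs sampler: CRP prior, assignment weights, sweeps,
schedule arithmetic, fast likelihood path, posterior score and convergence."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from dpgp.gp import (ClusterModel, DataError, KernelHyperparams, ParameterError,
                     TimeGrid, gram_matrix)
from dpgp.io import ExpressionMatrix
from dpgp.sampler import (DPConfig, Partition, assignment_log_weights,
                          check_convergence, crp_prior_probs,
                          fast_gene_log_likelihood, gibbs_sweep, initial_state,
                          partition_log_posterior, run_sampler,
                          sample_from_log_weights)
from dpgp.summarize import build_psm


def _matrix(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    grid = TimeGrid(np.arange(float(values.shape[1])))
    ids = np.array([f"g{i}" for i in range(values.shape[0])], dtype=object)
    return ExpressionMatrix(ids, grid, values)


class TestCRPPrior:
    def test_two_gene_example(self):
        cfg = DPConfig(alpha=1.0, m=4)
        existing, aux = crp_prior_probs(1, Partition(np.array([0, 0])), cfg)
        assert np.isclose(existing[0], 0.5)
        assert np.allclose(aux, 0.125)
        assert np.isclose(sum(existing.values()) + aux.sum(), 1.0)

    def test_mass_proportional_to_cluster_size(self):
        cfg = DPConfig()
        c = np.array([0] * 10 + [1] + [2])  # target gene is the last one
        existing, aux = crp_prior_probs(11, Partition(c), cfg)
        assert np.isclose(existing[0] / existing[1], 10.0)
        assert np.isclose(sum(existing.values()) + aux.sum(), 1.0)

    def test_singleton_dataset_puts_all_mass_on_aux(self):
        cfg = DPConfig()
        existing, aux = crp_prior_probs(0, Partition(np.array([0])), cfg)
        assert not existing
        assert np.isclose(aux.sum(), 1.0)


class TestAssignmentWeights:
    def test_equal_likelihoods_reduce_to_crp(self, grid8):
        hp = KernelHyperparams(1.0, 1.0, 0.2)
        mean = np.zeros(8)
        cfg = DPConfig()
        y = np.ones(8)
        # identical models -> identical likelihoods -> weights follow the prior
        cands = [(6, ClusterModel(grid8, hp, mean)), (2, ClusterModel(grid8, hp, mean)),
                 (None, ClusterModel(grid8, hp, mean))]
        w = assignment_log_weights(y, cands, cfg)
        p = np.exp(w - w.max())
        p /= p.sum()
        denom = 6 + 2 + cfg.alpha / cfg.m
        assert np.allclose(p, [6 / denom, 2 / denom, (cfg.alpha / cfg.m) / denom])

    def test_shift_invariance_of_sampling(self):
        logw = np.array([0.0, -1.0, -2.0])
        draws1 = [sample_from_log_weights(logw, np.random.default_rng(s)) for s in range(50)]
        draws2 = [sample_from_log_weights(logw + 123.4, np.random.default_rng(s)) for s in range(50)]
        assert draws1 == draws2

    def test_matching_cluster_dominates(self, grid8):
        rng = np.random.default_rng(0)
        hp = KernelHyperparams(1.0, 1.0, 0.05)
        K = gram_matrix(grid8, hp)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(8))
        m1, m2 = L @ rng.standard_normal(8), L @ rng.standard_normal(8)
        c1 = ClusterModel(grid8, hp, m1)
        c2 = ClusterModel(grid8, hp, m2)
        w = assignment_log_weights(m1, [(10, c1), (10, c2)], DPConfig())
        p = np.exp(w - w.max())
        p /= p.sum()
        assert p[0] > 0.99

    def test_all_minus_inf_rejected(self):
        with pytest.raises(ParameterError):
            sample_from_log_weights(np.array([-np.inf, -np.inf]),
                                    np.random.default_rng(0))


class TestGibbsSweep:
    def test_sweep_conserves_gene_count(self):
        rng = np.random.default_rng(1)
        data = _matrix(rng.standard_normal((20, 6)))
        cfg = DPConfig(seed=0)
        state = initial_state(data, cfg)
        for _ in range(5):
            state = gibbs_sweep(state, data, cfg, rng)
            sizes = state.partition.sizes()
            assert sum(sizes.values()) == 20
            assert all(state.clusters[l].size == n for l, n in sizes.items())

    def test_identical_trajectories_concentrate_on_one_cluster(self):
        y = np.sin(np.linspace(0, 3, 6))
        data = _matrix(np.tile(y, (12, 1)))
        trace = run_sampler(data, DPConfig(max_iterations=150, seed=4))
        counts = [len(np.unique(a)) for a in trace.assignments]
        # single-cluster partition is the modal sampled state
        assert np.bincount(counts).argmax() == 1

    def test_prior_only_expected_cluster_count(self):
        """Likelihood-disabled sampler matches the CRP closed form
        E[H] = sum_i alpha / (alpha + i - 1)."""
        P, alpha = 25, 1.0
        expected = sum(alpha / (alpha + i) for i in range(P))
        data = _matrix(np.zeros((P, 4)) + np.arange(4))
        chain_means = []
        for seed in range(12):
            cfg = DPConfig(max_iterations=120, thin=3, seed=seed, prior_only=True)
            trace = run_sampler(data, cfg)
            chain_means.append(np.mean([len(np.unique(a)) for a in trace.assignments]))
        se = np.std(chain_means, ddof=1) / math.sqrt(len(chain_means))
        assert abs(np.mean(chain_means) - expected) < 3 * se + 0.5


class TestSchedule:
    def test_trace_length_arithmetic(self):
        data = _matrix(np.random.default_rng(0).standard_normal((5, 6)))
        for max_iter, thin in [(50, 3), (100, 5), (25, 1)]:
            cfg = DPConfig(max_iterations=max_iter, thin=thin, seed=0)
            trace = run_sampler(data, cfg)
            expected = math.floor(0.52 * max_iter / thin)
            assert abs(trace.Q - expected) <= 1

    def test_too_few_iterations_rejected(self):
        data = _matrix(np.zeros((3, 6)) + np.arange(6))
        with pytest.raises(ParameterError):
            run_sampler(data, DPConfig(max_iterations=4, thin=3, seed=0))

    def test_fixed_seed_reproducible(self):
        data = _matrix(np.random.default_rng(3).standard_normal((15, 6)))
        t1 = run_sampler(data, DPConfig(max_iterations=100, seed=42))
        t2 = run_sampler(data, DPConfig(max_iterations=100, seed=42))
        assert np.array_equal(t1.assignments, t2.assignments)
        assert np.allclose(t1.log_posteriors, t2.log_posteriors)


class TestFastLikelihood:
    def test_agrees_with_dense_evaluation(self, grid8):
        rng = np.random.default_rng(8)
        for _ in range(100):
            hp = KernelHyperparams(*np.exp(rng.uniform(-1, 1, 3)))
            model = ClusterModel(grid8, hp, mean=rng.standard_normal(8))
            y = rng.standard_normal(8)
            dense = multivariate_normal(
                model.mean, model.covariance + hp.noise_variance * np.eye(8)).logpdf(y)
            assert abs(fast_gene_log_likelihood(y, model) - dense) < 1e-10

    def test_single_point_reduces_to_univariate_normal(self):
        g = TimeGrid(np.array([0.0]))
        hp = KernelHyperparams(1.0, 0.5, 0.5)
        model = ClusterModel(g, hp)
        ll = fast_gene_log_likelihood(np.array([0.3]), model)
        assert np.isclose(ll, -0.5 * np.log(2 * np.pi) - 0.5 * 0.3 ** 2, atol=1e-12)

    def test_missing_data_rejected(self, grid8):
        model = ClusterModel(grid8, KernelHyperparams())
        y = np.zeros(8)
        y[3] = np.nan
        with pytest.raises(DataError, match="general"):
            fast_gene_log_likelihood(y, model)

    def test_factorization_shared_across_genes(self, grid8):
        rng = np.random.default_rng(1)
        model = ClusterModel(grid8, KernelHyperparams())
        for _ in range(50):
            fast_gene_log_likelihood(rng.standard_normal(8), model)
        assert model.factor_computations == 1

    def test_fast_mode_requires_complete_data(self):
        values = np.random.default_rng(0).standard_normal((6, 6))
        values[0, 2] = np.nan
        with pytest.raises(DataError, match="fast"):
            run_sampler(_matrix(values), DPConfig(max_iterations=50, seed=0,
                                                  fast_mode=True))


class TestPartitionLogPosterior:
    def _setup(self, P=6, T=6, seed=0):
        rng = np.random.default_rng(seed)
        data = _matrix(rng.standard_normal((P, T)))
        hp = KernelHyperparams(1.0, 1.0, 0.2)
        return data, hp

    def test_invariant_under_relabeling(self):
        data, hp = self._setup()
        cfg = DPConfig()
        c1 = np.array([0, 0, 1, 1, 2, 2])
        c2 = np.array([5, 5, 9, 9, 7, 7])  # same partition, different labels
        models1 = {l: ClusterModel(data.grid, hp, np.zeros(6)) for l in [0, 1, 2]}
        models2 = {l: ClusterModel(data.grid, hp, np.zeros(6)) for l in [5, 9, 7]}
        lp1 = partition_log_posterior(Partition(c1), models1, data, cfg)
        lp2 = partition_log_posterior(Partition(c2), models2, data, cfg)
        assert np.isclose(lp1, lp2, atol=1e-10)

    def test_single_gene_crp_term_is_zero(self):
        data, hp = self._setup(P=1)
        cfg = DPConfig(prior_only=True)  # isolates the CRP term
        lp = partition_log_posterior(Partition(np.array([0])),
                                     {0: ClusterModel(data.grid, hp)}, data, cfg)
        assert np.isclose(lp, 0.0, atol=1e-12)

    def test_merging_identical_clusters_never_lowers_likelihood(self):
        y = np.cos(np.linspace(0, 2, 6))
        data = _matrix(np.tile(y, (6, 1)))
        cfg = DPConfig()
        hp = KernelHyperparams(1.0, 1.0, 0.2)

        def score(assign, labels):
            models = {l: ClusterModel(data.grid, hp, mean=y) for l in labels}
            crp_only = partition_log_posterior(
                Partition(assign), models, data, DPConfig(prior_only=True))
            full = partition_log_posterior(Partition(assign), models, data, cfg)
            prior = sum(cfg.hyperpriors.log_density(m.hyperparams)
                        for m in models.values())
            return full - crp_only - prior  # likelihood term alone

    # merged single cluster vs split into two, same parameters
        merged = score(np.zeros(6, dtype=int), [0])
        split = score(np.array([0, 0, 0, 1, 1, 1]), [0, 1])
        assert merged >= split - 1e-9


class TestConvergence:
    def test_identical_partitions_converge_at_minimum_window(self):
        A = np.tile(np.array([0, 0, 1, 1]), (10, 1))
        lp = np.full(10, -5.0)
        ok, diag = check_convergence(A, lp, window=4)
        assert ok
        assert np.allclose(diag["psm_distance"], 0.0)

    def test_alternating_partitions_do_not_converge(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        A = np.array([a, b] * 10)
        lp = np.full(20, -5.0)
        ok, diag = check_convergence(A, lp, window=4)
        assert not ok
        assert diag["psm_distance"][-1] > 0.05  # distance stays at its ceiling

    def test_too_few_samples_not_converged(self):
        A = np.tile(np.array([0, 1]), (3, 1))
        ok, _ = check_convergence(A, np.zeros(3), window=4)
        assert not ok


class TestExchangeability:
    def test_permuted_gene_order_gives_equivalent_psm(self, three_cluster_ds):
        """Mantel-style correlation between the PSM of the original data and
        the (unpermuted) PSM of a gene-shuffled copy."""
        matrix = three_cluster_ds.matrix
        sub = np.arange(0, matrix.P, 3)  # 50 genes, keeps runtime short
        values = matrix.values[sub]
        data = _matrix(values)
        cfg = DPConfig(max_iterations=200, seed=13)
        psm1 = build_psm(run_sampler(data, cfg)).S

        rng = np.random.default_rng(99)
        perm = rng.permutation(len(sub))
        data_p = _matrix(values[perm])
        psm2p = build_psm(run_sampler(data_p, cfg)).S
        inv = np.argsort(perm)
        psm2 = psm2p[np.ix_(inv, inv)]

        iu = np.triu_indices(len(sub), k=1)
        r = np.corrcoef(psm1[iu], psm2[iu])[0, 1]
        assert r > 0.95
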