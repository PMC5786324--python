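# dpgp — Dirichlet process Gaussian process mixture clustering of expression time series

Time-course expression experiments (a stress response, a drug exposure, a
developmental series) are usually summarized by grouping genes with similar
response shapes.  Distance-based clustering ignores the correlation between
adjacent time points and needs the number of clusters up front; `dpgp`
addresses both problems with a Bayesian nonparametric model: a **Dirichlet
process** (DP) prior over partitions, so the number of clusters is inferred,
coupled with a cluster-specific **Gaussian process** (GP) over time, so
temporal dependence is modeled explicitly.

For gene j assigned to cluster h,

    y_j | c_j = h  ~  N(mu_h, K_h + sigma_h^2 I),
    k_h(x, x') = tau_h^2 exp(-(x - x')^2 / (2 ell_h^2)),

with hyperpriors ell_h ~ logN(0,1), tau_h ~ logN(0,1), sigma_h^2 ~
InvGamma(12, 2), and DP concentration alpha = 1 (expected cluster count ~
alpha log P).  Inference is Gibbs sampling over assignments with m = 4
auxiliary empty clusters (Neal's Algorithm 8), a two-phase burn-in covering
the first 48% of iterations, and type-II maximum-likelihood kernel updates
via L-BFGS-B.  The thinned trace is summarized into a posterior similarity
matrix (pairwise co-clustering frequencies), the maximum a posteriori (MAP)
partition, per-gene cluster inclusion probabilities, and per-cluster
posterior means with 95% predictive bands — which also make the model usable
for imputing expression at unobserved times.  A fast path (one covariance
factorization per cluster per sweep) applies whenever all genes are observed
at identical time points.  Missing cells and uneven sampling are handled
exactly by GP marginalization.  See `docs/methods.md` for the full model and
the numerical choices.

Intended users: computational biologists clustering bulk or single-cell
time-course matrices (genes x time points, TSV), and methods developers who
want a reproducible, tested reference for DP-GP mixture inference.

## Worked example

```python
import numpy as np
from dpgp import (DPConfig, SimulationSpec, adjusted_rand_index, build_psm,
                  cluster_credible_bands, inclusion_probabilities,
                  run_sampler, select_map_partition, simulate_dataset)

# three well-separated GP clusters of 50 genes, 8 time points
spec = SimulationSpec(n_clusters=3, sizes=50, length_scale=1.0,
                      signal_variance=1.0, marginal_variance=0.05)
ds = simulate_dataset(spec, seed=1)

config = DPConfig(max_iterations=300, seed=7)
trace = run_sampler(ds.matrix, config)
result = select_map_partition(trace, ds.matrix, config)
psm = build_psm(trace)
probs = inclusion_probabilities(result, psm)

print(f"samples: {trace.Q}, clusters in MAP partition: {result.partition.n_clusters}")
print(f"ARI vs ground truth: {adjusted_rand_index(result.partition, ds.truth):.3f}")
print(f"median inclusion probability: {np.median(probs):.3f}")
bands = cluster_credible_bands(result, level=0.95)
```

Output:

```
samples: 52, clusters in MAP partition: 3
ARI vs ground truth: 1.000
median inclusion probability: 1.000
```

The sampler thins 300 iterations to 52 recorded partitions; the MAP
partition recovers the three generating clusters exactly (Adjusted Rand
Index 1.0 — chance-corrected agreement, 1 = identical), and every gene
co-clusters with its final partners in essentially all samples (inclusion
probability 1).  `bands` maps each cluster to (mean, lower, upper) arrays
over the grid: the 95% predictive interval for a member trajectory, usable
for imputation at held-out times.

## Command line

```sh
dpgp simulate --output bench --clusters 20 --genes-per-cluster 25 --seed 1
dpgp cluster --input bench_rep1.txt --output run --iterations 1000 --seed 1
```

`dpgp cluster` writes `run_clustering.txt` (gene, cluster, inclusion
probability), `run_psm.txt` (posterior similarity matrix), `run_cluster_means.txt`
(cluster, time, mean, lower, upper) and `run_log.txt` (full configuration
echo).  `--fast` enables the shared-factorization path (complete data only),
`--microarray-prior` relaxes the noise prior (alpha_IG = 6) for noisier
platforms, and `--check-convergence` stops the chain early once the
posterior-similarity and log-posterior criteria stabilize.

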