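# critmem

Attractor-network simulations of memory consolidation near criticality,
plus branching-parameter analysis of spike trains.

`critmem` is for computational neuroscientists studying how new information
is stored in recurrent networks that already hold memories. It implements
two connected analyses:

1. **In silico** — a mean-field Hopfield-like network of binary neurons
   S_i = ±1 on a directed small-world graph, with heat-bath dynamics
   driven by local fields h_i = (1/k) Σ_j J_ij S_j and alignment
   probability P = 1/(1+e^(−2β|h_i|)). Memories are stored by the
   outer-product rule J_ij = (1/p) Σ_μ ξ_{i,μ} ξ_{j,μ}; a new
   configuration ξᵉ arrives either through a clamped subset of input
   neurons or a uniform external field, and is consolidated by unbounded
   Hebbian plasticity ΔJ_ij = ε S_i S_j. The package measures overlap and
   stability order parameters, estimates critical temperatures (half-max
   interpolation and sigmoid fits of f(T) = 0.5/(1+e^(−(T−T_c)/μ))),
   consolidation times, input-robustness maps, and the memory-capacity
   phase diagram (classic deterministic limit α_max ≈ 0.14).

2. **Spike trains** — the branching parameter σ of pooled population
   activity, binned at 16 ms per sleep bout and estimated by multistep
   regression: lag slopes r_k = Cov(a_t, a_{t+k})/Var(a_t) decay as b·σ^k,
   and the exponential fit across k = 1..40 cancels the constant bias that
   spatial subsampling puts into any single-lag slope. Non-stationary
   bouts are screened out; subjects and groups are summarised as
   Δσ = σ_post − σ_baseline. A synthetic-data module generates driven
   branching processes and full conditioning cohorts so the whole pipeline
   runs without any recordings.

## Worked example

Temperature sweep of a single-memory network (N = 1000, 2% connectivity),
then locate the transition:

```python
import numpy as np
from critmem import SweepGrid, protocol_prelearn_sweep, tc_from_halfmax

grid = SweepGrid(temperatures=np.arange(0.2, 2.01, 0.2), realizations=5,
                 seed=0, n_neurons=1000, in_degree=20)
res = protocol_prelearn_sweep(grid, p=1, input_size=0)
print(res.to_frame().round(3).to_string(index=False))
fit = tc_from_halfmax(res.temperatures, res.overlap_native)
print(f"T_c = {fit.t_c:.3f}")
```

```
 temperature  overlap_native  overlap_native_sem  overlap_new  overlap_new_sem  flip_fraction
         0.2           0.810               0.171        0.023            0.010          0.013
         0.4           0.854               0.084        0.027            0.009          0.029
         0.6           0.904               0.001        0.027            0.008          0.094
         0.8           0.633               0.007        0.022            0.004          0.293
         1.0           0.050               0.013        0.022            0.002          0.473
         1.2           0.030               0.005        0.025            0.002          0.488
         2.0           0.026               0.002        0.026            0.003          0.498
T_c = 0.862
```

Below the transition the network recalls its stored memory (overlap ≈ 0.9,
few state changes); above it the dynamics disorder (overlap ≈ 0, half the
neurons flipping per sweep); the half-max crossing puts T_c near 1, as
expected for a single stored pattern.

Branching-parameter recovery under heavy subsampling — a σ = 0.95 driven
branching process observed through a 10% binomial window:

```python
from critmem import BranchingProcessSpec, simulate_branching, mr_estimate

spec = BranchingProcessSpec(sigma=0.95, drive_rate=2.0, n_bins=100_000,
                            subsample_prob=0.1, seed=0)
est = mr_estimate(simulate_branching(spec))
print(f"sigma_hat = {est.sigma:.4f}  (naive r1 = {est.lag_slopes[0]:.3f})")
```

```
sigma_hat = 0.9498  (naive r1 = 0.510)
```

The naive lag-1 slope collapses to 0.51 under subsampling; the multistep
fit recovers the true 0.95.

Shell users get the same protocols as subcommands:

```
critmem sweep-prelearn --config sweep.yaml --out sweep.csv
critmem synth-cohort --out cohort/ --seed 1
critmem branching --manifest cohort/manifest.tsv --behavior cohort/behavior.tsv --out sigma.csv
```

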