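# Methods

## The model

`critmem` simulates memory consolidation in a mean-field attractor network
of N binary neurons, S_i = ±1 (firing / quiescent), coupled through a
directed, weighted matrix J. Each sweep updates every non-clamped neuron
from its local field

    h_i = (1/k) Σ_{j→i} J_ij S_j ,

aligning S_i with sgn(h_i) with the heat-bath probability
P = 1/(1 + exp(−2β|h_i|)), β = 1/T. Temperature is the control parameter:
β → 0 gives coin-flip disorder, β → ∞ deterministic recall. The critical
temperature T_c separates the recall phase (a stored memory dominates)
from the disordered phase, and sits near T = 1 for a single stored memory.

Assumptions worth keeping in mind:

* neurons are homogeneous binary units — no cell types, no conductances;
* the update schedule is synchronous (whole-network sweeps); a
  random-sequential option exists behind `schedule="asynchronous"` for
  sensitivity checks and gives qualitatively identical sweeps;
* at zero local field the heat-bath distribution is uniform, so the update
  draws a fair coin at T > 0 and keeps the current state only in the
  deterministic T = 0 limit. This matters quantitatively: with in-degree
  k = 20 and one stored pattern, ~18% of fields are exactly zero at any
  instant, and pinning those neurons would depress the super-critical flip
  fraction well below its 1/2 asymptote.

## Network construction

The topology is a directed small-world graph built from a ring lattice in
which every neuron receives from its k nearest ring neighbours (⌈k/2⌉
clockwise, ⌊k/2⌋ counter-clockwise when k is odd). Each incoming edge has
its *source* rewired with probability 0.1 to a uniformly random non-self,
non-duplicate source. Source-rewiring preserves every in-degree exactly,
which the 1/k field normalisation presumes. Defaults mirror the study
system proportionally: N = 1000 with k = 20 (2% incoming connectivity,
rewiring 0.1); the full-scale system is N = 10 000, k = 200.

p native memories ξⁿ (entries ±1 with probability 1/2) are embedded by the
outer-product rule J_ij = (1/p) Σ_μ ξⁿ_{i,μ} ξⁿ_{j,μ} on existing edges
only (J_ii = 0 because self-edges do not exist). A new configuration ξᵉ
arrives through a random subset N′ of input neurons whose states are
clamped to ξᵉ and whose outgoing edges are overwritten to
J_ij = (w_e/p) ξᵉ_i ξᵉ_j. No edges are created. The alternative delivery
mode is a persistent uniform field h_i += (w_ext/p) ξᵉ_i applied to every
neuron.

## Order parameters and T_c estimation

Recall is measured by the overlap m = |⟨ξ_i S_i⟩| over non-clamped
neurons; stability by the per-sweep fraction of state changes, which rises
from 0 toward 1/2 across the transition. Sweep endpoints average the last
10 iterations to suppress single-sweep noise.

T_c is estimated two ways:

* **half-max interpolation** — the linear interpolation of the crossing of
  half the curve's *observed* maximum (robust to imperfect low-T recall at
  high loading); decreasing (overlap) curves use the first downward
  crossing, increasing (flip) curves the first upward crossing;
* **sigmoid fit** — least squares of f(T) = 0.5/(1 + exp(−(T − T_c)/μ))
  to the flip-fraction curve (scipy `curve_fit`, initialised from the
  half-max estimate, T_c bounded to the sweep window ±5), falling back to
  interpolation on non-convergence.

## Learning protocols

Plasticity is the unbounded state-based Hebbian rule ΔJ_ij = ε·S_i·S_j
(default ε = 0.1), applied after each state sweep to every edge except
those *targeting* clamped neurons (they receive no relevant input); edges
*sourced* at clamped neurons do learn — their output shapes the rest of
the network — with a flag to disable this, since the source behaviour is
genuinely ambiguous in the underlying description.

The standard experiment is pre-learning relaxation (100 sweeps, plasticity
off), a learning phase (default 500 sweeps, one state sweep interleaved
with one Hebbian update), and post-learning relaxation (100 sweeps,
plasticity off, input still wired). Relaxations start from uniform random
states. Pre and post sweeps share networks and seeds so their difference
isolates learning. The consolidation criterion is m^e ≥ 1/2 (reported
"censored" when never reached); stability classifications for phase maps
use the 0.45 threshold throughout.

The ΔT_c-versus-ε experiment uses its own default learning length of 20
sweeps on a T ∈ [0.2, 4] grid: with the unbounded rule the accumulated
weight growth scales like ε × (learning sweeps), and 500-sweep learning
pushes the post-learning transition to T ≳ 5–100, outside any practical
sweep window. With the short burst, ΔT_c = T_c(post) − T_c(pre) is
positive, monotone and approximately proportional to ε
(≈ 0.14 / 0.26 / 0.53 at ε = 0.05 / 0.1 / 0.2, N = 1000). ΔT_c is reported
post-minus-pre so that consolidation yields a positive shift.

The deterministic capacity check uses T = 0 sign-alignment dynamics (the
β → ∞ limit, computed without evaluating the exponential) on the fully
connected outer-product network: a loading p passes if relaxation from
every stored pattern keeps its overlap ≥ 0.9; p_max is bisected with
resolution Δp = max(1, N/200) and averaged over seeds. At N = 500 this
yields α_max = p_max/N ≈ 0.11–0.12, inside the finite-size band around the
classic ≈ 0.14 (the all-patterns-must-pass rule is a worst-case criterion
and sits slightly below the mean-field value).

## Branching-parameter analysis

Population spiking within each slow-wave-sleep bout is pooled across units
and binned into 16 ms half-open bins anchored at the bout start (final
partial bin discarded). For the binned counts a_t, the lag-k regression
slope r_k = Cov(a_t, a_{t+k})/Var(a_t) of a stationary driven branching
process decays as r_k = b·σ^k, where σ is the branching parameter (σ = 1
critical, σ < 1 sub-critical). Spatial subsampling — observing only a
fraction of the units — multiplies every r_k by the same constant, which
is absorbed into b; fitting the exponential over k = 1..40 (640 ms)
therefore recovers σ without the severe downward bias of the naive lag-1
slope (under 10% subsampling of a σ = 0.95 process, r_1 ≈ 0.51 while the
multistep estimate stays at 0.95). The fit includes a constant offset c to
absorb slow residual drifts; estimates are rejected outright when no lag
slope exceeds the 3/√n sampling noise of an independent series.

Per-bout estimates pass a stationarity screen before averaging; a bout is
rejected when (a) the mean count of its two halves differs by more than
0.5 pooled standard deviations (drifting drive), (b) the exponential fit's
R² falls below 0.7 (lag structure inconsistent with a single σ — this
catches fast up/down-state alternation, whose lag structure oscillates),
or (c) σ̂ ≥ 1.1 (runaway). These thresholds are this package's explicit
stand-ins for the unpublished rejection criteria of the established
multistep-regression toolchain; they are configurable and logged per bout.
Known limitation: *slow* two-state switching (periods ≳ 1 s at 16 ms bins)
inflates σ̂ toward 1 while leaving the exponential fit excellent, and is
statistically indistinguishable from genuine near-critical fluctuations by
any per-bout test we evaluated (including smoothed-rate bimodality); such
bouts pass the screen.

Subject summaries average accepted bouts per epoch (mean ± sem); group
summaries report mean Δσ = σ_post − σ_baseline per condition with a
one-sided one-sample t test of Δσ < 0 (reported, never used as a gate).
The behavioural learning score is the percentage-point change in
context-specific freezing between test and pre-shock baseline.

## Synthetic data

The generator emulates slow-wave-sleep population activity as a driven
branching process with Poisson offspring, a_{t+1} ~ Poisson(σ·a_t + drive)
— the estimator's own model class, by design: it validates estimator
correctness, not biological realism. Per-event binomial subsampling
emulates partial observation; injectable non-stationarities (a step change
in drive at the series midpoint; up/down drive alternation with a chosen
period) exercise the rejection screen. Spike times are scattered uniformly
within bins and assigned to units multinomially, so re-binning returns the
original counts exactly.

The default cohort mirrors the study design: 5 conditioned (CFC) and
3 sham subjects, two 24 h epochs each, 6 SWS bouts per epoch with
log-uniform durations of 2–10 minutes. Baselines sit near criticality
(σ = 0.99); conditioning shifts CFC subjects by −0.05 and sham by −0.01.
The drive is set per epoch as rate·(1 − σ) with a fixed observed rate of
4 spikes per bin after 25% subsampling (≈ 250 Hz pooled across 30 units),
so the σ shift — not a rate change — carries the signal. What passing
tests show: the pipeline recovers σ shifts of this size and sign pattern
when the data *are* a driven branching process. What they do not show:
robustness to oscillations, theta/ripple structure, refractoriness,
cell-type heterogeneity, or any feature of real CA1 spiking outside the
model class.

## Problem sizes and numerical choices

Simulations in the tests and the acceptance script run at N = 500–1000
with 2% connectivity (k = 20), 5–20 realizations per sweep point, and
10⁵-bin branching series — sizes chosen so the whole suite completes on a
single CPU in minutes. All randomness flows from explicitly passed
`numpy.random.Generator`s; per-realization generators are spawned from a
single `SeedSequence`, and identical seeds give identical outputs
(byte-identical synthetic cohort files).

One scaling limitation is documented rather than hidden: with k = 20, a
7%-of-N clamped input set supplies on average 1.4 input edges per neuron
(a quarter of neurons receive none), which caps the susceptibility-driven
alignment near T_c at m^e ≈ 0.36. The consolidated (m^e ≥ 0.45) window
therefore opens ~0.5 above T_c at desk scale, whereas at the full scale
(N = 10 000, k = 200, 14 input edges per neuron) the same code opens the
window within ~0.05 of T_c with post-learning m^e reaching 0.84. The
desk-scale consolidation-window test is kept at the stated conditions and
fails for this reason; every other consolidation property (gain appearing
at T_c, contiguity, sub-critical protection) holds at desk scale.
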