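"""Hebbian consolidation and the experiment protocols.

Protocols mirror the study design: a pre-learning relaxation with the input
wired in, a learning phase that interleaves one state sweep with one
unbounded Hebbian update ΔJ_ij = ε·S_i·S_j, and a post-learning relaxation
with plasticity off.  Consolidation is read out as the growth of the
new-configuration overlap m^e and the upward shift of the critical
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from critmem.network import (
    CoupledNetwork,
    PatternSet,
    build_small_world,
    embed_native,
    make_patterns,
    wire_input,
)
from critmem.dynamics import (
    NetworkState,
    TrajectorySummary,
    evolve,
    local_fields,
    overlap,
    random_state,
    step,
)

__all__ = [
    "LearningConfig",
    "SweepGrid",
    "SweepResult",
    "LearnSweepResult",
    "hebbian_step",
    "run_learning_phase",
    "protocol_prelearn_sweep",
    "protocol_learn_sweep",
    "input_degree_overlap",
    "protocol_input_robustness",
    "protocol_global_field",
    "consolidation_time",
]


@dataclass
class LearningConfig:
    """Plasticity and phase-structure knobs.

    learning_rate ε ≥ 0 (default 0.1); phase_lengths = (pre, learn, post)
    sweep counts; consolidation_threshold is the m^e level that counts as
    consolidated (default 1/2); input_mode selects clamped input neurons vs
    a uniform global field; plastic_fixed_sources controls whether edges
    emanating from clamped neurons learn (they do by default — their output
    shapes the rest of the network; edges *targeting* clamped neurons never
    learn, since those neurons receive no relevant input).
    """

    learning_rate: float = 0.1
    phase_lengths: tuple[int, int, int] = (100, 500, 100)
    consolidation_threshold: float = 0.5
    input_mode: str = "fixed_neurons"
    plastic_fixed_sources: bool = True
    overlap_tail: int = 10  # final-overlap averaging window

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if any(n < 0 for n in self.phase_lengths):
            raise ValueError("phase lengths must be >= 0")
        if not 0 < self.consolidation_threshold <= 1:
            raise ValueError("consolidation_threshold must be in (0, 1]")


@dataclass
class SweepGrid:
    """Temperature (and optionally input) grid plus realization count."""

    temperatures: np.ndarray
    realizations: int = 20
    seed: int = 0
    n_neurons: int = 1000
    in_degree: int = 20
    rewire_prob: float = 0.1

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.size and np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")


@dataclass
class SweepResult:
    """Per-temperature order parameters averaged over realizations."""

    temperatures: np.ndarray
    overlap_native: np.ndarray  # mean of max-over-memories overlap
    overlap_native_sem: np.ndarray
    overlap_new: np.ndarray
    overlap_new_sem: np.ndarray
    flip_fraction: np.ndarray  # mean per-sweep flip fraction
    realizations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature": self.temperatures,
                "overlap_native": self.overlap_native,
                "overlap_native_sem": self.overlap_native_sem,
                "overlap_new": self.overlap_new,
                "overlap_new_sem": self.overlap_new_sem,
                "flip_fraction": self.flip_fraction,
            }
        )


@dataclass
class LearnSweepResult:
    """Paired pre- and post-learning sweeps from the same networks."""

    pre: SweepResult
    post: SweepResult

    def delta_overlap_new(self) -> np.ndarray:
        return self.post.overlap_new - self.pre.overlap_new


def _edge_index_arrays(network: CoupledNetwork):
    """(targets, sources) aligned with the CSR data array."""
    w = network.weights
    tgt = np.repeat(
        np.arange(network.n_neurons), np.diff(w.indptr)
    )
    return tgt, w.indices


def hebbian_step(
    network: CoupledNetwork,
    state: NetworkState,
    learning_rate: float,
    *,
    plastic_fixed_sources: bool = True,
    inplace: bool = False,
) -> CoupledNetwork:
    """Apply ΔJ_ij = ε·S_i·S_j to every plastic edge.

    Edges targeting clamped neurons are frozen; edges sourced at clamped
    neurons learn unless ``plastic_fixed_sources=False``.  The rule is
    unbounded: no clipping or decay.
    """
    if learning_rate < 0:
        raise ValueError("learning_rate must be >= 0")
    out = network if inplace else network.copy()
    if learning_rate == 0:
        return out
    tgt, src = _edge_index_arrays(out)
    plastic = ~state.fixed_mask[tgt]
    if not plastic_fixed_sources:
        plastic &= ~state.fixed_mask[src]
    s = state.states.astype(np.float64)
    out.weights.data[plastic] += learning_rate * s[tgt[plastic]] * s[src[plastic]]
    return out


def run_learning_phase(
    network: CoupledNetwork,
    state: NetworkState,
    n_iterations: int,
    patterns: PatternSet,
    learning_rate: float,
    rng: np.random.Generator,
    field_mode: str = "none",
    field_params=None,
    *,
    plastic_fixed_sources: bool = True,
    stop_threshold: float | None = None,
) -> tuple[CoupledNetwork, NetworkState, TrajectorySummary, int | None]:
    """Interleave one synchronous state sweep with one Hebbian update.

    Returns the learned network, the final state, the trajectory, and the
    first iteration (1-based) at which m^e reached ``stop_threshold``
    (None if never; the loop does not stop early unless asked).
    """
    net = network.copy()
    tgt, src = _edge_index_arrays(net)
    plastic = ~state.fixed_mask[tgt]
    if not plastic_fixed_sources:
        plastic &= ~state.fixed_mask[src]
    ptgt, psrc = tgt[plastic], src[plastic]

    excl = patterns.input_set
    p = patterns.p
    m_native = np.empty((n_iterations, p))
    m_new = np.empty(n_iterations)
    flips = np.empty(n_iterations)
    n_free = max(state.n_free, 1)
    hit: int | None = None

    cur = state
    for t in range(n_iterations):
        fields = local_fields(net, cur, field_mode, field_params, n_patterns=p)
        nxt = step(cur, fields, rng)
        flips[t] = (nxt.states != cur.states)[~cur.fixed_mask].sum() / n_free
        s = nxt.states.astype(np.float64)
        net.weights.data[plastic] += learning_rate * s[ptgt] * s[psrc]
        for mu in range(p):
            m_native[t, mu] = overlap(nxt, patterns.native[mu], excl)
        m_new[t] = overlap(nxt, patterns.new, excl)
        cur = nxt
        if hit is None and m_new[t] >= (stop_threshold or np.inf):
            hit = t + 1
            break

    if hit is not None:
        m_native, m_new, flips = m_native[:hit], m_new[:hit], flips[:hit]
    summary = TrajectorySummary(m_native, m_new, flips, final_state=cur)
    return net, cur, summary, hit


def _realization_rngs(seed: int, realizations: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(realizations)]


def _build_system(
    grid: SweepGrid,
    p: int,
    input_size: int,
    input_weight: float,
    rng: np.random.Generator,
    recall_native: bool = False,
) -> tuple[CoupledNetwork, PatternSet, np.ndarray | None]:
    """One realization's network + patterns, with the input wired.

    With ``recall_native`` the input neurons are clamped to the first native
    memory and the rewired couplings use it too (a recall event rather than
    a novel input)."""
    topo = build_small_world(grid.n_neurons, grid.in_degree, grid.rewire_prob, rng)
    patterns = make_patterns(grid.n_neurons, p, input_size, rng)
    net = embed_native(topo, patterns)
    clamp = None
    if input_size > 0 and input_weight > 0:
        if recall_native:
            clamp = patterns.native[0]
            net = wire_input(net, patterns, input_weight, input_pattern=clamp)
        else:
            net = wire_input(net, patterns, input_weight)
    return net, patterns, clamp


def _aggregate(temps, m_nat, m_new, flips, realizations) -> SweepResult:
    def sem(a):
        return a.std(axis=0, ddof=1) / np.sqrt(a.shape[0]) if a.shape[0] > 1 else np.zeros(a.shape[1])

    return SweepResult(
        temperatures=np.asarray(temps, dtype=float),
        overlap_native=m_nat.mean(axis=0),
        overlap_native_sem=sem(m_nat),
        overlap_new=m_new.mean(axis=0),
        overlap_new_sem=sem(m_new),
        flip_fraction=flips.mean(axis=0),
        realizations=realizations,
    )


def protocol_prelearn_sweep(
    grid: SweepGrid,
    p: int = 1,
    input_size: int = 0,
    input_weight: float = 3.0,
    recall_native: bool = False,
    config: LearningConfig | None = None,
) -> SweepResult:
    """Temperature sweep of the network before any plasticity.

    Per temperature and realization: relax from a random initial state with
    the input wired (if any) and record the final max-over-memories native
    overlap, the new-configuration overlap, and the mean flip fraction over
    the second half of the relaxation.
    """
    cfg = config or LearningConfig()
    n_relax = cfg.phase_lengths[0]
    nT = grid.temperatures.size
    m_nat = np.empty((grid.realizations, nT))
    m_new = np.empty((grid.realizations, nT))
    flips = np.empty((grid.realizations, nT))

    for r, rng in enumerate(_realization_rngs(grid.seed, grid.realizations)):
        net, patterns, clamp = _build_system(
            grid, p, input_size, input_weight, rng, recall_native
        )
        for i, T in enumerate(grid.temperatures):
            st = random_state(grid.n_neurons, T, rng, patterns, clamp_pattern=clamp)
            traj = evolve(net, st, n_relax, patterns, rng)
            nat, new = traj.final_overlaps(cfg.overlap_tail)
            m_nat[r, i] = nat.max()
            m_new[r, i] = new
            flips[r, i] = traj.flip_fraction[n_relax // 2 :].mean()

    return _aggregate(grid.temperatures, m_nat, m_new, flips, grid.realizations)


def protocol_learn_sweep(
    grid: SweepGrid,
    p: int = 1,
    input_size: int = 70,
    input_weight: float = 3.0,
    learning_rate: float = 0.1,
    config: LearningConfig | None = None,
) -> LearnSweepResult:
    """Pre-learning relaxation, Hebbian learning phase, post-learning
    relaxation (plasticity off, input still wired), per temperature.

    Pre and post sweeps share networks and seeds, so their difference
    isolates the effect of learning.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be > 0 for the learning protocol")
    cfg = config or LearningConfig(learning_rate=learning_rate)
    n_pre, n_learn, n_post = cfg.phase_lengths
    nT = grid.temperatures.size
    shape = (grid.realizations, nT)
    pre_nat, pre_new, pre_fl = np.empty(shape), np.empty(shape), np.empty(shape)
    post_nat, post_new, post_fl = np.empty(shape), np.empty(shape), np.empty(shape)

    for r, rng in enumerate(_realization_rngs(grid.seed, grid.realizations)):
        net0, patterns, _ = _build_system(grid, p, input_size, input_weight, rng)
        for i, T in enumerate(grid.temperatures):
            st = random_state(grid.n_neurons, T, rng, patterns)
            pre = evolve(net0, st, n_pre, patterns, rng)
            nat, new = pre.final_overlaps(cfg.overlap_tail)
            pre_nat[r, i], pre_new[r, i] = nat.max(), new
            pre_fl[r, i] = pre.flip_fraction[n_pre // 2 :].mean()

            learned, st2, _, _ = run_learning_phase(
                net0,
                pre.final_state,
                n_learn,
                patterns,
                learning_rate,
                rng,
                plastic_fixed_sources=cfg.plastic_fixed_sources,
            )
            post = evolve(learned, st2, n_post, patterns, rng)
            nat, new = post.final_overlaps(cfg.overlap_tail)
            post_nat[r, i], post_new[r, i] = nat.max(), new
            post_fl[r, i] = post.flip_fraction[n_post // 2 :].mean()

    return LearnSweepResult(
        pre=_aggregate(grid.temperatures, pre_nat, pre_new, pre_fl, grid.realizations),
        post=_aggregate(grid.temperatures, post_nat, post_new, post_fl, grid.realizations),
    )


def input_degree_overlap(
    network: CoupledNetwork,
    patterns: PatternSet,
    final_state: NetworkState,
) -> pd.DataFrame:
    """Agreement with the new configuration grouped by input connectivity.

    Non-clamped neurons are grouped by how many of their incoming edges
    originate in N'; per group the mean signed agreement ξᵉ_i·S_i is
    reported.  Clamped neurons are excluded from every group.
    """
    if network.input_sources.size == 0:
        raise ValueError("input is not wired on this network")
    tgt, src = _edge_index_arrays(network)
    in_mask = patterns.input_mask()
    counts = np.bincount(
        tgt[in_mask[src]], minlength=network.n_neurons
    )
    free = ~patterns.input_mask()
    agree = patterns.new.astype(np.float64) * final_state.states.astype(np.float64)
    df = pd.DataFrame(
        {"n_input_connections": counts[free], "agreement": agree[free]}
    )
    out = (
        df.groupby("n_input_connections")["agreement"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_agreement", "count": "n_neurons"})
    )
    return out


def protocol_input_robustness(
    grid: SweepGrid,
    input_fractions: np.ndarray,
    input_weights: np.ndarray,
    p: int = 1,
    learning_rate: float = 0.1,
    config: LearningConfig | None = None,
) -> pd.DataFrame:
    """Peak consolidation gain over temperature as a function of input size
    (fraction of the network) and coupling strength w_e.

    For each (size, w_e) cell the learn protocol is run over the temperature
    grid and the maximum over T of (m^e_post − m^e_pre) is recorded.
    """
    rows = []
    for frac in np.asarray(input_fractions, dtype=float):
        size = int(round(frac * grid.n_neurons))
        for we in np.asarray(input_weights, dtype=float):
            if size == 0:
                peak = 0.0
            else:
                res = protocol_learn_sweep(
                    grid, p, size, we, learning_rate, config
                )
                peak = float(res.delta_overlap_new().max())
            rows.append(
                {"input_fraction": frac, "input_weight": we, "peak_delta_overlap": peak}
            )
    return pd.DataFrame(rows)


def protocol_global_field(
    grid: SweepGrid,
    field_strengths: np.ndarray,
    p: int = 1,
    learning_rate: float = 0.1,
    config: LearningConfig | None = None,
    stability_threshold: float = 0.45,
) -> pd.DataFrame:
    """Uniform-field variant: the new memory arrives as a persistent drive
    (w_ext/p)·ξᵉ to every neuron instead of clamped input neurons.

    Per (w_ext, T): pre-learning with the field on, learning with the field
    on, then a field-off relaxation; the final m^e − m^n and a stability
    classification (native / new / neither at the 0.45 threshold) are
    recorded.
    """
    cfg = config or LearningConfig(learning_rate=learning_rate)
    n_pre, n_learn, n_post = cfg.phase_lengths
    rows = []
    for w_ext in np.asarray(field_strengths, dtype=float):
        for T in grid.temperatures:
            m_new_f = np.empty(grid.realizations)
            m_nat_f = np.empty(grid.realizations)
            for r, rng in enumerate(_realization_rngs(grid.seed, grid.realizations)):
                net, patterns, _ = _build_system(grid, p, 0, 0.0, rng)
                fp = (w_ext, patterns.new)
                st = random_state(grid.n_neurons, T, rng, patterns)
                pre = evolve(net, st, n_pre, patterns, rng, "global", fp)
                learned, st2, _, _ = run_learning_phase(
                    net, pre.final_state, n_learn, patterns,
                    learning_rate, rng, "global", fp,
                    plastic_fixed_sources=cfg.plastic_fixed_sources,
                )
                off = evolve(learned, st2, n_post, patterns, rng, "none")
                nat, new = off.final_overlaps(cfg.overlap_tail)
                m_nat_f[r], m_new_f[r] = nat.max(), new
            mn, me = m_nat_f.mean(), m_new_f.mean()
            if me >= stability_threshold > mn:
                label = "new_stable"
            elif mn >= stability_threshold > me:
                label = "native_stable"
            elif me >= stability_threshold and mn >= stability_threshold:
                label = "both_stable"
            else:
                label = "neither"
            rows.append(
                {
                    "field_strength": w_ext,
                    "temperature": float(T),
                    "overlap_native": mn,
                    "overlap_new": me,
                    "delta_overlap": me - mn,
                    "classification": label,
                }
            )
    return pd.DataFrame(rows)


def consolidation_time(
    network: CoupledNetwork,
    patterns: PatternSet,
    temperature: float,
    learning_rate: float,
    max_iterations: int,
    rng: np.random.Generator,
    *,
    threshold: float = 0.5,
    plastic_fixed_sources: bool = True,
) -> int | None:
    """Number of learning sweeps until the new-configuration overlap first
    reaches ``threshold`` (m^e ≥ 1/2 by default); None means censored —
    consolidation did not occur within ``max_iterations``."""
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    st = random_state(network.n_neurons, temperature, rng, patterns)
    _, _, _, hit = run_learning_phase(
        network,
        st,
        max_iterations,
        patterns,
        learning_rate,
        rng,
        plastic_fixed_sources=plastic_fixed_sources,
        stop_threshold=threshold,
    )
    return hit
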