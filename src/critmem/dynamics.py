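"""Stochastic state dynamics and order-parameter measurement.

Neurons carry binary states S_i = ±1 (firing / quiescent).  Each update
computes the local field h_i = (1/k) Σ_{j→i} J_ij S_j and aligns S_i with
sgn(h_i) with the heat-bath probability P = 1 / (1 + exp(−2β|h_i|)), where
β = 1/T.  As β → 0 the alignment probability tends to 1/2 (disorder); as
β → ∞ updates become deterministic sign alignment (ordered recall).
Neurons in the input subset N' are clamped and never updated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from critmem.network import CoupledNetwork, PatternSet

__all__ = [
    "NetworkState",
    "FieldVector",
    "TrajectorySummary",
    "local_fields",
    "step",
    "overlap",
    "evolve",
    "random_state",
]

FIELD_MODES = ("none", "fixed_neurons", "global")


@dataclass
class NetworkState:
    """Instantaneous ±1 state with a clamp mask for input neurons.

    ``temperature`` T > 0 sets β = 1/T; T = 0 is accepted and means
    deterministic sign alignment (the β → ∞ limit, evaluated without
    overflowing the exponential).
    """

    states: np.ndarray  # (N,) int8 in {-1, +1}
    fixed_mask: np.ndarray  # (N,) bool, True for clamped neurons
    temperature: float

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        self.states = np.asarray(self.states, dtype=np.int8)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)

    @property
    def beta(self) -> float:
        return np.inf if self.temperature == 0 else 1.0 / self.temperature

    @property
    def n_free(self) -> int:
        return int((~self.fixed_mask).sum())

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.states.copy(), self.fixed_mask.copy(), self.temperature
        )


@dataclass(frozen=True)
class FieldVector:
    """Local-field decomposition h = hⁿ + h^ext.

    With fixed input neurons the external contribution is carried by the
    rewired couplings, so the split is bookkeeping; with a global field the
    external part is (w_ext/p)·ξᵉ applied to every neuron.
    """

    native_part: np.ndarray
    external_part: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.native_part + self.external_part


@dataclass
class TrajectorySummary:
    """Per-iteration order parameters of one run.

    ``overlaps_native`` has shape (n_iterations, p); ``overlap_new`` and
    ``flip_fraction`` have length n_iterations.  Flip fraction counts only
    non-clamped neurons.
    """

    overlaps_native: np.ndarray
    overlap_new: np.ndarray
    flip_fraction: np.ndarray
    final_state: NetworkState | None = None

    def final_overlaps(self, tail: int = 10) -> tuple[np.ndarray, float]:
        """Mean over the last ``tail`` iterations of (native overlaps, new
        overlap) — suppresses single-step noise in sweep endpoints."""
        t = min(tail, len(self.overlap_new))
        return (
            self.overlaps_native[-t:].mean(axis=0),
            float(self.overlap_new[-t:].mean()),
        )


def random_state(
    n_neurons: int,
    temperature: float,
    rng: np.random.Generator,
    patterns: PatternSet | None = None,
    *,
    clamp_pattern: np.ndarray | None = None,
) -> NetworkState:
    """Uniform random ±1 initial state; if ``patterns`` is given, neurons in
    N' are clamped to ξᵉ (or to ``clamp_pattern`` when provided)."""
    states = rng.choice((-1, 1), size=n_neurons).astype(np.int8)
    fixed = np.zeros(n_neurons, dtype=bool)
    if patterns is not None and patterns.input_set.size:
        fixed[patterns.input_set] = True
        src = patterns.new if clamp_pattern is None else clamp_pattern
        states[patterns.input_set] = src[patterns.input_set]
    return NetworkState(states, fixed, temperature)


def local_fields(
    network: CoupledNetwork,
    state: NetworkState,
    field_mode: str = "none",
    field_params: tuple[float, np.ndarray] | None = None,
    *,
    n_patterns: int = 1,
) -> FieldVector:
    """Compute h_i = (1/k) Σ_{j→i} J_ij S_j, optionally adding a uniform
    global drive h_i += (w_ext/p)·ξᵉ_i in mode ``"global"``.

    Mode ``"fixed_neurons"`` is identical to ``"none"`` at this level: the
    frozen sources already contribute through the rewired couplings.
    """
    if field_mode not in FIELD_MODES:
        raise ValueError(f"unknown field_mode {field_mode!r}; use one of {FIELD_MODES}")
    if state.states.size != network.n_neurons:
        raise ValueError("state length does not match network size")

    s = state.states.astype(np.float64)
    native = network.weights.dot(s) / network.in_degree
    if field_mode == "global":
        if field_params is None:
            raise ValueError("mode 'global' requires field_params=(w_ext, xi_e)")
        w_ext, xi_e = field_params
        # the drive shares the 1/p scale of the stored couplings
        external = (w_ext / n_patterns) * np.asarray(xi_e, dtype=np.float64)
    else:
        external = np.zeros_like(native)
    return FieldVector(native_part=native, external_part=external)


def step(
    state: NetworkState,
    fields: FieldVector,
    rng: np.random.Generator,
    *,
    schedule: str = "synchronous",
) -> NetworkState:
    """One sweep of heat-bath updates over all non-clamped neurons.

    With probability P = 1/(1+exp(−2β|h_i|)) neuron i aligns with sgn(h_i),
    otherwise it takes −sgn(h_i).  At zero field the heat-bath distribution
    is uniform, so the new state is a fair coin at T > 0; in the
    deterministic T = 0 limit a zero field keeps the current state (no
    information to align with).  ``schedule="asynchronous"`` performs one
    random-sequential sweep instead (sensitivity checks only).
    """
    h = fields.total
    new = state.states.copy()
    free = ~state.fixed_mask

    if schedule == "synchronous":
        _heat_bath(new, h, state, free, rng)
    elif schedule == "asynchronous":
        order = rng.permutation(np.flatnonzero(free))
        # fields are recomputed by the caller per sweep; within the sweep we
        # use the fields as passed — callers wanting exact async must step
        # neuron by neuron
        for i in order:
            _heat_bath_single(new, h, state, int(i), rng)
    else:
        raise ValueError(f"unknown schedule {schedule!r}")

    return NetworkState(new, state.fixed_mask, state.temperature)


def _heat_bath(new, h, state, free, rng):
    hf = h[free]
    sgn = np.sign(hf).astype(np.int8)
    cur = state.states[free]
    if state.temperature == 0:
        new[free] = np.where(sgn == 0, cur, sgn).astype(np.int8)
        return
    # zero field: alignment target is a fair coin (p_align is 1/2 there,
    # so aligned and misaligned branches are both uniform)
    coin = rng.choice((-1, 1), size=hf.size).astype(np.int8)
    target = np.where(sgn == 0, coin, sgn).astype(np.int8)
    p_align = 1.0 / (1.0 + np.exp(-2.0 * state.beta * np.abs(hf)))
    aligned = rng.random(hf.size) < p_align
    new[free] = np.where(aligned, target, -target)


def _heat_bath_single(new, h, state, i, rng):
    sgn = int(np.sign(h[i]))
    if sgn == 0:
        if state.temperature > 0:
            new[i] = rng.choice((-1, 1))
        return
    if state.temperature == 0:
        new[i] = sgn
        return
    p_align = 1.0 / (1.0 + np.exp(-2.0 * state.beta * abs(h[i])))
    new[i] = sgn if rng.random() < p_align else -sgn


def overlap(
    state: NetworkState | np.ndarray,
    pattern: np.ndarray,
    excluded: np.ndarray | None = None,
) -> float:
    """Order parameter m = |⟨ξ_i S_i⟩| over neurons outside ``excluded``.

    1 means perfect recall (of the pattern or its global flip); ≈0 means no
    relation.  Input neurons are excluded from every overlap the protocols
    report, since their states are clamped by construction.
    """
    s = state.states if isinstance(state, NetworkState) else np.asarray(state)
    keep = np.ones(s.size, dtype=bool)
    if excluded is not None and np.size(excluded) > 0:
        keep[np.asarray(excluded)] = False
    if not keep.any():
        raise ValueError("cannot exclude every neuron from the overlap")
    return float(
        abs(np.mean(pattern[keep].astype(np.float64) * s[keep].astype(np.float64)))
    )


def evolve(
    network: CoupledNetwork,
    state: NetworkState,
    n_iterations: int,
    patterns: PatternSet,
    rng: np.random.Generator,
    field_mode: str = "none",
    field_params: tuple[float, np.ndarray] | None = None,
    *,
    schedule: str = "synchronous",
) -> TrajectorySummary:
    """Run ``n_iterations`` sweeps, recording per-iteration overlaps with
    every native memory and with the new configuration, plus the fraction of
    non-clamped neurons that changed state."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    excl = patterns.input_set
    p = patterns.p
    m_native = np.empty((n_iterations, p))
    m_new = np.empty(n_iterations)
    flips = np.empty(n_iterations)
    n_free = max(state.n_free, 1)

    cur = state
    for t in range(n_iterations):
        fields = local_fields(network, cur, field_mode, field_params, n_patterns=p)
        nxt = step(cur, fields, rng, schedule=schedule)
        flips[t] = (
            (nxt.states != cur.states)[~cur.fixed_mask].sum() / n_free
        )
        for mu in range(p):
            m_native[t, mu] = overlap(nxt, patterns.native[mu], excl)
        m_new[t] = overlap(nxt, patterns.new, excl)
        cur = nxt

    return TrajectorySummary(
        overlaps_native=m_native,
        overlap_new=m_new,
        flip_fraction=flips,
        final_state=cur,
    )
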