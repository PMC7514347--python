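"""Network construction: directed small-world topology, memory embedding,
and external-input wiring.

The coupling convention throughout the package is row = target: entry
``J[i, j]`` is the weight of the directed edge j → i, so the local field of
neuron i is ``(J @ S)[i] / k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Topology",
    "PatternSet",
    "CoupledNetwork",
    "build_small_world",
    "make_patterns",
    "embed_native",
    "wire_input",
]


@dataclass(frozen=True)
class Topology:
    """Directed graph with fixed in-degree.

    ``sources`` has shape ``(n_neurons, in_degree)``: row i lists the
    presynaptic neurons of i.  With ``rewire_prob = 0`` row i is exactly the
    ring neighborhood of i (``ceil(k/2)`` clockwise, ``floor(k/2)``
    counter-clockwise).
    """

    n_neurons: int
    in_degree: int
    rewire_prob: float
    sources: np.ndarray  # (N, k) int array, row i = predecessors of i
    seed: int | None = None

    @property
    def n_edges(self) -> int:
        return self.sources.size

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (targets, sources) as flat aligned arrays, one entry per edge."""
        tgt = np.repeat(np.arange(self.n_neurons), self.in_degree)
        return tgt, self.sources.ravel()

    def edges(self) -> set[tuple[int, int]]:
        """Set of (source, target) pairs. O(N k); intended for small graphs."""
        tgt, src = self.edge_arrays()
        return set(zip(src.tolist(), tgt.tolist()))


@dataclass(frozen=True)
class PatternSet:
    """Random ±1 memories: ``native`` holds p stored patterns (p, N); ``new``
    is the single incoming configuration; ``input_set`` is the subset N' of
    neurons that relay it."""

    native: np.ndarray  # (p, N) in {-1, +1}
    new: np.ndarray  # (N,) in {-1, +1}
    input_set: np.ndarray  # sorted unique indices into 0..N-1

    def __post_init__(self):
        if self.native.ndim != 2 or self.native.shape[0] < 1:
            raise ValueError("need at least one native pattern")
        for arr in (self.native, self.new):
            if not np.isin(arr, (-1, 1)).all():
                raise ValueError("pattern entries must be ±1")
        if self.input_set.size != np.unique(self.input_set).size:
            raise ValueError("input_set indices must be distinct")
        n = self.native.shape[1]
        if self.input_set.size and (
            self.input_set.min() < 0 or self.input_set.max() >= n
        ):
            raise ValueError("input_set index out of range")

    @property
    def p(self) -> int:
        return self.native.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.native.shape[1]

    def loading(self, mean_in_degree: float) -> float:
        """Memory loading α = p / ⟨k⟩."""
        return self.p / mean_in_degree

    def input_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_neurons, dtype=bool)
        mask[self.input_set] = True
        return mask


@dataclass
class CoupledNetwork:
    """Topology plus the weighted coupling matrix J (CSR, row = target)."""

    topology: Topology
    weights: sp.csr_matrix
    input_sources: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.intp)
    )

    @property
    def n_neurons(self) -> int:
        return self.topology.n_neurons

    @property
    def in_degree(self) -> int:
        return self.topology.in_degree

    def copy(self) -> "CoupledNetwork":
        return CoupledNetwork(
            self.topology, self.weights.copy(), self.input_sources.copy()
        )

    def weight_of(self, source: int, target: int) -> float:
        return self.weights[target, source]


def _ring_offsets(k: int) -> np.ndarray:
    """Signed ring offsets: ceil(k/2) clockwise (+1, +2, ...), floor(k/2)
    counter-clockwise (-1, -2, ...)."""
    n_cw = (k + 1) // 2
    n_ccw = k // 2
    return np.concatenate(
        [np.arange(1, n_cw + 1), -np.arange(1, n_ccw + 1)]
    )


def lattice_sources(n_neurons: int, in_degree: int) -> np.ndarray:
    """Predecessor table of the pure ring lattice (rewire_prob = 0)."""
    offsets = _ring_offsets(in_degree)
    idx = np.arange(n_neurons)[:, None] + offsets[None, :]
    return np.mod(idx, n_neurons)


def build_small_world(
    n_neurons: int,
    in_degree: int,
    rewire_prob: float,
    seed: int | np.random.Generator | None = None,
) -> Topology:
    """Directed Watts–Strogatz variant preserving in-degree.

    Start from a ring lattice in which every neuron receives from its
    ``in_degree`` nearest ring neighbors; each incoming edge independently has
    its SOURCE replaced, with probability ``rewire_prob``, by a uniformly
    random neuron that is neither the target itself nor already a source of
    that target.  Rewiring therefore never changes any node's in-degree,
    which the 1/k field normalization presumes.
    """
    if not 0 < in_degree < n_neurons:
        raise ValueError(
            f"in_degree must satisfy 0 < k < N, got k={in_degree}, N={n_neurons}"
        )
    if not 0.0 <= rewire_prob <= 1.0:
        raise ValueError(f"rewire_prob must be in [0, 1], got {rewire_prob}")

    rng = np.random.default_rng(seed)
    sources = lattice_sources(n_neurons, in_degree)

    if rewire_prob > 0.0:
        rewire = rng.random(sources.shape) < rewire_prob
        for i in np.flatnonzero(rewire.any(axis=1)):
            row = sources[i]
            slots = np.flatnonzero(rewire[i])
            taken = set(row.tolist())
            taken.add(i)
            for s in slots:
                taken.discard(int(row[s]))
                while True:
                    cand = int(rng.integers(n_neurons))
                    if cand not in taken:
                        break
                row[s] = cand
                taken.add(cand)

    return Topology(
        n_neurons=n_neurons,
        in_degree=in_degree,
        rewire_prob=rewire_prob,
        sources=sources,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def make_patterns(
    n_neurons: int,
    p: int,
    input_size: int,
    seed: int | np.random.Generator | None = None,
) -> PatternSet:
    """Draw p native patterns and one new pattern, each entry ±1 with
    probability 1/2, plus a uniformly random input subset N' of size
    ``input_size`` (without replacement)."""
    if p < 1:
        raise ValueError(f"need p >= 1 native patterns, got {p}")
    if not 0 <= input_size <= n_neurons:
        raise ValueError(
            f"input_size must be in [0, N], got {input_size} with N={n_neurons}"
        )
    rng = np.random.default_rng(seed)
    native = rng.choice((-1, 1), size=(p, n_neurons)).astype(np.int8)
    new = rng.choice((-1, 1), size=n_neurons).astype(np.int8)
    input_set = np.sort(rng.choice(n_neurons, size=input_size, replace=False))
    return PatternSet(native=native, new=new, input_set=input_set.astype(np.intp))


def _coupling_csr(topology: Topology, data: np.ndarray) -> sp.csr_matrix:
    tgt, src = topology.edge_arrays()
    mat = sp.csr_matrix(
        (data, (tgt, src)), shape=(topology.n_neurons, topology.n_neurons)
    )
    # outer-product weights never cancel to exact zeros that matter, but keep
    # explicit zeros out of the way deterministically
    return mat


def native_weights(
    topology: Topology, native: np.ndarray
) -> np.ndarray:
    """Per-edge outer-product weights J_ij = (1/p) Σ_μ ξ_i,μ ξ_j,μ."""
    tgt, src = topology.edge_arrays()
    p = native.shape[0]
    patt = native.astype(np.float64)
    data = np.zeros(tgt.size)
    for mu in range(p):
        data += patt[mu, tgt] * patt[mu, src]
    return data / p


def embed_native(topology: Topology, patterns: PatternSet) -> CoupledNetwork:
    """Seed the coupling matrix with the native memories via the
    outer-product (Hebbian storage) rule; non-edges carry no weight and
    J_ii = 0 because the topology has no self-edges."""
    if patterns.n_neurons != topology.n_neurons:
        raise ValueError(
            f"pattern length {patterns.n_neurons} != n_neurons {topology.n_neurons}"
        )
    data = native_weights(topology, patterns.native)
    tgt, src = topology.edge_arrays()
    mat = sp.csr_matrix(
        (data, (tgt, src)), shape=(topology.n_neurons, topology.n_neurons)
    )
    return CoupledNetwork(topology=topology, weights=mat)


def wire_input(
    network: CoupledNetwork,
    patterns: PatternSet,
    input_weight: float,
    *,
    input_pattern: np.ndarray | None = None,
) -> CoupledNetwork:
    """Overwrite every existing edge whose source lies in N' with the
    new-state coupling J_ij = (w_e / p) ξᵉ_i ξᵉ_j.

    No edges are created: only pre-existing connections emanating from input
    neurons are modified.  The original network is left untouched.
    ``input_pattern`` overrides ξᵉ (used by recall protocols that clamp the
    input neurons to a native configuration instead).
    """
    if input_weight <= 0:
        raise ValueError(f"input_weight must be positive, got {input_weight}")
    if patterns.input_set.size == 0:
        warnings.warn("empty input_set: wire_input is a no-op", stacklevel=2)
        return network.copy()

    xi = patterns.new if input_pattern is None else input_pattern
    out = network.copy()
    coo = out.weights.tocoo()
    in_mask = patterns.input_mask()
    edge_sel = in_mask[coo.col]
    scale = input_weight / patterns.p
    coo.data[edge_sel] = (
        scale * xi[coo.row[edge_sel]].astype(np.float64) * xi[coo.col[edge_sel]]
    )
    out.weights = coo.tocsr()
    out.input_sources = patterns.input_set.copy()
    return out
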