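import numpy as np
import pytest

from critmem.dynamics import NetworkState, random_state
from critmem.learning import (
    LearningConfig,
    SweepGrid,
    consolidation_time,
    hebbian_step,
    input_degree_overlap,
    protocol_learn_sweep,
    protocol_prelearn_sweep,
    run_learning_phase,
)
from critmem.network import build_small_world, embed_native, make_patterns, wire_input


def _state(states, fixed=None, T=1.0):
    s = np.asarray(states, dtype=np.int8)
    f = np.zeros(s.size, dtype=bool) if fixed is None else np.asarray(fixed)
    return NetworkState(s, f, T)


class TestHebbianStep:
    def test_zero_rate_is_identity(self, small_net):
        net, pats = small_net
        st = random_state(200, 1.0, np.random.default_rng(0), pats)
        out = hebbian_step(net, st, 0.0)
        assert np.array_equal(out.weights.toarray(), net.weights.toarray())

    def test_uniform_state_increments_every_eligible_edge(self, rng):
        topo = build_small_world(50, 6, 0.1, rng)
        pats = make_patterns(50, 1, 0, rng)
        net = embed_native(topo, pats)
        st = _state(np.ones(50))
        out = hebbian_step(net, st, 0.1)
        diff = out.weights.toarray() - net.weights.toarray()
        tgt, src = topo.edge_arrays()
        assert np.allclose(diff[tgt, src], 0.1)

    def test_triangle_hand_application(self, triangle):
        """S = (+,−,+): ΔJ for the edge 2→1 is ε·S₁·S₂ = −0.1 and for
        3→1 is ε·S₁·S₃ = +0.1 (1-based neuron labels)."""
        topo, patterns = triangle
        net = embed_native(topo, patterns)
        st = _state([1, -1, 1])
        out = hebbian_step(net, st, 0.1)
        diff = out.weights.toarray() - net.weights.toarray()
        assert diff[0, 1] == pytest.approx(-0.1)
        assert diff[0, 2] == pytest.approx(+0.1)

    def test_edges_targeting_fixed_neurons_frozen(self, rng):
        topo = build_small_world(60, 6, 0.1, rng)
        pats = make_patterns(60, 1, 10, rng)
        net = wire_input(embed_native(topo, pats), pats, 3.0)
        fixed = pats.input_mask()
        st = _state(rng.choice((-1, 1), 60), fixed=fixed)
        out = hebbian_step(net, st, 0.1)
        diff = out.weights.toarray() - net.weights.toarray()
        assert np.allclose(diff[pats.input_set, :], 0.0)
        # edges sourced at fixed neurons do learn
        free_rows = ~fixed
        assert np.abs(diff[np.ix_(free_rows, fixed)]).sum() > 0

    def test_fixed_source_plasticity_flag(self, rng):
        topo = build_small_world(60, 6, 0.1, rng)
        pats = make_patterns(60, 1, 10, rng)
        net = wire_input(embed_native(topo, pats), pats, 3.0)
        st = _state(rng.choice((-1, 1), 60), fixed=pats.input_mask())
        out = hebbian_step(net, st, 0.1, plastic_fixed_sources=False)
        diff = out.weights.toarray() - net.weights.toarray()
        assert np.allclose(diff[:, pats.input_set], 0.0)


@pytest.fixture(scope="module")
def mini_grid():
    return SweepGrid(
        temperatures=np.array([0.3, 0.8, 1.3, 1.8]),
        realizations=3,
        seed=5,
        n_neurons=300,
        in_degree=12,
    )


class TestProtocols:
    def test_prelearn_cold_recall_hot_disorder(self, mini_grid):
        res = protocol_prelearn_sweep(mini_grid, p=1, input_size=21, input_weight=3.0)
        assert res.overlap_native[0] > 0.5  # ordered, native-dominated
        assert res.overlap_native[-1] < 0.2  # disordered
        assert res.overlap_new[-1] < 0.35

    def test_recall_native_extends_stability(self, mini_grid):
        """Clamping input neurons to the native configuration pushes the
        native overlap up at the transition region."""
        plain = protocol_prelearn_sweep(mini_grid, p=1, input_size=0)
        recall = protocol_prelearn_sweep(
            mini_grid, p=1, input_size=21, input_weight=3.0, recall_native=True
        )
        mid = slice(1, 3)  # around the transition
        assert (
            recall.overlap_native[mid].mean() > plain.overlap_native[mid].mean()
        )

    def test_learning_with_zero_effect_requires_positive_rate(self, mini_grid):
        with pytest.raises(ValueError):
            protocol_learn_sweep(mini_grid, learning_rate=0.0)

    def test_learn_sweep_consolidates_above_transition(self, mini_grid):
        cfg = LearningConfig(phase_lengths=(50, 200, 50))
        res = protocol_learn_sweep(
            mini_grid, p=1, input_size=21, input_weight=3.0,
            learning_rate=0.1, config=cfg,
        )
        d = res.delta_overlap_new()
        # learning raises the new-configuration overlap somewhere hot
        assert d[2:].max() > 0.1
        # and leaves the cold native regime essentially alone
        assert abs(d[0]) < 0.15

    def test_plasticity_off_phases_preserve_weights(self, rng):
        """The relaxation phases never touch a single weight."""
        topo = build_small_world(100, 8, 0.1, rng)
        pats = make_patterns(100, 1, 10, rng)
        net = wire_input(embed_native(topo, pats), pats, 3.0)
        before = net.weights.toarray().copy()
        from critmem.dynamics import evolve

        st = random_state(100, 1.0, rng, pats)
        evolve(net, st, 50, pats, rng)
        assert np.array_equal(net.weights.toarray(), before)

    def test_learning_phase_returns_grown_weights(self, rng):
        topo = build_small_world(100, 8, 0.1, rng)
        pats = make_patterns(100, 1, 10, rng)
        net = wire_input(embed_native(topo, pats), pats, 3.0)
        st = random_state(100, 1.0, rng, pats)
        learned, _, traj, _ = run_learning_phase(net, st, 30, pats, 0.1, rng)
        assert len(traj.overlap_new) == 30
        assert (
            np.abs(learned.weights.toarray()).sum()
            > np.abs(net.weights.toarray()).sum()
        )


class TestGlobalFieldAndRobustness:
    def test_zero_field_reduces_to_plain_system(self):
        """w_ext = 0: native-stable in the cold regime, nothing stable in
        the hot one, and never new-stable."""
        from critmem.learning import protocol_global_field

        grid = SweepGrid(
            temperatures=np.array([0.3, 1.8]), realizations=2, seed=9,
            n_neurons=250, in_degree=12,
        )
        cfg = LearningConfig(phase_lengths=(40, 80, 40))
        df = protocol_global_field(grid, np.array([0.0]), config=cfg)
        cold = df[df["temperature"] == 0.3].iloc[0]
        hot = df[df["temperature"] == 1.8].iloc[0]
        assert cold["classification"] == "native_stable"
        assert hot["classification"] in ("neither", "native_stable")
        assert not (df["classification"] == "new_stable").any()

    def test_strong_field_consolidates_somewhere(self):
        from critmem.learning import protocol_global_field

        grid = SweepGrid(
            temperatures=np.array([1.0, 1.4]), realizations=2, seed=9,
            n_neurons=250, in_degree=12,
        )
        cfg = LearningConfig(phase_lengths=(40, 120, 40))
        df = protocol_global_field(grid, np.array([2.0]), config=cfg)
        assert (df["overlap_new"] > df["overlap_native"]).any()

    def test_input_robustness_zero_size_is_flat(self):
        from critmem.learning import protocol_input_robustness

        grid = SweepGrid(
            temperatures=np.array([0.8, 1.4]), realizations=1, seed=2,
            n_neurons=200, in_degree=10,
        )
        cfg = LearningConfig(phase_lengths=(30, 60, 30))
        df = protocol_input_robustness(
            grid, input_fractions=np.array([0.0, 0.07]),
            input_weights=np.array([3.0]), config=cfg,
        )
        by_frac = df.set_index("input_fraction")["peak_delta_overlap"]
        assert by_frac.loc[0.0] == 0.0
        assert np.isfinite(by_frac.loc[0.07])


class TestInputDegreeOverlap:
    def test_groups_exclude_fixed_and_cover_free(self, small_net, rng):
        net, pats = small_net
        st = random_state(200, 1.0, rng, pats)
        table = input_degree_overlap(net, pats, st)
        assert table["n_neurons"].sum() == 200 - pats.input_set.size
        assert (table["mean_agreement"].abs() <= 1).all()

    def test_aligned_state_gives_full_agreement(self, small_net):
        net, pats = small_net
        st = _state(pats.new, fixed=pats.input_mask())
        table = input_degree_overlap(net, pats, st)
        assert np.allclose(table["mean_agreement"], 1.0)


class TestConsolidationTime:
    def test_censoring_below_transition(self, rng):
        """Deep sub-critical: the native attractor holds, m^e never reaches
        1/2 within the budget."""
        topo = build_small_world(300, 12, 0.1, rng)
        pats = make_patterns(300, 1, 21, rng)
        net = wire_input(embed_native(topo, pats), pats, 3.0)
        t = consolidation_time(net, pats, 0.1, 0.1, 60, rng)
        assert t is None

    def test_consolidates_in_hot_regime(self, rng):
        topo = build_small_world(300, 12, 0.1, rng)
        pats = make_patterns(300, 1, 21, rng)
        net = wire_input(embed_native(topo, pats), pats, 3.0)
        t = consolidation_time(net, pats, 1.6, 0.1, 400, rng)
        assert t is not None and 1 <= t <= 400
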