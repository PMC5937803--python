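"""SPN engine: compilation, firing semantics, simulation contracts."""

import numpy as np
import pytest

from steroflow.engine import (
    CompileError,
    SimulationConfig,
    compile_net,
    knockout,
    simulate,
    stage_mean,
    step,
    summarize,
)
from steroflow.mepn import MepnGraph, NodeKind
from steroflow.schedule import parse_schedule


def gated_chain() -> MepnGraph:
    """Token input -> substrate S; enzyme E gates the process S+E -> P."""
    g = MepnGraph(name="gated-chain")
    g.add_node("S", NodeKind.BIOCHEMICAL)
    g.add_node("E", NodeKind.PROTEIN)
    g.add_node("P", NodeKind.BIOCHEMICAL)
    g.add_node("rxn", NodeKind.PROCESS)
    g.add_node("TI_S", NodeKind.TOKEN_INPUT)
    g.add_node("TI_E", NodeKind.TOKEN_INPUT)
    g.add_edge("TI_S", "S")
    g.add_edge("TI_E", "E")
    g.add_edge("S", "rxn")
    g.add_edge("E", "rxn")
    g.add_edge("rxn", "P")
    return g


class TestCompile:
    def test_process_node_becomes_transition(self):
        net = compile_net(gated_chain())
        assert set(net.places) == {"S", "E", "P"}
        assert len(net.transitions) == 1
        t = net.transitions[0]
        assert set(t.inputs) == {"S", "E"} and t.outputs == ("P",)

    def test_direct_edge_becomes_implicit_transition(self):
        g = MepnGraph()
        g.add_node("A", NodeKind.BIOCHEMICAL)
        g.add_node("B", NodeKind.BIOCHEMICAL)
        g.add_edge("A", "B")
        net = compile_net(g)
        assert len(net.transitions) == 1
        assert net.transitions[0].inputs == ("A",)
        assert net.transitions[0].source.startswith("edge:")

    def test_annotation_nodes_excluded(self):
        g = MepnGraph()
        g.add_node("A", NodeKind.BIOCHEMICAL)
        g.add_node("B", NodeKind.BIOCHEMICAL)
        g.add_node("legend", NodeKind.ANNOTATION)
        g.add_edge("A", "B")
        g.add_edge("legend", "A")
        net = compile_net(g)
        assert "legend" not in net.places
        assert all("legend" not in t.inputs for t in net.transitions)

    def test_invalid_graph_refuses_to_compile(self):
        g = MepnGraph()
        g.add_node("s", NodeKind.BIOCHEMICAL)
        g.add_node("p", NodeKind.PROCESS)
        g.add_edge("s", "p")  # process without output
        with pytest.raises(CompileError, match="p"):
            compile_net(g)

    def test_compilation_is_deterministic(self, leydig_graph):
        assert compile_net(leydig_graph) == compile_net(leydig_graph)


class TestStep:
    def test_zero_state_is_fixed_point(self):
        net = compile_net(gated_chain())
        state = {p: 0.0 for p in net.places}
        cfg = SimulationConfig(noise_sigma=0.0, n_runs=1)
        assert step(state, {}, 1, net, cfg) == state

    def test_min_rule_consumes_both_inputs(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(noise_sigma=0.0, n_runs=1)
        new = step({"S": 10.0, "E": 5.0, "P": 0.0}, {}, 1, net, cfg)
        assert new == {"S": 5.0, "E": 0.0, "P": 5.0}

    def test_overdemand_split_proportionally(self):
        g = MepnGraph()
        for n in "ABC":
            g.add_node(n, NodeKind.BIOCHEMICAL)
        g.add_edge("A", "B")
        g.add_edge("A", "C")
        net = compile_net(g)
        cfg = SimulationConfig(noise_sigma=0.0, n_runs=1)
        new = step({"A": 6.0, "B": 0.0, "C": 0.0}, {}, 1, net, cfg)
        assert new == {"A": 0.0, "B": 3.0, "C": 3.0}

    def test_negative_state_rejected(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(noise_sigma=0.0, n_runs=1)
        with pytest.raises(ValueError, match="negative"):
            step({"S": -1.0}, {}, 1, net, cfg)

    def test_non_consumptive_preserves_inputs(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(noise_sigma=0.0, n_runs=1, consumptive=False)
        new = step({"S": 10.0, "E": 5.0, "P": 0.0}, {}, 1, net, cfg)
        assert new == {"S": 10.0, "E": 5.0, "P": 5.0}


GATED_SCHEDULES = {"S": parse_schedule("1-100,10"), "E": parse_schedule("1-100,5")}


class TestSimulate:
    def test_gated_chain_closed_form(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(n_blocks=100, n_runs=1, noise_sigma=0.0)
        trace = simulate(net, GATED_SCHEDULES, cfg)
        p = trace.of("P")[0]
        np.testing.assert_array_equal(p, 5.0 * np.arange(1, 101))
        assert p[-1] == 500.0

    def test_sigma_zero_variance_identically_zero(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(n_blocks=30, n_runs=10, noise_sigma=0.0)
        trace = simulate(net, GATED_SCHEDULES, cfg)
        assert trace.variance.max() == 0.0

    def test_noisy_mean_tracks_noise_free_trace(self):
        """Noise enters injections unbiasedly: the time-averaged product
        trace over 500 replicates matches the noise-free trace to 3 SE."""
        net = compile_net(gated_chain())
        noisy = simulate(
            net, GATED_SCHEDULES,
            SimulationConfig(n_blocks=100, n_runs=500, noise_sigma=0.1, seed=3),
        )
        exact = simulate(
            net, GATED_SCHEDULES,
            SimulationConfig(n_blocks=100, n_runs=1, noise_sigma=0.0),
        )
        per_run_avg = noisy.of("P").mean(axis=1)
        se = per_run_avg.std(ddof=1) / np.sqrt(500)
        assert abs(per_run_avg.mean() - exact.of("P")[0].mean()) <= 3 * se

    def test_identical_seed_bit_identical(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(n_blocks=50, n_runs=20, noise_sigma=0.1, seed=11)
        a = simulate(net, GATED_SCHEDULES, cfg)
        b = simulate(net, GATED_SCHEDULES, cfg)
        assert np.array_equal(a.tokens, b.tokens)

    def test_unknown_place_rejected_before_running(self):
        net = compile_net(gated_chain())
        with pytest.raises(KeyError, match="nonexistent"):
            simulate(net, {"nonexistent": parse_schedule("1-5,1")})

    def test_tokens_never_negative(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(n_blocks=60, n_runs=50, noise_sigma=0.5, seed=2)
        trace = simulate(net, GATED_SCHEDULES, cfg)
        assert trace.tokens.min() >= 0.0

    def test_monotone_gating(self):
        """Raising the enzyme's injection never lowers the downstream mean."""
        net = compile_net(gated_chain())
        cfg = SimulationConfig(n_blocks=50, n_runs=1, noise_sigma=0.0)
        lo = simulate(net, {**GATED_SCHEDULES, "E": parse_schedule("1-100,2")}, cfg)
        hi = simulate(net, {**GATED_SCHEDULES, "E": parse_schedule("1-100,4")}, cfg)
        assert np.all(hi.of("P")[0] >= lo.of("P")[0])


class TestKnockout:
    def test_removes_only_target(self):
        schedules = dict(GATED_SCHEDULES)
        ko = knockout(schedules, "E")
        assert "E" not in ko and ko["S"] is schedules["S"]
        assert "E" in schedules  # input untouched

    def test_missing_target_raises(self):
        with pytest.raises(KeyError, match="no token input to remove"):
            knockout(GATED_SCHEDULES, "P")

    def test_gated_product_is_zero_after_knockout(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(n_blocks=40, n_runs=5, noise_sigma=0.1, seed=9)
        trace = simulate(net, knockout(GATED_SCHEDULES, "E"), cfg)
        assert np.all(trace.of("P") == 0.0)

    def test_restoring_schedule_restores_trace(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(n_blocks=40, n_runs=5, noise_sigma=0.1, seed=9)
        restored = dict(knockout(GATED_SCHEDULES, "E"))
        restored["E"] = GATED_SCHEDULES["E"]
        a = simulate(net, GATED_SCHEDULES, cfg)
        b = simulate(net, restored, cfg)
        assert np.array_equal(a.tokens, b.tokens)


class TestSummaries:
    def test_single_run_summary(self):
        net = compile_net(gated_chain())
        cfg = SimulationConfig(n_blocks=10, n_runs=1, noise_sigma=0.0)
        trace = simulate(net, GATED_SCHEDULES, cfg)
        table = summarize(trace, ["P"])
        assert list(table.columns) == ["place", "block", "mean", "variance"]
        assert (table["variance"] == 0).all()
        assert table["mean"].tolist() == trace.of("P")[0].tolist()

    def test_sample_variance_convention(self):
        from steroflow.engine import TokenTrace

        tokens = np.zeros((2, 1, 1))
        tokens[0, 0, 0], tokens[1, 0, 0] = 4.0, 6.0
        trace = TokenTrace(("x",), tokens, SimulationConfig(n_blocks=1, n_runs=2))
        table = summarize(trace)
        assert table["mean"].iloc[0] == 5.0
        assert table["variance"].iloc[0] == 2.0  # sample (ddof=1)

    def test_unknown_place_error_lists_known(self):
        net = compile_net(gated_chain())
        trace = simulate(
            net, GATED_SCHEDULES, SimulationConfig(n_blocks=5, n_runs=1, noise_sigma=0)
        )
        with pytest.raises(KeyError, match="known places"):
            summarize(trace, ["Q"])

    def test_stage_mean_window(self):
        net = compile_net(gated_chain())
        trace = simulate(
            net, GATED_SCHEDULES,
            SimulationConfig(n_blocks=100, n_runs=1, noise_sigma=0),
        )
        # P(t) = 5t, so the mean over blocks 51..100 is 5 * 75.5
        assert stage_mean(trace, "P", 51, 100) == pytest.approx(5 * 75.5)
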