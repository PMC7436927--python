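import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gencirc.engine import (
    Assignment,
    CircuitNetlist,
    EngineConfig,
    GateNode,
    TruthTable,
    assign_gates,
    boolean_truth_table,
    circuit_score,
    enumerate_states,
    predict_all_states,
    predict_distribution,
    predict_state,
    synthesize_nor,
    total_flux_report,
)
from gencirc.library import GateLibrary
from gencirc.quantitation import hill_response
from gencirc.simulate import gen_fixture_circuits


class TestTruthTable:
    def test_hex_row_order_is_msb_first(self):
        t = TruthTable.from_hex("0xF1", 3)
        assert t.outputs == (1, 1, 1, 1, 0, 0, 0, 1)

    def test_hex_round_trip(self):
        t = TruthTable.from_hex("0x0B", 3)
        assert t.hex() == "0x0B"

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValueError):
            TruthTable.from_hex("0x10", 1)


class TestEnumerateStates:
    @pytest.mark.parametrize("n, count", [(1, 2), (2, 4), (3, 8)])
    def test_counts(self, n, count):
        states = enumerate_states(n)
        assert len(states) == count
        assert states[0] == (0,) * n

    def test_binary_counting_order(self):
        assert enumerate_states(2) == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enumerate_states(5)


class TestSynthesis:
    def test_and2_is_not_not_nor(self):
        net = synthesize_nor(TruthTable(2, (0, 0, 0, 1)))
        kinds = sorted(g.kind for g in net.gate_nodes)
        assert kinds == ["NOR", "NOT", "NOT"]
        out = next(g for g in net.gate_nodes if g.id == net.output_node)
        assert out.kind == "NOR"

    def test_single_not(self):
        net = synthesize_nor(TruthTable(1, (1, 0)))
        assert net.n_gates == 1
        assert net.gate_nodes[0].kind == "NOT"

    def test_xor_boolean_equivalence(self):
        t = TruthTable(2, (0, 1, 1, 0))
        assert boolean_truth_table(synthesize_nor(t)).outputs == t.outputs

    def test_constant_table_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            synthesize_nor(TruthTable(2, (1, 1, 1, 1)))

    def test_fan_in_capped_at_two(self):
        for code in range(1, 255):
            net = synthesize_nor(TruthTable.from_hex(code, 3))
            assert all(len(g.inputs) <= 2 for g in net.gate_nodes)

    @given(code=st.integers(1, 254))
    @settings(max_examples=60, deadline=None)
    def test_random_arity3_tables_reproduced(self, code):
        t = TruthTable.from_hex(code, 3)
        assert boolean_truth_table(synthesize_nor(t)).outputs == t.outputs

    def test_deterministic(self):
        t = TruthTable.from_hex("0x68", 3)
        assert synthesize_nor(t) == synthesize_nor(t)


class TestNetlistValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            CircuitNetlist(
                ("x1",),
                (GateNode("g1", "NOT", ("g2",)), GateNode("g2", "NOT", ("g1",))),
                "g1",
            )

    def test_unreachable_gate_rejected(self):
        with pytest.raises(ValueError, match="output"):
            CircuitNetlist(
                ("x1",),
                (GateNode("g1", "NOT", ("x1",)), GateNode("g2", "NOT", ("x1",))),
                "g1",
            )


@pytest.fixture()
def not_gate_net(lib):
    return synthesize_nor(TruthTable(1, (1, 0))).with_sensors(("P_Tac",))


class TestPredictState:
    def test_not_gate_on_state(self, lib, not_gate_net):
        asg = Assignment({"g1": "PhlF"})
        p = predict_state(not_gate_net, asg, lib, (1,))
        # sensor ON at 4.20 drives the gate deep into repression
        assert p.node_outputs["P_Tac"] == 4.20
        expected = hill_response(lib.gate("P1_PhlF").response, 4.20)
        assert p.output == pytest.approx(expected)
        assert p.output == pytest.approx(0.0117, abs=2e-4)

    def test_not_gate_off_state_near_ymax(self, lib, not_gate_net):
        asg = Assignment({"g1": "PhlF"})
        p = predict_state(not_gate_net, asg, lib, (0,))
        assert p.node_outputs["P_Tac"] == 0.02
        assert p.output == pytest.approx(5.12, rel=0.05)

    def test_split_sums_inputs_and_tandem_alpha1_matches(self, lib):
        net = synthesize_nor(TruthTable(2, (1, 0, 0, 0))).with_sensors(
            ("P_Tac", "P_Tet")
        )
        asg = Assignment({net.output_node: "PhlF"})
        split = predict_state(net, asg, lib, (0, 0), EngineConfig("split"))
        # both inputs OFF: x_eff = 0.02 + 0.02
        assert split.total_flux == pytest.approx(0.04 + 0.04)
        tandem = predict_state(net, asg, lib, (0, 0), EngineConfig("tandem", 1.0))
        assert tandem.output == pytest.approx(split.output)

    def test_tandem_attenuation_reduces_effective_input(self, lib):
        net = synthesize_nor(TruthTable(2, (1, 0, 0, 0))).with_sensors(
            ("P_Tac", "P_Tet")
        )
        asg = Assignment({net.output_node: "PhlF"})
        full = predict_state(net, asg, lib, (1, 1), EngineConfig("tandem", 1.0))
        half = predict_state(net, asg, lib, (1, 1), EngineConfig("tandem", 0.5))
        assert half.output > full.output  # weaker repression with attenuated input

    def test_missing_repressor_rejected(self, lib, not_gate_net):
        with pytest.raises(KeyError):
            predict_state(not_gate_net, Assignment({"g1": "NoSuchRep"}), lib, (0,))

    def test_single_not_flux_accounting(self, lib, not_gate_net):
        asg = Assignment({"g1": "PhlF"})
        p = predict_state(not_gate_net, asg, lib, (1,))
        # gate input 4.20 plus sensor output 4.20
        assert p.total_flux == pytest.approx(8.40)


class TestScoreAndAssignment:
    def test_score_arithmetic(self):
        t = TruthTable(2, (0, 0, 1, 1))
        preds = []
        outs = {(0, 0): 0.1, (0, 1): 0.2, (1, 0): 2.0, (1, 1): 4.0}
        for s, o in outs.items():
            preds.append(
                predict_fake(state=s, output=o)
            )
        assert circuit_score(preds, t) == pytest.approx(10.0)

    def test_equal_levels_score_one(self):
        t = TruthTable(1, (0, 1))
        preds = [predict_fake((0,), 1.0), predict_fake((1,), 1.0)]
        assert circuit_score(preds, t) == pytest.approx(1.0)

    def test_three_gate_netlist_examines_120_assignments(self, lib):
        net = synthesize_nor(TruthTable(2, (0, 0, 0, 1))).with_sensors(
            ("P_Tac", "P_Tet")
        )
        res = assign_gates(net, lib)
        assert res.n_examined == 120  # 6 * 5 * 4

    def test_single_not_winner_maximizes_on_off_ratio(self, lib, not_gate_net):
        res = assign_gates(not_gate_net, lib)
        scores = {}
        for rep in lib.repressors:
            p = lib.gate_by_repressor(rep).response
            scores[rep] = hill_response(p, 0.02) / hill_response(p, 4.20)
        best = max(sorted(scores), key=lambda r: scores[r])
        assert res.assignment.mapping["g1"] == best
        assert res.score == pytest.approx(scores[best])

    def test_neutral_growth_means_cutoff_inactive(self, lib, not_gate_net):
        res0 = assign_gates(not_gate_net, lib, EngineConfig(growth_cutoff=0.0))
        res75 = assign_gates(not_gate_net, lib, EngineConfig(growth_cutoff=0.75))
        assert res0.assignment == res75.assignment
        assert not res75.growth_infeasible

    def test_more_gates_than_repressors_rejected(self, lib):
        small = GateLibrary(gates=lib.gates[:1], sensors=lib.sensors)
        net = synthesize_nor(TruthTable(2, (0, 0, 0, 1))).with_sensors(
            ("P_Tac", "P_Tet")
        )
        with pytest.raises(ValueError, match="repressors"):
            assign_gates(net, small)

    def test_score_matches_per_state_reevaluation(self, lib):
        net = synthesize_nor(TruthTable(2, (0, 0, 0, 1))).with_sensors(
            ("P_Tac", "P_Tet")
        )
        res = assign_gates(net, lib)
        redo = [
            predict_state(net, res.assignment, lib, s) for s in enumerate_states(2)
        ]
        assert circuit_score(redo, boolean_truth_table(net)) == pytest.approx(res.score)

    def test_analog_digital_consistency(self, lib):
        # thresholding predicted outputs at the geometric mean of
        # (min ON, max OFF) reproduces the digital table when score > 1
        for name, t in gen_fixture_circuits().items():
            net = synthesize_nor(t)
            if net.n_gates > len(lib.repressors):
                continue
            sensors = tuple(s.name for s in lib.sensors[: t.n_inputs])
            res = assign_gates(net.with_sensors(sensors), lib)
            if res.score <= 1:
                continue
            outs = {p.state: p.output for p in res.predictions}
            on = [outs[s] for s, b in zip(enumerate_states(t.n_inputs), t.outputs) if b]
            off = [outs[s] for s, b in zip(enumerate_states(t.n_inputs), t.outputs) if not b]
            thr = math.sqrt(min(on) * max(off))
            digital = tuple(
                int(outs[s] > thr) for s in enumerate_states(t.n_inputs)
            )
            assert digital == t.outputs, name


def predict_fake(state, output):
    from gencirc.engine import StatePrediction

    return StatePrediction(
        state=state, node_outputs={}, output=output, total_flux=0.0,
        growth_score=1.0, output_repressor="PhlF",
    )


class TestFluxReport:
    def test_unit_columns_consistent(self, lib, not_gate_net):
        res = assign_gates(not_gate_net, lib)
        df = total_flux_report(res.predictions, lib.constants)
        assert np.allclose(df["flux_rpu"], df["flux_rpug"] / 6.33)
        assert np.allclose(df["flux_rnap_per_s"], df["flux_rpug"] * 0.019 * 3.5)

    def test_flux_invariant_to_gate_relabeling(self, lib):
        net = synthesize_nor(TruthTable(2, (0, 0, 0, 1))).with_sensors(
            ("P_Tac", "P_Tet")
        )
        relabeled = CircuitNetlist(
            net.sensor_nodes,
            tuple(
                GateNode("h" + g.id[1:], g.kind,
                         tuple("h" + s[1:] if s.startswith("g") else s for s in g.inputs))
                for g in net.gate_nodes
            ),
            "h" + net.output_node[1:],
        )
        asg1 = Assignment({"g1": "PhlF", "g2": "QacR", "g3": "BetI"})
        asg2 = Assignment({"h1": "PhlF", "h2": "QacR", "h3": "BetI"})
        for s in enumerate_states(2):
            p1 = predict_state(net, asg1, lib, s)
            p2 = predict_state(relabeled, asg2, lib, s)
            assert p1.total_flux == pytest.approx(p2.total_flux)


class TestPredictDistribution:
    def test_zero_cv_is_point_mass(self, lib):
        from gencirc.library import GateLibrary, GateModel

        g = lib.gate("P1_PhlF")
        quiet = GateLibrary(
            gates=(GateModel(g.name, g.repressor, g.response, g.growth, 0.0),),
            sensors=lib.sensors,
        )
        d = predict_distribution(predict_fake((0,), 1.0), quiet)
        assert d.sigma_log == 0.0
        rng = np.random.default_rng(0)
        assert np.all(d.sample(100, rng) == 1.0)

    def test_sampled_median_matches_prediction(self, lib):
        d = predict_distribution(predict_fake((0,), 2.5), lib)
        rng = np.random.default_rng(5)
        assert np.median(d.sample(30_000, rng)) == pytest.approx(2.5, rel=0.02)

    def test_tenfold_states_separable_at_midpoint(self, lib):
        from scipy.stats import lognorm

        lo = predict_distribution(predict_fake((0,), 0.3), lib)
        hi = predict_distribution(predict_fake((1,), 3.0), lib)
        thr = math.sqrt(lo.median * hi.median)
        err = (1 - lognorm(lo.sigma_log, scale=lo.median).cdf(thr)) + lognorm(
            hi.sigma_log, scale=hi.median
        ).cdf(thr)
        assert err < 0.01


class TestMonotonicity:
    def test_raising_ymax_never_lowers_on_output(self, lib, not_gate_net):
        from dataclasses import replace

        from gencirc.library import GateLibrary, HillParams

        asg = Assignment({"g1": "PhlF"})
        base_gate = lib.gate("P1_PhlF")
        base_out = predict_state(not_gate_net, asg, lib, (0,)).output
        p = base_gate.response
        boosted = GateLibrary(
            gates=tuple(
                replace(g, response=HillParams(p.y_max * 2, p.y_min, p.K, p.n))
                if g.name == "P1_PhlF"
                else g
                for g in lib.gates
            ),
            sensors=lib.sensors,
        )
        assert predict_state(not_gate_net, asg, boosted, (0,)).output >= base_out
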