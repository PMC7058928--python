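"""Gate response functions, tandem composition, and circuit evaluation."""

import dataclasses
import random

import pytest
from hypothesis import given, settings, strategies as st

from norcad import (ADDITIVE, INTERFERENCE, Assignment, CircuitNetlist,
                    Node, circuit_score, compose_tandem, evaluate_state,
                    hill_response, roadblock_factor, truth_table_prediction,
                    two_not_circuit)
from norcad.errors import SpecificationError, StructuralError
from norcad.steady_state import INPUT, NOR2, NOT, OUTPUT, StateTable

from conftest import random_circuit, recursive_reference_fluxes


class TestHillResponse:
    def test_unrepressed_limit_is_ymax(self, library):
        g = library.gate("P1-PhlF")
        assert hill_response(g, 0.0) == pytest.approx(6.9)

    def test_half_maximal_at_K(self, library):
        g = library.gate("P1-PhlF")
        # y_min + (y_max - y_min)/2 with the packaged parameters
        assert hill_response(g, g.K) == pytest.approx(3.452)

    def test_fully_repressed_limit_is_ymin(self, library):
        for g in library.gates:
            assert hill_response(g, 1e9) == pytest.approx(g.y_min,
                                                          rel=1e-6)

    def test_negative_input_rejected(self, library):
        with pytest.raises(ValueError):
            hill_response(library.gates[0], -0.1)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(gi=st.integers(0, 17),
       x1=st.floats(min_value=0, max_value=100),
       x2=st.floats(min_value=0, max_value=100))
def test_hill_response_is_monotone_non_increasing(library, gi, x1, x2):
    g = library.gates[gi]
    lo, hi = sorted((x1, x2))
    assert hill_response(g, lo) >= hill_response(g, hi)
    assert g.y_min < hill_response(g, hi) <= g.y_max


class TestRoadblockFactor:
    def test_limits(self, library):
        g = library.gate("P1-PhlF")
        assert roadblock_factor(g, 0.0) == pytest.approx(g.alpha)
        assert roadblock_factor(g, 1e9) == pytest.approx(g.alpha * g.beta,
                                                         rel=1e-6)

    def test_unity_factors_are_inert(self, library):
        g = dataclasses.replace(library.gate("P1-PhlF"), alpha=1.0,
                                beta=1.0)
        for x in (0.0, 0.01, 0.04, 1.0, 50.0):
            assert roadblock_factor(g, x) == pytest.approx(1.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(gi=st.integers(0, 17),
           x1=st.floats(min_value=0, max_value=100),
           x2=st.floats(min_value=0, max_value=100))
    def test_bounded_and_monotone(self, library, gi, x1, x2):
        g = library.gates[gi]
        lo, hi = sorted((x1, x2))
        f_lo, f_hi = roadblock_factor(g, lo), roadblock_factor(g, hi)
        for f in (f_lo, f_hi):
            assert g.alpha * g.beta - 1e-12 <= f <= g.alpha + 1e-12
        assert f_lo >= f_hi - 1e-12


class TestComposeTandem:
    def test_additive_reduction(self):
        assert compose_tandem(0.5, 1.0, 0.3) == pytest.approx(0.8)

    def test_silent_upstream_passes_downstream(self):
        assert compose_tandem(0.0, 0.4, 0.7) == pytest.approx(0.7)

    def test_interference_corrected_sum(self, library):
        # factor of the PhlF promoter at half-maximal repressor input
        f = roadblock_factor(library.gate("P1-PhlF"), 0.04)
        assert f == pytest.approx(0.1166)
        assert compose_tandem(2.0, f, 0.004) == pytest.approx(0.2372)


class TestEvaluateState:
    def test_sensor_passthrough(self, library):
        net = CircuitNetlist(nodes=(
            Node("x1", INPUT, sensor="P_Tac"),
            Node("y", OUTPUT, parents=("x1",))))
        st_on = evaluate_state(net, Assignment({}), library, [1])
        assert st_on.output_flux == pytest.approx(1.686)
        st_off = evaluate_state(net, Assignment({}), library, [0])
        assert st_off.output_flux == pytest.approx(0.008)

    def test_single_not_gate(self, library):
        net = CircuitNetlist(nodes=(
            Node("x1", INPUT, sensor="P_Tac"),
            Node("g1", NOT, parents=("x1",)),
            Node("y", OUTPUT, parents=("g1",))))
        asg = Assignment({"g1": "P1-PhlF"})
        state = evaluate_state(net, asg, library, [1])
        expect = hill_response(library.gate("P1-PhlF"), 1.686)
        assert state.output_flux == pytest.approx(expect, rel=1e-12)

    def test_models_differ_only_through_downstream_occupancy(self, library):
        net, asg = two_not_circuit("A1-AmtR_2", "P1-PhlF")
        for bits in ((0, 0), (1, 0), (0, 1), (1, 1)):
            inter = evaluate_state(net, asg, library, bits, INTERFERENCE)
            add = evaluate_state(net, asg, library, bits, ADDITIVE)
            occ = inter.states["g2"].occupancy_factor
            assert occ < 1  # PhlF roadblocks in every state (alpha 0.22)
            assert inter.output_flux < add.output_flux

    def test_agrees_with_recursive_oracle(self, library):
        rng = random.Random(20240)
        for _ in range(60):
            net, asg = random_circuit(rng, library)
            n = net.n_inputs
            for k in range(2 ** n):
                bits = [(k >> i) & 1 for i in range(n)]
                for model in (ADDITIVE, INTERFERENCE):
                    got = evaluate_state(net, asg, library, bits, model)
                    ref = recursive_reference_fluxes(net, asg, library,
                                                     bits, model)
                    for name, val in ref.items():
                        assert got.states[name].output_flux == \
                            pytest.approx(val, rel=1e-12)

    def test_gate_outputs_stay_in_dynamic_range(self, library):
        rng = random.Random(77)
        for _ in range(20):
            net, asg = random_circuit(rng, library)
            bits = [rng.randint(0, 1) for _ in range(net.n_inputs)]
            state = evaluate_state(net, asg, library, bits)
            for node, gname in asg.node_to_gate.items():
                g = library.gate(gname)
                assert g.y_min < state.states[node].output_flux <= g.y_max

    def test_unity_interference_equals_additive_everywhere(self, library):
        """With alpha = beta = 1 on every record the corrected model
        collapses exactly onto the additive one."""
        unity = dataclasses.replace(
            library,
            gates=tuple(dataclasses.replace(g, alpha=1.0, beta=1.0)
                        for g in library.gates))
        rng = random.Random(5)
        for _ in range(100):
            net, asg = random_circuit(rng, unity)
            bits = [rng.randint(0, 1) for _ in range(net.n_inputs)]
            a = evaluate_state(net, asg, unity, bits, ADDITIVE)
            b = evaluate_state(net, asg, unity, bits, INTERFERENCE)
            for name in a.states:
                assert b.states[name].output_flux == pytest.approx(
                    a.states[name].output_flux, rel=1e-12)

    def test_cycle_rejected(self):
        with pytest.raises(StructuralError):
            CircuitNetlist(nodes=(
                Node("x1", INPUT, sensor="P_Tac"),
                Node("g1", NOT, parents=("g2",)),
                Node("g2", NOT, parents=("g1",)),
                Node("y", OUTPUT, parents=("g1",))))


class TestTruthTablePrediction:
    def test_row_counts(self, library):
        net, asg = two_not_circuit("P1-PhlF", "A1-AmtR_2")
        assert len(truth_table_prediction(net, asg, library).rows) == 4

    def test_nand_logic_low_only_when_both_inputs_high(self, library):
        net, asg = two_not_circuit("P1-PhlF", "A1-AmtR_2")
        table = truth_table_prediction(net, asg, library)
        required = {r.input_bits: r.required for r in table.rows}
        assert required == {(0, 0): "ON", (1, 0): "ON",
                            (0, 1): "ON", (1, 1): "OFF"}
        fluxes = {r.input_bits: r.output_flux for r in table.rows}
        assert max(fluxes[b] for b in [(0, 0), (1, 0), (0, 1)]) > \
            fluxes[(1, 1)]


class TestCircuitScore:
    def test_ratio(self, library):
        net, asg = two_not_circuit("P1-PhlF", "A1-AmtR_2")
        table = truth_table_prediction(net, asg, library)
        on = [r.output_flux for r in table.rows if r.required == "ON"]
        off = [r.output_flux for r in table.rows if r.required == "OFF"]
        assert circuit_score(table) == pytest.approx(min(on) / max(off))

    def test_invariant_to_row_order(self, library):
        net, asg = two_not_circuit("P1-PhlF", "A1-AmtR_2")
        table = truth_table_prediction(net, asg, library)
        shuffled = StateTable(rows=tuple(reversed(table.rows)))
        assert circuit_score(shuffled) == circuit_score(table)

    def test_requires_both_levels(self, library):
        net, asg = two_not_circuit("P1-PhlF", "A1-AmtR_2")
        table = truth_table_prediction(net, asg, library)
        only_on = StateTable(rows=tuple(
            dataclasses.replace(r, required="ON") for r in table.rows))
        with pytest.raises(SpecificationError):
            circuit_score(only_on)
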