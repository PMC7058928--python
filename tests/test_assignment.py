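"""Assignment feasibility, optimization oracles, and construct layout."""

import itertools
import random

import pytest

from norcad import (Assignment, CircuitNetlist, Node, circuit_score,
                    count_feasible_assignments, feasible, layout, optimize,
                    truth_table_prediction)
from norcad.errors import AssignmentError, CapacityError, ValidationError
from norcad.steady_state import INPUT, NOR2, NOT, OUTPUT

from conftest import random_circuit


def chain_netlist(n_gates: int, sensor="P_Tac") -> CircuitNetlist:
    """x1 -> g1 -> g2 -> ... -> y (a NOT-gate cascade)."""
    nodes = [Node("x1", INPUT, sensor=sensor)]
    prev = "x1"
    for i in range(n_gates):
        nodes.append(Node(f"g{i + 1}", NOT, parents=(prev,)))
        prev = f"g{i + 1}"
    nodes.append(Node("y", OUTPUT, parents=(prev,)))
    return CircuitNetlist(nodes=tuple(nodes))


def brute_force_best(netlist, library, gate_pool=None):
    """Independent arg-max over all feasible assignments using the
    reference prediction path (not the compiled scorer)."""
    nodes = sorted(nd.name for nd in netlist.logic_nodes)
    pool = gate_pool if gate_pool is not None else \
        [g.name for g in library.gates]
    best = None
    for combo in itertools.permutations(pool, len(nodes)):
        asg = Assignment(node_to_gate=dict(zip(nodes, combo)))
        ok, _ = feasible(asg, library)
        if not ok:
            continue
        s = circuit_score(truth_table_prediction(netlist, asg, library))
        key = (-s, combo)
        if best is None or key < best[0]:
            best = (key, asg, s)
    return best[1], best[2]


class TestFeasible:
    def test_same_family_twice_infeasible(self, library):
        asg = Assignment({"g1": "P1-PhlF", "g2": "P2-PhlF"})
        ok, why = feasible(asg, library)
        assert not ok and any("PhlF" in w for w in why)

    def test_prohibited_pair_infeasible(self, library):
        asg = Assignment({"g1": "C1-CymR", "g2": "S1-SrpR"})
        ok, why = feasible(asg, library)
        assert not ok and any("CymR:SrpR" in w for w in why)

    def test_distinct_families_feasible(self, library):
        asg = Assignment({"g1": "P1-PhlF", "g2": "A1-AmtR_2",
                          "g3": "V1-VanR"})
        assert feasible(asg, library) == (True, [])

    def test_unknown_gate_raises(self, library):
        with pytest.raises(AssignmentError):
            feasible(Assignment({"g1": "NoSuchGate"}), library)


class TestCounting:
    def test_single_node_counts_gates(self, library):
        assert count_feasible_assignments(1, library) == 18

    def test_prohibited_pair_reduces_count(self, library):
        # 10 families; for 2 nodes: ordered family pairs excluding the
        # prohibited one, weighted by per-family variant counts
        byfam = library.gates_by_family()
        total = 0
        for f1, f2 in itertools.permutations(byfam, 2):
            if {f1, f2} == {"CymR", "SrpR"}:
                continue
            total += len(byfam[f1]) * len(byfam[f2])
        assert count_feasible_assignments(2, library) == total


class TestOptimize:
    def test_single_node_matches_brute_force(self, library):
        net = chain_netlist(1)
        asg, score = optimize(net, library, method="exhaustive")
        ref_asg, ref_score = brute_force_best(net, library)
        assert score == pytest.approx(ref_score, rel=1e-12)
        assert asg.node_to_gate == ref_asg.node_to_gate

    @pytest.mark.parametrize("n_gates", [2, 3])
    def test_small_chains_match_brute_force(self, library, n_gates):
        pool = [g.name for g in library.gates[:8]]
        sub = type(library)(
            gates=tuple(g for g in library.gates if g.name in pool),
            sensors=library.sensors, reporter=library.reporter,
            layout=library.layout)
        net = chain_netlist(n_gates)
        asg, score = optimize(net, sub, method="exhaustive")
        ref_asg, ref_score = brute_force_best(net, sub)
        assert score == pytest.approx(ref_score, rel=1e-12)
        assert asg.node_to_gate == ref_asg.node_to_gate

    def test_anneal_is_reproducible(self, library):
        net = chain_netlist(3)
        a1 = optimize(net, library, method="anneal", seed=42)
        a2 = optimize(net, library, method="anneal", seed=42)
        assert a1[0].node_to_gate == a2[0].node_to_gate
        assert a1[1] == a2[1]

    def test_anneal_never_beats_exhaustive(self, library):
        """On small instances annealing is bounded by the global optimum
        and almost always attains it."""
        net = chain_netlist(2)
        _, exact = optimize(net, library, method="exhaustive")
        hits = 0
        for seed in range(20):
            _, s = optimize(net, library, method="anneal", seed=seed,
                            options={"anneal_steps": 1000})
            assert s <= exact + 1e-9
            if s == pytest.approx(exact, rel=1e-9):
                hits += 1
        assert hits >= 19  # >= 95% of 20 instances

    def test_too_few_families_raises(self, library):
        import dataclasses
        small = dataclasses.replace(
            library, gates=tuple(library.gates[:2]))  # both AmeR + 1
        with pytest.raises(CapacityError):
            optimize(chain_netlist(3), small)

    def test_returned_assignment_is_feasible(self, library):
        rng = random.Random(3)
        for _ in range(5):
            net, _ = random_circuit(rng, library)
            asg, _ = optimize(net, library, method="anneal", seed=7,
                              options={"anneal_steps": 500})
            assert feasible(asg, library)[0]


class TestLayout:
    def test_family_order_enforced(self, library):
        asg = Assignment({"n1": "C1-CymR", "n2": "P1-PhlF",
                          "n3": "A1-AmtR_2"})
        plan = layout(asg, library)
        assert [g for _, g in plan.entries] == \
            ["P1-PhlF", "A1-AmtR_2", "C1-CymR"]
        scars = [s for s, _ in plan.entries] + [plan.closing_scar]
        assert scars == ["A", "B", "D", "C"]

    def test_single_gate_flanked_by_A_and_C(self, library):
        plan = layout(Assignment({"n1": "P1-PhlF"}), library)
        assert plan.entries == (("A", "P1-PhlF"),)
        assert plan.closing_scar == "C"

    def test_empty_assignment_rejected(self, library):
        with pytest.raises(AssignmentError):
            layout(Assignment({}), library)

    def test_invariant_to_map_iteration_order(self, library):
        a = {"n1": "P1-PhlF", "n2": "V1-VanR", "n3": "B1-BM3R1"}
        b = dict(reversed(list(a.items())))
        assert layout(Assignment(a), library) == \
            layout(Assignment(b), library)
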