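"""Model reading/writing: text SOP dialect, SBML-qual, validation."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from qualnet.dynamics import evaluate_boolean
from qualnet.io import (
    ParseError,
    parse_boolean_equations,
    read_sbml_qual,
    validate_network,
    write_boolean_equations,
    write_sbml_qual,
)
from qualnet.model import BooleanNetwork, Literal, NetworkError, UpdateRule
from qualnet.synthetic import GeneratorConfig, generate_network


def truth_tables(net: BooleanNetwork) -> dict:
    """Exhaustive per-rule truth table over each rule's own regulators."""
    tables = {}
    for target, rule in net.rules.items():
        regs = rule.regulators
        tables[target] = {
            corner: evaluate_boolean(rule, dict(zip(regs, corner)))
            for corner in itertools.product((0, 1), repeat=len(regs))
        }
    return tables


class TestTextDialect:
    def test_simple_and_with_inhibition(self):
        net = parse_boolean_equations("C = A & !B")
        assert set(net.inputs) == {"A", "B"}
        assert net.rules["C"].clauses == (
            (Literal("A"), Literal("B", negated=True)),
        )

    def test_inputs_are_rhs_only_nodes(self):
        net = parse_boolean_equations("C = A | B\nD = C")
        assert set(net.inputs) == {"A", "B"}
        assert set(net.rules) == {"C", "D"}
        assert net.rules["D"].regulators == ("C",)

    def test_contradictory_clause_rejected(self):
        with pytest.raises(ParseError, match="both signs"):
            parse_boolean_equations("C = A & !A")

    def test_duplicate_target_rejected(self):
        with pytest.raises(ParseError, match="line 2.*duplicate"):
            parse_boolean_equations("C = A\nC = B")

    def test_syntax_error_carries_line_number(self):
        with pytest.raises(ParseError, match="line 3"):
            parse_boolean_equations("A1 = B\nC = A1\nD = & B")

    def test_parentheses_distribute_to_sop(self):
        net = parse_boolean_equations("D = (A | B) & C")
        assert net.rules["D"].clauses == (
            (Literal("A"), Literal("C")),
            (Literal("B"), Literal("C")),
        )

    def test_distribution_drops_false_conjuncts(self):
        # (A | !B) & B -> A&B | B&!B -> A&B
        net = parse_boolean_equations("D = (A | !B) & B")
        assert net.rules["D"].clauses == ((Literal("A"), Literal("B")),)

    def test_comments_and_blank_lines_ignored(self):
        net = parse_boolean_equations("# header\n\nC = A  # trailing\n")
        assert set(net.inputs) == {"A"}

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_preserves_structure(self, seed):
        net = generate_network(GeneratorConfig(
            n_nodes=14, n_inputs=3, cycle_enrichment=0.4, seed=seed
        ))
        back = parse_boolean_equations(write_boolean_equations(net))
        assert back.nodes == net.nodes
        assert back.inputs == net.inputs
        assert truth_tables(back) == truth_tables(net)

    def test_round_trip_keeps_unreferenced_inputs(self):
        net = BooleanNetwork(
            nodes=("A", "B", "ORPHAN"),
            rules={"B": UpdateRule("B", ((Literal("A"),),))},
        )
        back = parse_boolean_equations(write_boolean_equations(net))
        assert back.nodes == net.nodes
        assert "ORPHAN" in back.inputs


class TestSbmlQual:
    def test_three_node_round_trip_identity(self):
        net = parse_boolean_equations("C = A & !B\nD = C | A")
        back = read_sbml_qual(write_sbml_qual(net))
        assert back.nodes == net.nodes
        assert back.rules == net.rules

    def test_species_without_transition_is_input(self):
        net = parse_boolean_equations("C = A & B")
        back = read_sbml_qual(write_sbml_qual(net))
        assert set(back.inputs) == {"A", "B"}

    def test_random_network_round_trips_with_identical_truth_tables(self):
        net = generate_network(GeneratorConfig(
            n_nodes=15, n_inputs=3, max_clauses_per_rule=3,
            max_literals_per_clause=3, cycle_enrichment=0.5, seed=7,
        ))
        back = read_sbml_qual(write_sbml_qual(net))
        assert set(back.nodes) == set(net.nodes)
        assert set(back.inputs) == set(net.inputs)
        assert truth_tables(back) == truth_tables(net)

    def test_text_and_sbml_agree(self, toy_net):
        via_sbml = read_sbml_qual(write_sbml_qual(toy_net))
        assert truth_tables(via_sbml) == truth_tables(toy_net)

    def test_malformed_xml_rejected(self):
        with pytest.raises(ParseError, match="malformed XML"):
            read_sbml_qual("<sbml><unclosed>")

    def test_multivalued_species_rejected(self):
        doc = write_sbml_qual(parse_boolean_equations("B = A"))
        doc = doc.replace('maxLevel="1"', 'maxLevel="3"', 1)
        with pytest.raises(ParseError, match="maxLevel"):
            read_sbml_qual(doc)

    def test_general_mathml_normalized_to_sop(self):
        # not(or(A, B)) is not SOP as written; reader must normalize it
        doc = write_sbml_qual(parse_boolean_equations("C = !A & !B"))
        net = read_sbml_qual(doc)
        assert net.rules["C"].clauses == (
            (Literal("A", True), Literal("B", True)),
        )


class TestValidation:
    def test_unreachable_node_flagged(self):
        net = BooleanNetwork(
            nodes=("A", "B", "E", "F"),
            rules={
                "B": UpdateRule("B", ((Literal("A"),),)),
                # E and F feed each other but no input reaches them
                "E": UpdateRule("E", ((Literal("F"),),)),
                "F": UpdateRule("F", ((Literal("E"),),)),
            },
        )
        report = validate_network(net)
        assert set(report.unreachable) == {"E", "F"}

    def test_clean_network_gives_empty_report(self, toy_net):
        assert validate_network(toy_net).is_empty()

    def test_self_loop_only_rule_flagged(self):
        net = parse_boolean_equations("X = X\nY = A")
        assert validate_network(net).self_loop_only == ["X"]

    @pytest.mark.parametrize("seed", range(5))
    def test_reachability_agrees_with_bfs_oracle(self, seed):
        import networkx as nx

        net = generate_network(GeneratorConfig(
            n_nodes=20, n_inputs=4, cycle_enrichment=0.5, seed=seed
        ))
        report = validate_network(net)
        g = nx.DiGraph()
        g.add_nodes_from(net.nodes)
        for t, rule in net.rules.items():
            g.add_edges_from((r, t) for r in rule.regulators)
        reachable = set(net.inputs)
        for inp in net.inputs:
            reachable |= nx.descendants(g, inp)
        assert set(report.unreachable) == set(net.nodes) - reachable


class TestNetworkInvariants:
    def test_duplicate_nodes_rejected(self):
        with pytest.raises(NetworkError, match="duplicate"):
            BooleanNetwork(nodes=("A", "A"))

    def test_whitespace_identifier_rejected(self):
        with pytest.raises(NetworkError, match="invalid node"):
            BooleanNetwork(nodes=("A B",))

    def test_unknown_regulator_rejected(self):
        with pytest.raises(NetworkError, match="unknown nodes"):
            BooleanNetwork(
                nodes=("A",),
                rules={"A": UpdateRule("A", ((Literal("GHOST"),),))},
            )

    def test_inputs_and_rule_targets_partition_nodes(self, toy_net):
        assert set(toy_net.inputs) | set(toy_net.rules) == set(toy_net.nodes)
        assert not set(toy_net.inputs) & set(toy_net.rules)
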