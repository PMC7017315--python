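"""Model/scenario parsing, serialization and the packaged CRC fixture."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from squadron import (
    ACTIVATION,
    INHIBITION,
    Edge,
    GeneratorConfig,
    ModelValidationError,
    NetworkModel,
    Node,
    NodeCategory,
    ParseError,
    parse_model,
    parse_scenarios,
    random_signed_network,
    serialize_model,
    serialize_scenarios,
)
from squadron.crc import READOUT_NODES, SCENARIO_NAMES


class TestSignedSif:
    def test_single_edge_line_with_defaults(self):
        model = parse_model("A\t+\tB", format="signed_sif")
        assert set(model.nodes) == {"A", "B"}
        assert model.edges == [Edge("A", "B", ACTIVATION, 1.0)]
        assert model.nodes["A"].gain == 10.0
        assert model.nodes["A"].decay == 1.0

    def test_node_declarations_without_edges(self):
        text = "NODE\tA\tsignaling\nNODE\tB\tphenotype\n"
        model = parse_model(text, format="signed_sif")
        assert set(model.nodes) == {"A", "B"}
        assert model.edges == []
        assert model.nodes["B"].category is NodeCategory.PHENOTYPE

    def test_names_with_parentheses_and_asterisks(self):
        model = parse_model("(EGFR)*\t-\tRAS stuff\t2.5", format="signed_sif")
        assert "(EGFR)*" in model.nodes
        assert model.edges[0].sign == INHIBITION
        assert model.edges[0].weight == 2.5

    def test_comments_and_blank_lines_ignored(self):
        model = parse_model("# header\n\nA\t+\tB\n", format="signed_sif")
        assert len(model.edges) == 1

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("A\t+\t", "line 1"),
            ("A\t*\tB", "sign"),
            ("NODE\tA\tnot-a-category", "category"),
            ("NODE\tA\tsignaling\t-1\t1", "gain"),
            ("A\t+\tB\t0", "weight"),
        ],
    )
    def test_malformed_lines_raise_with_position(self, text, fragment):
        with pytest.raises(ParseError, match=fragment):
            parse_model(text, format="signed_sif")


class TestJson:
    def test_missing_top_level_key(self):
        with pytest.raises(ParseError, match="edges"):
            parse_model('{"nodes": []}', format="json")

    def test_unknown_edge_endpoint(self):
        text = '{"nodes": [{"name": "A"}], "edges": [{"source": "A", "target": "Z"}]}'
        with pytest.raises(ModelValidationError, match="Z"):
            parse_model(text, format="json")

    def test_defaults_applied(self):
        text = '{"nodes": [{"name": "A"}], "edges": []}'
        model = parse_model(text, format="json")
        node = model.nodes["A"]
        assert (node.gain, node.decay) == (10.0, 1.0)
        assert node.category is NodeCategory.SIGNALING


@settings(deadline=None, max_examples=25, suppress_health_check=[HealthCheck.too_slow])
@given(seed=st.integers(0, 10_000), fmt=st.sampled_from(["signed_sif", "json"]))
def test_round_trip_identity_on_random_models(seed, fmt):
    """parse(serialize(M)) == M structurally, for either text dialect."""
    model = random_signed_network(
        GeneratorConfig(
            n_nodes=10,
            edge_probability=0.3,
            inhibition_fraction=0.4,
            weight_range=(0.5, 2.0),
            gain_range=(5.0, 20.0),
            decay_range=(0.5, 1.5),
            seed=seed,
        )
    )
    assert parse_model(serialize_model(model, fmt), fmt) == model


def test_serialization_is_deterministic():
    model = random_signed_network(GeneratorConfig(n_nodes=6, seed=1))
    assert serialize_model(model, "json") == serialize_model(model, "json")
    assert serialize_model(model, "signed_sif") == serialize_model(model, "signed_sif")


class TestBnetExport:
    def test_two_node_activation_chain(self, chain):
        text = serialize_model(chain, "bnet")
        lines = text.strip().splitlines()
        assert lines[0] == "targets, factors"
        assert "A, 0" in lines  # input node with no regulators decays
        assert "B, A" in lines

    def test_mixed_regulation_rule(self):
        model = NetworkModel(
            [Node("A"), Node("B"), Node("C")],
            [Edge("A", "B", ACTIVATION), Edge("C", "B", INHIBITION)],
        )
        assert "B, A & !C" in serialize_model(model, "bnet")

    def test_weighted_model_refused(self):
        model = NetworkModel(
            [Node("A"), Node("B")], [Edge("A", "B", ACTIVATION, 2.0)]
        )
        with pytest.raises(ModelValidationError, match="weight"):
            serialize_model(model, "bnet")


class TestScenarioTables:
    def test_minimal_single_column(self):
        scenarios = parse_scenarios("node\tonly\nA\t0.5\n")
        assert len(scenarios) == 1
        assert scenarios[0].clamps == {"A": 0.5}

    def test_blank_cells_leave_nodes_free(self):
        scenarios = parse_scenarios("node\ts1\ts2\nA\t0.3\t\nB\t\t0.9\n")
        assert scenarios[0].clamps == {"A": 0.3}
        assert scenarios[1].clamps == {"B": 0.9}

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ParseError, match=r"outside \[0, 1\]"):
            parse_scenarios("node\ts\nA\t1.2\n")

    def test_unknown_node_warns_but_parses(self, chain):
        with pytest.warns(UserWarning, match="Z"):
            scenarios = parse_scenarios("node\ts\nA\t0.1\nZ\t0.2\n", model=chain)
        assert scenarios[0].clamps == {"A": 0.1, "Z": 0.2}

    def test_round_trip(self):
        text = "node\ts1\ts2\nA\t0.25\t\nB\t\t1.0\n"
        scenarios = parse_scenarios(text)
        again = parse_scenarios(serialize_scenarios(scenarios))
        assert [(s.name, s.clamps) for s in again] == [
            (s.name, s.clamps) for s in scenarios
        ]


class TestCrcFixture:
    def test_validates_and_contains_all_printed_nodes(self, crc_model):
        crc_model.validate()
        printed = {
            "BRAF(V600)-Act", "EGFR", "(EGFR)*", "HGFR", "(HGFR)*", "ERK",
            "ERK-Inh", "p53-Mut", "Bcl2", "c-Myc-Inh", "c-Myc-Act", "AKT",
            "Gefitinib", "Vemurafenib", "MEK-Inhibitor", "Bcl2-Inhibitor",
            "apoptosis", "proliferation",
        }
        assert printed <= set(crc_model.nodes)

    @pytest.mark.parametrize(
        "source, target, sign",
        [
            ("ERK", "Bcl2", ACTIVATION),
            ("AKT", "Bcl2", ACTIVATION),
            ("Bcl2", "BAX", INHIBITION),
            ("PTEN", "AKT", INHIBITION),
            ("p53", "BAX", ACTIVATION),
            ("p53", "PTEN", ACTIVATION),
            ("MEK", "BAD", INHIBITION),
            ("AKT", "BAD", INHIBITION),
            ("BAD", "Bcl2", INHIBITION),
        ],
    )
    def test_apoptosis_arm_wiring(self, crc_model, source, target, sign):
        """Bcl2 integrates ERK/AKT survival input; p53 acts via BAX and PTEN;
        MEK and AKT silence BAD, which otherwise suppresses Bcl2."""
        edges = {(e.source, e.target): e.sign for e in crc_model.edges}
        assert edges[(source, target)] == sign

    def test_phenotype_nodes_are_sinks(self, crc_model):
        phenotypes = set(crc_model.phenotype_nodes())
        assert {"apoptosis", "proliferation"} <= phenotypes
        for edge in crc_model.edges:
            assert edge.source not in phenotypes

    def test_fixture_round_trips(self, crc_model):
        assert parse_model(serialize_model(crc_model, "json"), "json") == crc_model

    def test_scenario_table_matches_pre_stimulations(self, treatment_scenarios):
        assert list(treatment_scenarios) == SCENARIO_NAMES
        untr = treatment_scenarios["untr."]
        assert untr.clamps["BRAF(V600)-Act"] == 0.7
        assert "Gefitinib" not in untr.clamps
        assert len(untr.clamps) == 8
        gef = treatment_scenarios["+gef"]
        assert gef.clamps["Gefitinib"] == 1.0
        assert gef.clamps["(HGFR)*"] == 0.6
        mek = treatment_scenarios["+MEK-Inh"]
        assert mek.clamps["MEK-Inhibitor"] == 1.0
        assert "Bcl2" not in mek.clamps
        combi = treatment_scenarios["+combi"]
        assert combi.clamps["Bcl2"] == 0.2252
        assert combi.clamps["c-Myc-Act"] == 0.09

    def test_scenarios_reference_only_model_nodes(self, crc_model, treatment_scenarios):
        for scenario in treatment_scenarios.values():
            assert scenario.check_against(crc_model) == []

    def test_readout_nodes_present(self, crc_model):
        assert all(node in crc_model.nodes for node in READOUT_NODES)


class TestModelInvariants:
    def test_duplicate_edge_rejected(self):
        with pytest.raises(ModelValidationError, match="duplicate edge"):
            NetworkModel(
                [Node("A"), Node("B")],
                [Edge("A", "B"), Edge("A", "B", INHIBITION)],
            )

    def test_duplicate_node_rejected(self):
        with pytest.raises(ModelValidationError, match="duplicate node"):
            NetworkModel([Node("A"), Node("A")])

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ModelValidationError, match="gain"):
            Node("A", gain=0.0)
        with pytest.raises(ModelValidationError, match="decay"):
            Node("A", decay=-1.0)

    def test_scenario_clamp_initial_overlap_rejected(self):
        from squadron import ScenarioSpec

        with pytest.raises(ModelValidationError, match="both"):
            ScenarioSpec("s", clamps={"A": 0.5}, initials={"A": 0.1})
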