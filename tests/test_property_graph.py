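import networkx as nx
import numpy as np
import pytest

from emrgraph.errors import ConfigError, CypherParseError, PatientNotFoundError, QueryError
from emrgraph.propgraph import (
    NODE_LABELS,
    RELATIONS,
    build_property_graph,
    export_cypher,
    export_graphml,
    parse_cypher_export,
    patient_journey,
    query_patients,
)


@pytest.fixture(scope="module")
def journey_graph(journey_tables, journey_cohort):
    return build_property_graph(journey_tables, journey_cohort)


def test_fully_populated_patient_has_ten_node_star(journey_graph):
    journey = patient_journey(journey_graph, 107411)
    assert journey.num_nodes == 10
    assert journey.num_edges == 9
    assert journey.node_types() == set(NODE_LABELS)
    assert journey.edge_types() == set(RELATIONS.values())


def test_absent_record_group_produces_no_node(journey_graph):
    # patient 107412 has no surgery records
    journey = patient_journey(journey_graph, 107412)
    assert "Surgery" not in journey.node_types()


def test_documented_journey_properties(journey_graph):
    journey = patient_journey(journey_graph, 107411)
    props = {n.label: n.properties for n in journey.nodes.values()}
    assert props["Diagnosis"]["name"] == "hypertension"
    assert props["Laboratory"]["blood"] == 94.0
    assert props["Echocardiography"]["gls"] == -1.0
    assert props["Physical"]["weight"] == 53.55
    assert props["Smoke"]["level"] == 1
    assert "statin" in props["Medication"]["drugs"]
    assert props["Event"]["outcome"] == 1
    assert props["Event"]["age_at_event"] == 67.0


def test_unknown_patient_raises(journey_graph):
    with pytest.raises(PatientNotFoundError):
        patient_journey(journey_graph, 999999)


def test_journeys_partition_the_graph(journey_graph):
    total_nodes = sum(
        patient_journey(journey_graph, pid).num_nodes for pid in journey_graph.patient_ids()
    )
    total_edges = sum(
        patient_journey(journey_graph, pid).num_edges for pid in journey_graph.patient_ids()
    )
    assert total_nodes == journey_graph.num_nodes
    assert total_edges == journey_graph.num_edges


def test_node_and_edge_counts_match_row_count_oracle(small_tables, small_cohort):
    graph = build_property_graph(small_tables, small_cohort)
    # independent oracle: one node per populated per-patient record group
    # (+ person + event), one edge per non-person node
    expected_nodes = 2 * len(small_cohort)  # Person + Event per patient
    for table, date_col in [
        ("diagnosis", "diagnosis_date"),
        ("laboratory", "date"),
        ("echocardiography", "date"),
        ("physical", "date"),
    ]:
        frame = getattr(small_tables, table).merge(
            small_cohort[["patient_id", "index_date"]], on="patient_id"
        )
        frame = frame[frame[date_col] <= frame["index_date"]]
        expected_nodes += frame["patient_id"].nunique()
    for table in ["medication", "surgery", "visit", "smoke"]:
        frame = getattr(small_tables, table)
        expected_nodes += frame[frame["patient_id"].isin(set(small_cohort["patient_id"]))][
            "patient_id"
        ].nunique()
    assert graph.num_nodes == expected_nodes
    assert graph.num_edges == expected_nodes - len(small_cohort)  # all but Person nodes
    # star invariant: every edge starts at a Person node
    assert all(graph.nodes[e.head].label == "Person" for e in graph.edges)


def test_statin_query_and_conjunction(journey_graph):
    on_statin, count = query_patients(journey_graph, {"medication_name": "statin"})
    assert count == len(on_statin) == 3
    both, _ = query_patients(journey_graph, {"medication_name": "statin", "outcome": 1})
    with_outcome, _ = query_patients(journey_graph, {"outcome": 1})
    assert set(both) == set(on_statin) & set(with_outcome)


def test_query_counts_match_table_scan(small_tables, small_cohort):
    graph = build_property_graph(small_tables, small_cohort)
    _, count = query_patients(graph, {"medication_name": "statin"})
    scan = small_tables.medication[
        (small_tables.medication["drug_name"] == "statin")
        & small_tables.medication["patient_id"].isin(set(small_cohort["patient_id"]))
    ]["patient_id"].nunique()
    assert count == scan


def test_unknown_predicate_rejected(journey_graph):
    with pytest.raises(QueryError):
        query_patients(journey_graph, {"favourite_colour": "blue"})


def test_cypher_export_constraint_and_batch_counts(journey_graph, tmp_path):
    files = export_cypher(journey_graph, tmp_path, batch_size=2)
    constraints = (tmp_path / "constraints.cypher").read_text().strip().split("\n")
    assert len(constraints) == 10  # one uniqueness constraint per node label
    # 5 Person nodes at batch_size=2 -> ceil(5/2) = 3 batches
    assert len(list(tmp_path.glob("nodes_Person_*.csv"))) == 3
    assert (tmp_path / "indexes.cypher").exists()


def test_cypher_batch_size_validation(journey_graph, tmp_path):
    with pytest.raises(ConfigError):
        export_cypher(journey_graph, tmp_path, batch_size=0)


def test_cypher_roundtrip_identity(journey_graph, tmp_path):
    export_cypher(journey_graph, tmp_path, batch_size=3)
    assert parse_cypher_export(tmp_path).equals(journey_graph)


def test_cypher_roundtrip_fuzz(tmp_path):
    """Random small graphs survive export -> parse property-wise."""
    from emrgraph.cohort import label_outcome, select_cohort
    from emrgraph.synthetic import GeneratorConfig, generate_emr

    for seed in range(8):
        tables = generate_emr(GeneratorConfig(n_patients=15, seed=seed))
        cohort = label_outcome(select_cohort(tables), tables.events)
        if cohort.empty:
            continue
        graph = build_property_graph(tables, cohort)
        out = tmp_path / f"g{seed}"
        export_cypher(graph, out, batch_size=4)
        assert parse_cypher_export(out).equals(graph)


def test_unsupported_cypher_statement_names_file(tmp_path, journey_graph):
    export_cypher(journey_graph, tmp_path)
    (tmp_path / "load_nodes.cypher").write_text("MERGE (n:Bogus {x: 1});\n")
    with pytest.raises(CypherParseError):
        parse_cypher_export(tmp_path)


def test_graphml_counts_survive_third_party_reader(journey_graph, tmp_path):
    path = tmp_path / "graph.graphml"
    export_graphml(journey_graph, path)
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == journey_graph.num_nodes
    assert back.number_of_edges() == journey_graph.num_edges


def test_graphml_empty_graph(tmp_path):
    from emrgraph.propgraph import PropertyGraph

    path = tmp_path / "empty.graphml"
    export_graphml(PropertyGraph(), path)
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == 0
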