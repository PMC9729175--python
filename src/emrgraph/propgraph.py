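"""Patient-centric heterogeneous property graph.

The graph follows a star (bipartite) shape: every non-person node hangs off
exactly one Person node through a typed edge, and no edge connects two
non-person nodes.  Ten node labels and nine relation labels are defined;
each per-patient auxiliary record group is aggregated into a single node
whose properties hold the latest values at or before the index admission.

Alongside the in-memory query engine the module emits Neo4j-style bulk
import artifacts — one uniqueness constraint per node label, lookup
indexes, and batched ``LOAD CSV`` scripts guarded by ``USING PERIODIC
COMMIT`` — plus GraphML for generic visualization tools, and can parse its
own Cypher exports back for lossless round-trips.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, CypherParseError, PatientNotFoundError, QueryError
from .synthetic import EmrTables

NODE_LABELS = [
    "Person",
    "Diagnosis",
    "Laboratory",
    "Echocardiography",
    "Physical",
    "Medication",
    "Surgery",
    "Visit",
    "Smoke",
    "Event",
]

#: relation label is determined by the tail node's label
RELATIONS = {
    "Diagnosis": "HAS_DIAGNOSIS",
    "Laboratory": "HAS_LAB",
    "Echocardiography": "HAS_ECHO",
    "Physical": "HAS_PHYSICAL",
    "Medication": "TAKES_MEDICATION",
    "Surgery": "UNDERWENT_SURGERY",
    "Visit": "HAS_VISIT",
    "Smoke": "HAS_SMOKING_STATUS",
    "Event": "EXPERIENCED_EVENT",
}

#: lookup attributes that receive index statements in the Cypher export
INDEXED_PROPERTIES = [
    ("Diagnosis", "name"),
    ("Medication", "drugs"),
    ("Event", "outcome"),
    ("Person", "sex"),
]

QUERYABLE_PREDICATES = {"medication_name", "outcome", "diagnosis_name"}


@dataclass
class Node:
    node_id: int
    label: str
    properties: dict


@dataclass
class Edge:
    head: int
    tail: int
    relation: str
    properties: dict = field(default_factory=dict)


class PropertyGraph:
    """Typed, attributed multigraph with a patient-centric star topology."""

    def __init__(self) -> None:
        self.nodes: dict[int, Node] = {}
        self.edges: list[Edge] = []
        self._next_id = 0
        self._person_of: dict = {}  # patient_id -> person node_id
        self._star: dict[int, list[int]] = {}  # person node_id -> neighbor node ids

    def add_node(self, label: str, properties: dict) -> int:
        if label not in NODE_LABELS:
            raise ConsistencyError(f"unknown node label {label!r}")
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = Node(nid, label, dict(properties))
        if label == "Person":
            pid = properties["patient_id"]
            if pid in self._person_of:
                raise ConsistencyError(f"duplicate Person patient_id {pid!r}")
            self._person_of[pid] = nid
            self._star[nid] = []
        return nid

    def add_edge(self, head: int, tail: int, relation: str, properties: dict | None = None) -> None:
        if head not in self.nodes or tail not in self.nodes:
            raise ConsistencyError("edge endpoint does not exist")
        if self.nodes[head].label != "Person":
            raise ConsistencyError("star invariant: every edge must start at a Person node")
        self.edges.append(Edge(head, tail, relation, dict(properties or {})))
        self._star[head].append(tail)

    # ---- introspection ---------------------------------------------------
    def node_types(self) -> set[str]:
        return {n.label for n in self.nodes.values()}

    def edge_types(self) -> set[str]:
        return {e.relation for e in self.edges}

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def patient_ids(self) -> list:
        return sorted(self._person_of)

    def _canonical(self):
        """Order-insensitive canonical form for equality testing."""
        def freeze(props):
            return tuple(sorted(props.items()))

        nodes = sorted(
            (n.label, n.properties.get("patient_id"), freeze(n.properties))
            for n in self.nodes.values()
        )
        edges = sorted(
            (
                e.relation,
                self.nodes[e.head].properties.get("patient_id"),
                self.nodes[e.tail].label,
                freeze(e.properties),
            )
            for e in self.edges
        )
        return nodes, edges

    def equals(self, other: "PropertyGraph") -> bool:
        """Property-wise equality, ignoring internal IDs and insert order."""
        return self._canonical() == other._canonical()


def _latest_row(frame: pd.DataFrame, date_col: str, index_date) -> pd.DataFrame:
    sub = frame[frame[date_col] <= index_date]
    return sub.sort_values(date_col, kind="stable")


def build_property_graph(tables: EmrTables, cohort: pd.DataFrame) -> PropertyGraph:
    """Build the 10-label star graph for a labeled cohort.

    One node per populated auxiliary record group per patient, aggregated
    to latest-at-or-before-index values; an Event node per labeled patient
    carrying the outcome.  Every node stores the patient ID property in
    addition to its graph-internal ID.
    """
    g = PropertyGraph()
    if "outcome" not in cohort.columns:
        raise ConsistencyError("cohort must be labeled before graph construction")
    person = tables.person.set_index("patient_id")
    missing = set(cohort["patient_id"]) - set(person.index)
    if missing:
        raise ConsistencyError(f"cohort patients absent from person table: {sorted(missing)[:3]}")

    grouped = {name: dict(list(frame.groupby("patient_id"))) for name, frame in tables.tables().items() if name != "person"}

    for row in cohort.itertuples(index=False):
        pid = row.patient_id
        index_date = pd.Timestamp(row.index_date)
        prow = person.loc[pid]
        person_id = g.add_node(
            "Person",
            {
                "patient_id": pid,
                "sex": str(prow["sex"]),
                "birth_date": str(pd.Timestamp(prow["birth_date"]).date()),
                "age_at_index": float(row.age_at_index),
            },
        )

        def attach(label: str, props: dict) -> None:
            props = {"patient_id": pid, **props}
            nid = g.add_node(label, props)
            g.add_edge(person_id, nid, RELATIONS[label])

        dx = grouped["diagnosis"].get(pid)
        if dx is not None:
            past = _latest_row(dx, "diagnosis_date", index_date)
            latest = past.iloc[-1] if len(past) else dx.sort_values("diagnosis_date").iloc[0]
            attach(
                "Diagnosis",
                {
                    "code": str(latest["icd10_code"]),
                    "name": str(latest["diagnosis_name"]),
                    "n_codes": int(dx["icd10_code"].nunique()),
                },
            )

        for table, label, name_col in [
            ("laboratory", "Laboratory", "test_name"),
            ("echocardiography", "Echocardiography", "measure_name"),
            ("physical", "Physical", "measure_name"),
        ]:
            rec = grouped[table].get(pid)
            if rec is None:
                continue
            past = _latest_row(rec, "date", index_date)
            if not len(past):
                continue
            latest = past.groupby(name_col)["value"].last()
            attach(label, {str(k): float(v) for k, v in latest.items()})

        meds = grouped["medication"].get(pid)
        if meds is not None:
            drugs = sorted(set(meds["drug_name"].astype(str)))
            attach("Medication", {"drugs": ",".join(drugs), "n_drugs": len(drugs)})

        surg = grouped["surgery"].get(pid)
        if surg is not None:
            procs = sorted(set(surg["procedure_name"].astype(str)))
            attach("Surgery", {"procedures": ",".join(procs), "n_procedures": len(procs)})

        visits = grouped["visit"].get(pid)
        if visits is not None:
            attach(
                "Visit",
                {
                    "n_visits": int(len(visits)),
                    "last_visit_date": str(pd.Timestamp(visits["visit_date"].max()).date()),
                },
            )

        smoke = grouped["smoke"].get(pid)
        if smoke is not None:
            attach("Smoke", {"level": int(smoke["smoking_level"].max())})

        event_props = {"outcome": int(row.outcome)}
        ev = grouped["events"].get(pid)
        if row.outcome == 1 and ev is not None:
            fut = ev[pd.to_datetime(ev["event_date"]) > index_date].sort_values("event_date")
            if len(fut):
                first = fut.iloc[0]
                event_props["event_type"] = str(first["event_type"])
                birth = pd.Timestamp(prow["birth_date"])
                age_ev = (pd.Timestamp(first["event_date"]) - birth).days / 365.25
                event_props["age_at_event"] = float(math.floor(age_ev))
        attach("Event", event_props)

    return g


def patient_journey(graph: PropertyGraph, patient_id) -> PropertyGraph:
    """The star subgraph around one patient, properties intact."""
    if patient_id not in graph._person_of:
        raise PatientNotFoundError(f"patient {patient_id!r} is not in the graph")
    sub = PropertyGraph()
    person_id = graph._person_of[patient_id]
    new_person = sub.add_node("Person", graph.nodes[person_id].properties)
    for edge in graph.edges:
        if edge.head != person_id:
            continue
        tail = graph.nodes[edge.tail]
        new_tail = sub.add_node(tail.label, tail.properties)
        sub.add_edge(new_person, new_tail, edge.relation, edge.properties)
    return sub


def query_patients(graph: PropertyGraph, predicates: dict, distinct: bool = True):
    """Conjunctive patient filter across the star; returns (ids, count).

    Supported predicate keys: ``medication_name`` (patient takes the drug),
    ``outcome`` (Event outcome equals the value), ``diagnosis_name``.
    With ``distinct=False`` a patient appears once per matching diagnosis /
    medication record combination that satisfied the predicates.
    """
    unknown = set(predicates) - QUERYABLE_PREDICATES
    if unknown:
        raise QueryError(f"unknown predicate(s) {sorted(unknown)}; supported: {sorted(QUERYABLE_PREDICATES)}")

    matches = []
    for pid in graph.patient_ids():
        person_id = graph._person_of[pid]
        neighbors = [graph.nodes[nid] for nid in graph._star[person_id]]
        multiplicity = 1
        ok = True
        for key, value in predicates.items():
            if key == "medication_name":
                med = [n for n in neighbors if n.label == "Medication"]
                hits = sum(
                    1 for n in med if value in n.properties.get("drugs", "").split(",")
                )
            elif key == "outcome":
                hits = sum(
                    1
                    for n in neighbors
                    if n.label == "Event" and n.properties.get("outcome") == value
                )
            else:  # diagnosis_name
                hits = sum(
                    1
                    for n in neighbors
                    if n.label == "Diagnosis" and n.properties.get("name") == value
                )
            if hits == 0:
                ok = False
                break
            multiplicity *= hits
        if ok:
            matches.extend([pid] * (1 if distinct else multiplicity))
    return matches, len(matches)


# ---------------------------------------------------------------------------
# Cypher export / parse
# ---------------------------------------------------------------------------

_CONVERTERS = {"toInteger": int, "toFloat": float, "": str}


def _property_types(graph: PropertyGraph) -> dict[str, dict[str, str]]:
    """Per-label property -> {'int','float','str'} inferred from values."""
    types: dict[str, dict[str, str]] = {}
    for node in graph.nodes.values():
        slot = types.setdefault(node.label, {})
        for key, value in node.properties.items():
            if isinstance(value, bool):
                kind = "str"
            elif isinstance(value, (int, np.integer)):
                kind = "int"
            elif isinstance(value, (float, np.floating)):
                kind = "float"
            else:
                kind = "str"
            prev = slot.get(key)
            if prev is None:
                slot[key] = kind
            elif prev != kind:
                # widen: int+float -> float, anything else -> str
                slot[key] = "float" if {prev, kind} == {"int", "float"} else "str"
    return types


def _format_value(value, kind: str) -> str:
    if kind == "float":
        return repr(float(value))
    if kind == "int":
        return str(int(value))
    return str(value)


def export_cypher(graph: PropertyGraph, outdir, batch_size: int = 1000) -> list[Path]:
    """Write constraint, index and batched LOAD CSV import scripts.

    Emits one uniqueness constraint per node label in the schema, index
    statements on the lookup attributes, and per-label node / per-relation
    edge CSV chunks of at most ``batch_size`` rows, each loaded by its own
    ``USING PERIODIC COMMIT`` transaction.  Output is deterministic: sorted
    by label, then patient ID.
    """
    if batch_size < 1:
        raise ConfigError("batch_size must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    constraints = [
        f"CREATE CONSTRAINT {label.lower()}_patient_id IF NOT EXISTS "
        f"FOR (n:{label}) REQUIRE n.patient_id IS UNIQUE;"
        for label in NODE_LABELS
    ]
    path = outdir / "constraints.cypher"
    path.write_text("\n".join(constraints) + "\n", encoding="utf-8")
    written.append(path)

    indexes = [
        f"CREATE INDEX {label.lower()}_{prop}_idx IF NOT EXISTS FOR (n:{label}) ON (n.{prop});"
        for label, prop in INDEXED_PROPERTIES
    ]
    path = outdir / "indexes.cypher"
    path.write_text("\n".join(indexes) + "\n", encoding="utf-8")
    written.append(path)

    types = _property_types(graph)
    node_stmts = []
    for label in NODE_LABELS:
        nodes = sorted(
            (n for n in graph.nodes.values() if n.label == label),
            key=lambda n: (str(n.properties.get("patient_id")), n.node_id),
        )
        if not nodes:
            continue
        props = sorted(types[label])
        columns = ["_id"] + props
        n_batches = math.ceil(len(nodes) / batch_size)
        for b in range(n_batches):
            chunk = nodes[b * batch_size : (b + 1) * batch_size]
            csv_name = f"nodes_{label}_{b:03d}.csv"
            buf = io.StringIO()
            writer = csv.writer(buf, lineterminator="\n")
            writer.writerow(columns)
            for node in chunk:
                row = [str(node.node_id)]
                for prop in props:
                    if prop in node.properties:
                        row.append(_format_value(node.properties[prop], types[label][prop]))
                    else:
                        row.append("")
                writer.writerow(row)
            csv_path = outdir / csv_name
            csv_path.write_text(buf.getvalue(), encoding="utf-8")
            written.append(csv_path)
            assigns = ["_id: toInteger(row._id)"]
            for prop in props:
                kind = types[label][prop]
                conv = {"int": "toInteger", "float": "toFloat", "str": ""}[kind]
                expr = f"{conv}(row.{prop})" if conv else f"row.{prop}"
                assigns.append(f"{prop}: {expr}")
            node_stmts.append(
                f"USING PERIODIC COMMIT {batch_size}\n"
                f"LOAD CSV WITH HEADERS FROM 'file:///{csv_name}' AS row\n"
                f"CREATE (n:{label} {{{', '.join(assigns)}}});"
            )
    path = outdir / "load_nodes.cypher"
    path.write_text("\n\n".join(node_stmts) + "\n", encoding="utf-8")
    written.append(path)

    edge_stmts = []
    for relation in sorted(set(RELATIONS.values())):
        edges = sorted(
            (e for e in graph.edges if e.relation == relation),
            key=lambda e: (str(graph.nodes[e.head].properties.get("patient_id")), e.tail),
        )
        if not edges:
            continue
        n_batches = math.ceil(len(edges) / batch_size)
        for b in range(n_batches):
            chunk = edges[b * batch_size : (b + 1) * batch_size]
            csv_name = f"edges_{relation}_{b:03d}.csv"
            lines = ["_head,_tail"] + [f"{e.head},{e.tail}" for e in chunk]
            csv_path = outdir / csv_name
            csv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
            written.append(csv_path)
            edge_stmts.append(
                f"USING PERIODIC COMMIT {batch_size}\n"
                f"LOAD CSV WITH HEADERS FROM 'file:///{csv_name}' AS row\n"
                f"MATCH (a {{_id: toInteger(row._head)}}), (b {{_id: toInteger(row._tail)}})\n"
                f"CREATE (a)-[:{relation}]->(b);"
            )
    path = outdir / "load_edges.cypher"
    path.write_text("\n\n".join(edge_stmts) + "\n", encoding="utf-8")
    written.append(path)
    return written


_NODE_STMT = re.compile(
    r"USING PERIODIC COMMIT (\d+)\n"
    r"LOAD CSV WITH HEADERS FROM 'file:///(?P<csv>[\w.\-]+)' AS row\n"
    r"CREATE \(n:(?P<label>\w+) \{(?P<props>.*)\}\);",
)
_EDGE_STMT = re.compile(
    r"USING PERIODIC COMMIT (\d+)\n"
    r"LOAD CSV WITH HEADERS FROM 'file:///(?P<csv>[\w.\-]+)' AS row\n"
    r"MATCH \(a \{_id: toInteger\(row\._head\)\}\), \(b \{_id: toInteger\(row\._tail\)\}\)\n"
    r"CREATE \(a\)-\[:(?P<rel>\w+)\]->\(b\);",
)
_PROP_ASSIGN = re.compile(r"(\w+): (?:(toInteger|toFloat)\(row\.(\w+)\)|row\.(\w+))")


def parse_cypher_export(indir) -> PropertyGraph:
    """Reconstruct a graph from :func:`export_cypher` output (that dialect only)."""
    indir = Path(indir)
    graph = PropertyGraph()
    id_map: dict[int, int] = {}

    def read_csv_rows(name: str) -> tuple[list[str], list[list[str]]]:
        with (indir / name).open(encoding="utf-8", newline="") as fh:
            rows = list(csv.reader(fh))
        return rows[0], rows[1:]

    deferred_persons: list[tuple[str, dict]] = []
    node_batches: list[tuple[str, str, str]] = []  # (label, csv, props)
    for lineno, stmt in _statements(indir / "load_nodes.cypher"):
        m = _NODE_STMT.fullmatch(stmt)
        if not m:
            raise CypherParseError(f"load_nodes.cypher line {lineno}: unsupported statement")
        node_batches.append((m.group("label"), m.group("csv"), m.group("props")))
    # Person rows first so the star can be rebuilt as tails arrive
    node_batches.sort(key=lambda t: (t[0] != "Person",))
    for label, csv_name, props_src in node_batches:
        assigns = []
        pos = 0
        for m in _PROP_ASSIGN.finditer(props_src):
            assigns.append((m.group(1), m.group(2) or "", m.group(3) or m.group(4)))
            pos = m.end()
        header, rows = read_csv_rows(csv_name)
        col_idx = {c: i for i, c in enumerate(header)}
        for row in rows:
            props = {}
            old_id = None
            for prop, conv, col in assigns:
                raw = row[col_idx[col]]
                if raw == "":
                    continue
                value = _CONVERTERS[conv](raw)
                if prop == "_id":
                    old_id = value
                else:
                    props[prop] = value
            if old_id is None:
                raise CypherParseError(f"{csv_name}: node row without _id")
            new_id = graph.add_node(label, props)
            id_map[old_id] = new_id

    for lineno, stmt in _statements(indir / "load_edges.cypher"):
        m = _EDGE_STMT.fullmatch(stmt)
        if not m:
            raise CypherParseError(f"load_edges.cypher line {lineno}: unsupported statement")
        _, rows = read_csv_rows(m.group("csv"))
        for head, tail in rows:
            graph.add_edge(id_map[int(head)], id_map[int(tail)], m.group("rel"))
    return graph


def _statements(path: Path):
    """Yield (starting line number, statement text) from a script file."""
    text = path.read_text(encoding="utf-8")
    lineno = 1
    for block in text.split("\n\n"):
        stmt = block.strip("\n")
        if stmt:
            yield lineno, stmt
        lineno += block.count("\n") + 2 - 1


# ---------------------------------------------------------------------------
# GraphML export
# ---------------------------------------------------------------------------

def export_graphml(graph: PropertyGraph, path) -> None:
    """Write standard GraphML; node label, relation and properties become attributes."""
    g = nx.MultiDiGraph()
    for node in graph.nodes.values():
        attrs = {k: v for k, v in node.properties.items()}
        g.add_node(node.node_id, label=node.label, **attrs)
    for edge in graph.edges:
        g.add_edge(edge.head, edge.tail, relation=edge.relation, **edge.properties)
    nx.write_graphml(g, path)
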