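"""Learning-ready bipartite attributed graph.

Two node partitions — patients and diagnosis profiles — carry fixed-length
feature vectors (defaults: 12 patient features, 147 diagnosis features),
and every edge carries exactly one attribute: the binary five-year outcome.
Node indices are prefixed (``p_``/``d_``) so raw IDs can never collide
across partitions.

In the default ``per_patient`` mode each patient links to their own
diagnosis-profile node, so a cohort of N patients yields 2N nodes and N
edges.  ``shared_diagnosis`` deduplicates identical diagnosis profiles into
shared nodes, producing a multigraph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, SchemaError
from .synthetic import EmrTables

DEFAULT_PATIENT_FEATURES = [
    "age_at_index",
    "sex_male",
    "smoke_level",
    "lab_blood",
    "lab_glucose",
    "lab_ldl",
    "echo_ef",
    "phys_sbp",
    "phys_weight",
    "n_medications",
    "n_visits",
    "n_diagnoses",
]

BINARY_FEATURES = {"sex_male"}
COUNT_FEATURES = {"n_medications", "n_visits", "n_diagnoses", "n_surgeries", "smoke_level"}


@dataclass(frozen=True)
class FeatureSchema:
    """Which cohort columns become node features, and how they are scaled.

    ``patient_features`` names cohort summary columns (12 by default).
    Diagnosis features are multi-hot indicators over the
    ``n_diagnosis_codes`` most frequent three-character ICD-10 codes plus a
    trailing "other" bucket, 146 + 1 = 147 columns by default.
    Continuous patient features are median-imputed; features listed in
    ``missing_indicators`` additionally get a 0/1 missingness column
    (lengthening the vector).  ``normalization`` is ``"zscore"`` (train-split
    statistics) or ``"none"``.
    """

    patient_features: tuple[str, ...] = tuple(DEFAULT_PATIENT_FEATURES)
    n_diagnosis_codes: int = 146
    normalization: str = "zscore"
    missing_indicators: tuple[str, ...] = ()

    @property
    def patient_dim(self) -> int:
        return len(self.patient_features) + len(self.missing_indicators)

    @property
    def diagnosis_dim(self) -> int:
        return self.n_diagnosis_codes + 1


def build_features(
    cohort: pd.DataFrame,
    tables: EmrTables,
    schema: FeatureSchema = FeatureSchema(),
    train_ids=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient and diagnosis feature matrices, one row per cohort patient.

    Imputation medians and z-score statistics come from the ``train_ids``
    subset when given (so test rows never leak into scaling), otherwise
    from all rows.  Column order is deterministic.
    """
    frame = cohort.copy()
    frame["sex_male"] = (frame["sex"] == "M").astype(float) if "sex" in frame else 0.0

    missing = [c for c in schema.patient_features if c not in frame.columns]
    if missing:
        raise SchemaError(f"schema references absent cohort columns: {missing}")
    unknown_ind = [c for c in schema.missing_indicators if c not in schema.patient_features]
    if unknown_ind:
        raise SchemaError(f"missing_indicators not among patient_features: {unknown_ind}")

    train_mask = (
        frame["patient_id"].isin(set(train_ids)).to_numpy()
        if train_ids is not None
        else np.ones(len(frame), dtype=bool)
    )

    pat = pd.DataFrame(index=frame["patient_id"])
    for col in schema.patient_features:
        vals = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
        isna = np.isnan(vals)
        if isna.all():
            med = 0.0
        else:
            train_vals = vals[train_mask & ~isna]
            med = float(np.median(train_vals)) if train_vals.size else float(np.nanmedian(vals))
        filled = np.where(isna, med, vals)
        if (
            schema.normalization == "zscore"
            and col not in BINARY_FEATURES
            and col not in COUNT_FEATURES | {"smoke_level"}
        ):
            mu = float(filled[train_mask].mean())
            sd = float(filled[train_mask].std())
            filled = (filled - mu) / sd if sd > 0 else filled - mu
        pat[col] = filled
        if col in schema.missing_indicators:
            pat[f"{col}_missing"] = isna.astype(float)
    # keep indicator columns adjacent to the end, deterministic order
    ordered = list(schema.patient_features) + [
        f"{c}_missing" for c in schema.missing_indicators
    ]
    pat = pat[ordered]

    diag = _diagnosis_indicators(frame, tables, schema.n_diagnosis_codes)
    return pat, diag


def _diagnosis_indicators(cohort: pd.DataFrame, tables: EmrTables, n_codes: int) -> pd.DataFrame:
    """Multi-hot over the top-``n_codes`` 3-character codes plus "other"."""
    ids = cohort["patient_id"]
    dx = tables.diagnosis[tables.diagnosis["patient_id"].isin(set(ids))].copy()
    dx["code3"] = dx["icd10_code"].astype(str).str[:3]
    pairs = dx[["patient_id", "code3"]].drop_duplicates()
    counts = pairs["code3"].value_counts()
    # frequency-ranked, ties broken lexicographically for determinism
    ranked = sorted(counts.index, key=lambda c: (-counts[c], c))
    top = ranked[:n_codes]
    # pad with always-zero columns if the data has fewer distinct codes
    pads = [f"__pad_{i}" for i in range(len(top), n_codes)]
    columns = top + pads + ["other"]
    arr = np.zeros((len(ids), len(columns)))
    row_of = {pid: i for i, pid in enumerate(ids)}
    col_of = {c: j for j, c in enumerate(columns)}
    top_set = set(top)
    other_col = len(columns) - 1
    for pid, code in zip(pairs["patient_id"], pairs["code3"]):
        arr[row_of[pid], col_of[code] if code in top_set else other_col] = 1.0
    return pd.DataFrame(arr, index=ids, columns=columns)


@dataclass
class BipartiteGraph:
    """Patient/diagnosis partitions, feature matrices and the outcome edges.

    ``patient_features`` is indexed by ``p_<id>``, ``diagnosis_features`` by
    ``d_<id>``; ``edges`` has columns ``source`` (patient), ``target``
    (diagnosis) and ``outcome``.  Undirected multigraph semantics: an edge
    connects its two endpoints symmetrically.
    """

    patient_features: pd.DataFrame
    diagnosis_features: pd.DataFrame
    edges: pd.DataFrame
    mode: str = "per_patient"

    @property
    def num_nodes(self) -> int:
        return len(self.patient_features) + len(self.diagnosis_features)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def validate(self) -> None:
        pids = set(self.patient_features.index)
        dids = set(self.diagnosis_features.index)
        if pids & dids:
            raise ConsistencyError("prefixed node IDs collide across partitions")
        if not set(self.edges["source"]) <= pids:
            raise ConsistencyError("edge source outside the patient partition")
        if not set(self.edges["target"]) <= dids:
            raise ConsistencyError("edge target outside the diagnosis partition")
        if not self.edges["outcome"].isin([0, 1]).all():
            raise ConsistencyError("edge outcome must be binary")

    def adjacency(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Positional adjacency: patient->diagnosis and diagnosis->patient."""
        p_index = {pid: i for i, pid in enumerate(self.patient_features.index)}
        d_index = {did: i for i, did in enumerate(self.diagnosis_features.index)}
        adj_p: list[list[int]] = [[] for _ in range(len(p_index))]
        adj_d: list[list[int]] = [[] for _ in range(len(d_index))]
        for s, t in zip(self.edges["source"], self.edges["target"]):
            si, ti = p_index[s], d_index[t]
            adj_p[si].append(ti)
            adj_d[ti].append(si)
        return (
            [np.asarray(a, dtype=np.int64) for a in adj_p],
            [np.asarray(a, dtype=np.int64) for a in adj_d],
        )

    def to_csv_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patient_features.to_csv(outdir / "patient_nodes.csv")
        self.diagnosis_features.to_csv(outdir / "diagnosis_nodes.csv")
        self.edges.to_csv(outdir / "edges.csv", index=False)


def build_bipartite(
    cohort: pd.DataFrame,
    patient_matrix: pd.DataFrame,
    diagnosis_matrix: pd.DataFrame,
    mode: str = "per_patient",
) -> BipartiteGraph:
    """Assemble the bipartite graph from row-aligned feature matrices.

    ``per_patient``: one diagnosis-profile node and exactly one edge per
    patient (2N nodes, N edges).  ``shared_diagnosis``: identical diagnosis
    profiles collapse into shared nodes, patients keep one outcome edge each.
    """
    if mode not in {"per_patient", "shared_diagnosis"}:
        raise ValueError(f"unknown mode {mode!r}")
    if not (
        len(patient_matrix) == len(diagnosis_matrix) == len(cohort)
        and (patient_matrix.index == cohort["patient_id"]).all()
        and (diagnosis_matrix.index == cohort["patient_id"]).all()
    ):
        raise ConsistencyError("feature matrices must be row-aligned with the cohort")

    raw_ids = cohort["patient_id"].astype(str)
    p_ids = ("p_" + raw_ids).to_numpy()
    pat = patient_matrix.copy()
    pat.index = p_ids

    if mode == "per_patient":
        d_ids = ("d_" + raw_ids).to_numpy()
        diag = diagnosis_matrix.copy()
        diag.index = d_ids
    else:
        profiles = diagnosis_matrix.to_numpy()
        _, first_idx, inverse = np.unique(
            profiles, axis=0, return_index=True, return_inverse=True
        )
        d_ids = np.asarray([f"d_{k}" for k in inverse])
        diag = pd.DataFrame(
            profiles[first_idx],
            index=[f"d_{k}" for k in range(len(first_idx))],
            columns=diagnosis_matrix.columns,
        )

    edges = pd.DataFrame(
        {"source": p_ids, "target": d_ids, "outcome": cohort["outcome"].to_numpy()}
    )
    graph = BipartiteGraph(pat, diag, edges, mode=mode)
    graph.validate()
    return graph


def flatten_for_baselines(graph: BipartiteGraph) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate each patient's features with its linked diagnosis profile.

    Returns an (N, patient_dim + diagnosis_dim) matrix (159 under the
    default schema) and the outcome vector.  Requires exactly one edge per
    patient; a multigraph with several edges per patient is ambiguous.
    """
    if graph.edges["source"].duplicated().any():
        raise ConsistencyError("flattening requires exactly one edge per patient")
    pat = graph.patient_features.loc[graph.edges["source"]].to_numpy(dtype=float)
    diag = graph.diagnosis_features.loc[graph.edges["target"]].to_numpy(dtype=float)
    X = np.hstack([pat, diag])
    y = graph.edges["outcome"].to_numpy(dtype=int)
    return X, y
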