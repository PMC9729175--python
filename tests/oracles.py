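"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (pairwise enumeration, dense
recursion over full neighborhoods) and shares no code with the package.
"""

import numpy as np


def auroc_bruteforce(labels, scores) -> float:
    """P(random positive outscores random negative), ties 1/2, by enumeration."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def average_precision_bruteforce(labels, scores) -> float:
    """Step-wise integral of precision over recall at each score threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    ap = 0.0
    prev_recall = 0.0
    for threshold in sorted(set(scores), reverse=True):
        called = scores >= threshold
        tp = int(((labels == 1) & called).sum())
        precision = tp / int(called.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def dense_hinsage_embedding(graph, params, node_id: str) -> np.ndarray:
    """Recursive two-layer full-neighborhood aggregation for one node.

    Independent of the package's sampled/segmented forward pass: plain
    per-node recursion over the complete neighbor multiset, ReLU on the
    hidden layer, linear output, L2 normalization.
    """
    feats = {}
    for nid, row in graph.patient_features.iterrows():
        feats[nid] = row.to_numpy(dtype=float)
    for nid, row in graph.diagnosis_features.iterrows():
        feats[nid] = row.to_numpy(dtype=float)
    nbrs = {nid: [] for nid in feats}
    for s, t in zip(graph.edges["source"], graph.edges["target"]):
        nbrs[s].append(t)
        nbrs[t].append(s)

    def h(nid: str, k: int) -> np.ndarray:
        if k == 0:
            return feats[nid]
        t = "patient" if nid.startswith("p_") else "diagnosis"
        self_part = params[f"W_self_{k}_{t}"].T @ h(nid, k - 1)
        if nbrs[nid]:
            mean_nb = np.mean([h(u, k - 1) for u in nbrs[nid]], axis=0)
        else:
            mean_nb = np.zeros(params[f"W_neigh_{k}_{t}"].shape[0])
        out = np.concatenate([self_part, params[f"W_neigh_{k}_{t}"].T @ mean_nb]) + params[f"b_{k}_{t}"]
        return np.maximum(out, 0.0) if k < 2 else out

    z = h(node_id, 2)
    return z / max(np.linalg.norm(z), 1e-12)


def cohort_membership_scan(tables, criteria) -> set:
    """Per-patient predicate scan over the raw tables (no pandas filtering).

    A patient is in the cohort iff some diagnosis row matches the index
    code on an allowed encounter inside the window, and no exclusion event
    predates the earliest such row.
    """
    import pandas as pd

    lo, hi = pd.Timestamp(criteria.window_start), pd.Timestamp(criteria.window_end)
    index_dates = {}
    for row in tables.diagnosis.itertuples(index=False):
        when = pd.Timestamp(row.diagnosis_date)
        if (
            str(row.icd10_code).startswith(criteria.index_code)
            and row.encounter_type in criteria.allowed_encounters
            and lo <= when <= hi
        ):
            prev = index_dates.get(row.patient_id)
            if prev is None or when < prev:
                index_dates[row.patient_id] = when
    members = set(index_dates)
    for row in tables.events.itertuples(index=False):
        if row.patient_id in members and row.event_type in criteria.exclusion_history:
            if pd.Timestamp(row.event_date) < index_dates[row.patient_id]:
                members.discard(row.patient_id)
    return members
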