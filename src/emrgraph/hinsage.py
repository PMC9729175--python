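"""Heterogeneous GraphSAGE (HinSAGE) for supervised link-attribute inference.

Implemented from scratch in numpy: typed neighbor sampling, two layers of
mean aggregation with node-type-specific weights, an L2-normalized
embedding, a logistic link head, manual backpropagation and Adam/SGD
optimizers.

Layer rule, for a node v of type t with sampled neighbor multiset S(v):

    h_v^k = sigma( W_self^{t,k} h_v^{k-1}  (+)  W_neigh^{t,k} mean_{u in S(v)} h_u^{k-1}  + b^{t,k} )

where (+) is concatenation along the hidden axis, sigma is ReLU on the
hidden layer and identity on the final layer, h^0 are the raw node
features, and the final embeddings are L2-normalized.  In the bipartite
patient-diagnosis graph neighbor types strictly alternate, so the
"neighbor" weight of type t consumes features of the opposite type.

The link head scores an edge (src, dst) as
``sigmoid(w . op(z_src, z_dst) + b)`` with op either concatenation
(default) or the Hadamard product; training minimizes binary cross-entropy
of this score against the edge's outcome attribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .bipartite import BipartiteGraph
from .errors import ConfigError, ConsistencyError

PATIENT, DIAGNOSIS = "patient", "diagnosis"
_OTHER = {PATIENT: DIAGNOSIS, DIAGNOSIS: PATIENT}
_EPS = 1e-12


@dataclass(frozen=True)
class SamplerConfig:
    """Per-layer neighbor sample counts and the sampling seed.

    ``exhaustive=True`` aggregates the full neighbor multiset instead of a
    fixed-size sample (used by the dense-oracle tests).
    """

    num_samples: tuple[int, ...] = (8, 4)
    seed: int = 0
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if len(self.num_samples) != 2:
            raise ConfigError("this implementation is two-layer: num_samples needs 2 entries")
        if any(k < 1 for k in self.num_samples):
            raise ConfigError("all neighbor sample counts must be >= 1")


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 200
    learning_rate: float = 1e-3
    optimizer: str = "adam"  # or "sgd"
    split: float = 0.8  # train fraction, stratified
    seed: int = 42

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not 0.0 < self.split < 1.0:
            raise ConfigError("train split fraction must lie in (0, 1)")
        if self.optimizer not in {"adam", "sgd"}:
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """Per-epoch series tracked during training (length == epochs)."""

    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def _segment_mean(flat: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Row-wise mean of consecutive segments of ``flat`` (every length >= 1)."""
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    sums = np.add.reduceat(flat, offsets, axis=0)
    return sums / lengths[:, None]


def _expand_segments(grad_mean: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Backward of :func:`_segment_mean`: spread each row over its segment."""
    return np.repeat(grad_mean / lengths[:, None], lengths, axis=0)


def link_score(z_src: np.ndarray, z_dst: np.ndarray, w: np.ndarray, b: float, operator: str = "concat") -> np.ndarray:
    """Edge probability from endpoint embeddings; strictly in (0, 1)."""
    z_src = np.atleast_2d(z_src)
    z_dst = np.atleast_2d(z_dst)
    if z_src.shape != z_dst.shape:
        raise ConsistencyError("endpoint embeddings must have identical shapes")
    if operator == "concat":
        u = np.concatenate([z_src, z_dst], axis=1)
    elif operator == "hadamard":
        u = z_src * z_dst
    else:
        raise ConfigError(f"unknown link operator {operator!r}")
    logits = u @ w + b
    return 1.0 / (1.0 + np.exp(-logits))


class HinsageLinkModel:
    """Two-layer HinSAGE with a logistic link head over a bipartite graph.

    Holds the graph's feature matrices/adjacency in positional form, the
    per-layer per-type weights, and the optimizer state.  A zero-feature
    sentinel row backs isolated nodes, so sampling never fails.
    """

    def __init__(
        self,
        graph: BipartiteGraph,
        hidden: tuple[int, int] = (32, 32),
        operator: str = "concat",
        seed: int = 42,
    ) -> None:
        if any(h % 2 for h in hidden):
            raise ConfigError("hidden sizes must be even (self/neighbor halves are concatenated)")
        self.graph = graph
        self.hidden = tuple(hidden)
        self.operator = operator

        self.X = {
            PATIENT: np.vstack(
                [graph.patient_features.to_numpy(dtype=float), np.zeros((1, graph.patient_features.shape[1]))]
            ),
            DIAGNOSIS: np.vstack(
                [graph.diagnosis_features.to_numpy(dtype=float), np.zeros((1, graph.diagnosis_features.shape[1]))]
            ),
        }
        adj_p, adj_d = graph.adjacency()
        self.adj = {PATIENT: adj_p, DIAGNOSIS: adj_d}
        self.sentinel = {PATIENT: len(adj_p), DIAGNOSIS: len(adj_d)}
        self.index = {
            PATIENT: {nid: i for i, nid in enumerate(graph.patient_features.index)},
            DIAGNOSIS: {nid: i for i, nid in enumerate(graph.diagnosis_features.index)},
        }

        dims = {PATIENT: self.X[PATIENT].shape[1], DIAGNOSIS: self.X[DIAGNOSIS].shape[1]}
        h1, h2 = self.hidden
        rng = np.random.default_rng(seed)

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        self.params: dict[str, np.ndarray] = {}
        for t in (PATIENT, DIAGNOSIS):
            o = _OTHER[t]
            self.params[f"W_self_1_{t}"] = glorot(dims[t], h1 // 2)
            self.params[f"W_neigh_1_{t}"] = glorot(dims[o], h1 // 2)
            self.params[f"b_1_{t}"] = np.zeros(h1)
            self.params[f"W_self_2_{t}"] = glorot(h1, h2 // 2)
            self.params[f"W_neigh_2_{t}"] = glorot(h1, h2 // 2)
            self.params[f"b_2_{t}"] = np.zeros(h2)
        head_dim = 2 * h2 if operator == "concat" else h2
        self.params["w_link"] = glorot(head_dim, 1)[:, 0]
        self.params["b_link"] = np.zeros(())
        self._opt_state: dict | None = None

    # ---- sampling --------------------------------------------------------
    def _sample(self, ntype: str, nodes: np.ndarray, k: int, rng, exhaustive: bool):
        """Ragged neighbor lists for ``nodes`` of type ``ntype``.

        Nodes sampled uniformly with replacement when degree < k, without
        replacement otherwise; isolated nodes (and the sentinel itself)
        yield the sentinel, whose features are all-zero.
        """
        adj = self.adj[ntype]
        sent_self = self.sentinel[ntype]
        sent_nb = self.sentinel[_OTHER[ntype]]
        lists = []
        for node in nodes:
            if node == sent_self:
                lists.append(np.array([sent_nb] * (1 if exhaustive else k), dtype=np.int64))
                continue
            nbrs = adj[node]
            if len(nbrs) == 0:
                lists.append(np.array([sent_nb] * (1 if exhaustive else k), dtype=np.int64))
            elif exhaustive:
                lists.append(nbrs)
            elif len(nbrs) == 1:
                lists.append(np.repeat(nbrs, k))
            else:
                lists.append(rng.choice(nbrs, size=k, replace=len(nbrs) < k))
        return lists

    # ---- forward / backward ---------------------------------------------
    def _forward_tree(self, nodes: np.ndarray, ntype: str, rng, exhaustive: bool, num_samples):
        """Embeddings for ``nodes`` plus the cache needed for backprop."""
        t, o = ntype, _OTHER[ntype]
        k1, k2 = num_samples
        lists1 = self._sample(t, nodes, k1, rng, exhaustive)
        lens1 = np.array([len(a) for a in lists1], dtype=np.int64)
        flat1 = np.concatenate(lists1) if lists1 else np.empty(0, dtype=np.int64)
        lists2 = self._sample(o, flat1, k2, rng, exhaustive)
        lens2 = np.array([len(a) for a in lists2], dtype=np.int64)
        flat2 = np.concatenate(lists2) if lists2 else np.empty(0, dtype=np.int64)

        P = self.params
        F0 = self.X[t][nodes]
        F1 = self.X[o][flat1]
        F2 = self.X[t][flat2]
        M1 = _segment_mean(F1, lens1)
        M2 = _segment_mean(F2, lens2)

        pre1_self = np.concatenate([F0 @ P[f"W_self_1_{t}"], M1 @ P[f"W_neigh_1_{t}"]], axis=1) + P[f"b_1_{t}"]
        h1_self = np.maximum(pre1_self, 0.0)
        pre1_nb = np.concatenate([F1 @ P[f"W_self_1_{o}"], M2 @ P[f"W_neigh_1_{o}"]], axis=1) + P[f"b_1_{o}"]
        h1_nb = np.maximum(pre1_nb, 0.0)
        # the sentinel aggregates as an all-zero vector at every layer,
        # so its hidden state must not pick up the bias through the ReLU
        sent1 = flat1 == self.sentinel[o]
        if sent1.any():
            h1_nb[sent1] = 0.0
        Mh1 = _segment_mean(h1_nb, lens1)

        h2 = np.concatenate([h1_self @ P[f"W_self_2_{t}"], Mh1 @ P[f"W_neigh_2_{t}"]], axis=1) + P[f"b_2_{t}"]
        norms = np.maximum(np.linalg.norm(h2, axis=1, keepdims=True), _EPS)
        z = h2 / norms
        cache = dict(
            t=t, o=o, F0=F0, F1=F1, M1=M1, M2=M2,
            pre1_self=pre1_self, h1_self=h1_self, pre1_nb=pre1_nb, sent1=sent1,
            Mh1=Mh1, lens1=lens1, norms=norms, z=z,
        )
        return z, cache

    def _backward_tree(self, dz: np.ndarray, cache: dict, grads: dict) -> None:
        P = self.params
        t, o = cache["t"], cache["o"]
        z, norms = cache["z"], cache["norms"]
        h2half = self.hidden[1] // 2

        dh2 = (dz - z * np.sum(z * dz, axis=1, keepdims=True)) / norms
        dA, dB = dh2[:, :h2half], dh2[:, h2half:]
        grads[f"W_self_2_{t}"] += cache["h1_self"].T @ dA
        grads[f"W_neigh_2_{t}"] += cache["Mh1"].T @ dB
        grads[f"b_2_{t}"] += dh2.sum(axis=0)
        dh1_self = dA @ P[f"W_self_2_{t}"].T
        dMh1 = dB @ P[f"W_neigh_2_{t}"].T

        h1half = self.hidden[0] // 2
        dh1_nb = _expand_segments(dMh1, cache["lens1"])
        dpre1_nb = dh1_nb * (cache["pre1_nb"] > 0.0)
        if cache["sent1"].any():
            dpre1_nb[cache["sent1"]] = 0.0
        grads[f"W_self_1_{o}"] += cache["F1"].T @ dpre1_nb[:, :h1half]
        grads[f"W_neigh_1_{o}"] += cache["M2"].T @ dpre1_nb[:, h1half:]
        grads[f"b_1_{o}"] += dpre1_nb.sum(axis=0)

        dpre1_self = dh1_self * (cache["pre1_self"] > 0.0)
        grads[f"W_self_1_{t}"] += cache["F0"].T @ dpre1_self[:, :h1half]
        grads[f"W_neigh_1_{t}"] += cache["M1"].T @ dpre1_self[:, h1half:]
        grads[f"b_1_{t}"] += dpre1_self.sum(axis=0)

    # ---- public forward paths -------------------------------------------
    def embed(self, node_ids, ntype: str, sampler: SamplerConfig = SamplerConfig(), rng=None) -> np.ndarray:
        """Final L2-normalized embeddings for prefixed node IDs of one type."""
        nodes = np.array([self.index[ntype][nid] for nid in node_ids], dtype=np.int64)
        rng = np.random.default_rng(sampler.seed) if rng is None else rng
        z, _ = self._forward_tree(nodes, ntype, rng, sampler.exhaustive, sampler.num_samples)
        return z

    def _edge_indices(self, edges) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        try:
            p = np.array([self.index[PATIENT][s] for s in edges["source"]], dtype=np.int64)
            d = np.array([self.index[DIAGNOSIS][t] for t in edges["target"]], dtype=np.int64)
        except KeyError as err:
            raise ConsistencyError(f"edge endpoint {err.args[0]!r} missing from the graph") from err
        y = edges["outcome"].to_numpy(dtype=float)
        return p, d, y

    def _forward_edges(self, p, d, rng, exhaustive, num_samples):
        zp, cp = self._forward_tree(p, PATIENT, rng, exhaustive, num_samples)
        zd, cd = self._forward_tree(d, DIAGNOSIS, rng, exhaustive, num_samples)
        if self.operator == "concat":
            u = np.concatenate([zp, zd], axis=1)
        else:
            u = zp * zd
        logits = u @ self.params["w_link"] + self.params["b_link"]
        probs = 1.0 / (1.0 + np.exp(-logits))
        return probs, (zp, cp, zd, cd, u)

    def predict(self, edges, sampler: SamplerConfig = SamplerConfig(), batch_size: int = 2048) -> np.ndarray:
        """Probability per edge; deterministic given ``sampler.seed``."""
        p, d, _ = self._edge_indices(edges)
        rng = np.random.default_rng(sampler.seed)
        out = []
        for start in range(0, len(p), batch_size):
            sl = slice(start, start + batch_size)
            probs, _ = self._forward_edges(p[sl], d[sl], rng, sampler.exhaustive, sampler.num_samples)
            out.append(probs)
        return np.concatenate(out) if out else np.empty(0)

    # ---- training --------------------------------------------------------
    def _loss_and_grads(self, p, d, y, rng, num_samples):
        probs, (zp, cp, zd, cd, u) = self._forward_edges(p, d, rng, False, num_samples)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
        acc = float(np.mean((probs >= 0.5) == y))

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        g = (probs - y) / len(y)
        grads["w_link"] += u.T @ g
        grads["b_link"] += g.sum()
        du = g[:, None] * self.params["w_link"][None, :]
        h2 = self.hidden[1]
        if self.operator == "concat":
            dzp, dzd = du[:, :h2], du[:, h2:]
        else:
            dzp, dzd = du * zd, du * zp
        self._backward_tree(dzp, cp, grads)
        self._backward_tree(dzd, cd, grads)
        return loss, acc, grads

    def _step(self, grads: dict, lr: float, optimizer: str) -> None:
        if optimizer == "sgd":
            for key, g in grads.items():
                self.params[key] = self.params[key] - lr * g
            return
        if self._opt_state is None:
            self._opt_state = {
                "t": 0,
                "m": {k: np.zeros_like(v) for k, v in self.params.items()},
                "v": {k: np.zeros_like(v) for k, v in self.params.items()},
            }
        st = self._opt_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for key, g in grads.items():
            st["m"][key] = b1 * st["m"][key] + (1 - b1) * g
            st["v"][key] = b2 * st["v"][key] + (1 - b2) * g * g
            mhat = st["m"][key] / (1 - b1 ** st["t"])
            vhat = st["v"][key] / (1 - b2 ** st["t"])
            self.params[key] = self.params[key] - lr * mhat / (np.sqrt(vhat) + eps)

    # ---- serialization ---------------------------------------------------
    def save(self, path) -> None:
        """Single-archive .npz with arrays plus a JSON manifest."""
        manifest = json.dumps(
            {
                "hidden": self.hidden,
                "operator": self.operator,
                "shapes": {k: list(np.shape(v)) for k, v in self.params.items()},
            }
        )
        np.savez(path, __manifest__=np.frombuffer(manifest.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path, graph: BipartiteGraph) -> "HinsageLinkModel":
        data = np.load(path)
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        model = cls(graph, hidden=tuple(manifest["hidden"]), operator=manifest["operator"])
        for key in model.params:
            model.params[key] = data[key]
        return model


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def sample_neighbors(graph: BipartiteGraph, seed_nodes, config: SamplerConfig = SamplerConfig()):
    """Layered neighbor samples for prefixed seed node IDs.

    Returns one list per layer; layer k holds, for every node expanded at
    that depth (in order), an array of sampled neighbor IDs.
    """
    model = HinsageLinkModel(graph, seed=0)
    rng = np.random.default_rng(config.seed)
    ids = {PATIENT: list(graph.patient_features.index), DIAGNOSIS: list(graph.diagnosis_features.index)}

    def which_type(nid: str) -> str:
        if nid in model.index[PATIENT]:
            return PATIENT
        if nid in model.index[DIAGNOSIS]:
            return DIAGNOSIS
        raise ConsistencyError(f"unknown node {nid!r}")

    layers = []
    frontier = [(which_type(nid), model.index[which_type(nid)][nid]) for nid in seed_nodes]
    for k in config.num_samples:
        layer = []
        next_frontier = []
        for ntype, node in frontier:
            o = _OTHER[ntype]
            sampled = model._sample(ntype, np.array([node]), k, rng, config.exhaustive)[0]
            named = [
                ids[o][i] if i < model.sentinel[o] else None  # None marks the sentinel
                for i in sampled
            ]
            layer.append(named)
            next_frontier.extend((o, i) for i in sampled)
        layers.append(layer)
        frontier = next_frontier
    return layers


def hinsage_forward(model: HinsageLinkModel, node_ids, ntype: str, sampler: SamplerConfig = SamplerConfig()) -> np.ndarray:
    """Final embeddings for the requested nodes (see :meth:`HinsageLinkModel.embed`)."""
    return model.embed(node_ids, ntype, sampler)


def stratified_edge_split(edges, train_fraction: float = 0.8, seed: int = 42):
    """Outcome-stratified train/test split of an edge table."""
    idx_train, idx_test = train_test_split(
        np.arange(len(edges)),
        train_size=train_fraction,
        random_state=seed,
        stratify=edges["outcome"],
    )
    return edges.iloc[np.sort(idx_train)], edges.iloc[np.sort(idx_test)]


def train_link_model(
    graph: BipartiteGraph,
    train_edges,
    val_edges,
    sampler: SamplerConfig = SamplerConfig(),
    config: TrainConfig = TrainConfig(),
    model: HinsageLinkModel | None = None,
) -> tuple[HinsageLinkModel, TrainHistory]:
    """Minibatch BCE training of the link head + HinSAGE encoder.

    Fully seeded: weight init, epoch shuffling and neighbor sampling all
    derive from ``config.seed`` / ``sampler.seed``.  Single-class training
    labels only warn (the loss stays defined).  Accuracy uses a 0.5 cutoff.
    """
    import warnings

    if model is None:
        model = HinsageLinkModel(graph, seed=config.seed)
    p_tr, d_tr, y_tr = model._edge_indices(train_edges)
    p_va, d_va, y_va = model._edge_indices(val_edges)
    if len(np.unique(y_tr)) < 2:
        warnings.warn("training labels are single-class; proceeding anyway", stacklevel=2)

    shuffle_rng = np.random.default_rng(config.seed + 1)
    sample_rng = np.random.default_rng(sampler.seed)
    history = TrainHistory()
    n = len(y_tr)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses, accs, weights = [], [], []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, acc, grads = model._loss_and_grads(
                p_tr[batch], d_tr[batch], y_tr[batch], sample_rng, sampler.num_samples
            )
            model._step(grads, config.learning_rate, config.optimizer)
            losses.append(loss)
            accs.append(acc)
            weights.append(len(batch))
        w = np.asarray(weights, dtype=float)
        history.train_loss.append(float(np.average(losses, weights=w)))
        history.train_acc.append(float(np.average(accs, weights=w)))

        val_rng = np.random.default_rng(sampler.seed + 1000 + epoch)
        probs, _ = model._forward_edges(p_va, d_va, val_rng, False, sampler.num_samples)
        eps = 1e-12
        history.val_loss.append(
            float(-np.mean(y_va * np.log(probs + eps) + (1 - y_va) * np.log(1 - probs + eps)))
        )
        history.val_acc.append(float(np.mean((probs >= 0.5) == y_va)))
    return model, history


def predict_links(
    model: HinsageLinkModel, graph: BipartiteGraph, edges, sampler: SamplerConfig = SamplerConfig()
) -> np.ndarray:
    """One probability per edge in (0, 1); deterministic given the sampler seed."""
    if model.graph is not graph:
        # allow scoring on a different (but schema-compatible) graph object
        fresh = HinsageLinkModel(graph, hidden=model.hidden, operator=model.operator)
        fresh.params = model.params
        model = fresh
    return model.predict(edges, sampler)
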