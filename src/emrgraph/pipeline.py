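"""End-to-end pipeline: generate -> cohort -> graphs -> train -> evaluate.

Every stage writes its artifact under the run directory and registers it in
``manifest.json`` (stage name, files, SHA-256 content hashes, elapsed
seconds, the seed the stage used).  A single global seed fans out to
per-stage seeds as ``seed + stage index``, so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bipartite import FeatureSchema, build_bipartite, build_features, flatten_for_baselines
from .cohort import CohortCriteria, label_outcome, select_cohort
from .errors import ConfigError
from .evaluation import compare_report, run_baselines
from .hinsage import (
    HinsageLinkModel,
    SamplerConfig,
    TrainConfig,
    predict_links,
    stratified_edge_split,
    train_link_model,
)
from .propgraph import build_property_graph, export_cypher, export_graphml
from .synthetic import GeneratorConfig, generate_emr

logger = logging.getLogger(__name__)

STAGES = [
    "tables",
    "cohort",
    "property_graph",
    "bipartite_graph",
    "model",
    "scores",
    "report",
]


@dataclass
class PipelineConfig:
    """Nested configuration of every stage plus the run directory and seed."""

    outdir: str = "run"
    seed: int = 42
    n_patients: int = 2000
    event_prevalence: float = 1.0 / 12.0
    signal_scale: float = 1.0
    bipartite_mode: str = "per_patient"
    property_graph_max_patients: int = 1000  # cap the (quadratic-artifact) export
    epochs: int = 10
    batch_size: int = 200
    learning_rate: float = 1e-3
    train_fraction: float = 0.8
    num_samples: tuple = (8, 4)
    n_boot: int = 200
    rf_trees: int = 500

    def validate(self) -> None:
        GeneratorConfig(n_patients=self.n_patients, seed=0, event_prevalence=self.event_prevalence)
        TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            split=self.train_fraction,
        )
        SamplerConfig(num_samples=tuple(self.num_samples))
        if self.bipartite_mode not in {"per_patient", "shared_diagnosis"}:
            raise ConfigError(f"unknown bipartite mode {self.bipartite_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("emrgraph")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    stage_seed = {name: config.seed + i for i, name in enumerate(STAGES)}

    def record(stage: str, files: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed[stage],
            "elapsed_s": round(time.time() - t0, 3),
            "files": {str(f.relative_to(outdir)): _sha256(f) for f in files},
        }
        logger.info("stage %s done (%.2fs)", stage, time.time() - t0)

    try:
        t0 = time.time()
        gen_cfg = GeneratorConfig(
            n_patients=config.n_patients,
            seed=stage_seed["tables"],
            event_prevalence=config.event_prevalence,
            signal_scale=config.signal_scale,
        )
        tables = generate_emr(gen_cfg)
        tables_dir = outdir / "tables"
        tables.to_csv_dir(tables_dir)
        record("tables", sorted(tables_dir.glob("*.csv")), t0)

        t0 = time.time()
        cohort = label_outcome(select_cohort(tables, CohortCriteria()), tables.events)
        cohort_path = outdir / "cohort.csv"
        out = cohort.copy()
        out["index_date"] = out["index_date"].dt.strftime("%Y-%m-%d")
        out.to_csv(cohort_path, index=False)
        record("cohort", [cohort_path], t0)

        t0 = time.time()
        pg_cohort = cohort.head(config.property_graph_max_patients)
        pg = build_property_graph(tables.restrict(pg_cohort["patient_id"]), pg_cohort)
        pg_dir = outdir / "property_graph"
        files = export_cypher(pg, pg_dir)
        graphml = pg_dir / "graph.graphml"
        export_graphml(pg, graphml)
        record("property_graph", files + [graphml], t0)

        t0 = time.time()
        schema = FeatureSchema()
        from sklearn.model_selection import train_test_split

        train_pids, _ = train_test_split(
            cohort["patient_id"].to_numpy(),
            train_size=config.train_fraction,
            random_state=stage_seed["bipartite_graph"],
            stratify=cohort["outcome"],
        )
        pat_m, diag_m = build_features(cohort, tables, schema, train_ids=train_pids)
        graph = build_bipartite(cohort, pat_m, diag_m, mode=config.bipartite_mode)
        bg_dir = outdir / "bipartite_graph"
        graph.to_csv_dir(bg_dir)
        record("bipartite_graph", sorted(bg_dir.glob("*.csv")), t0)

        t0 = time.time()
        train_sources = {f"p_{pid}" for pid in train_pids}
        in_train = graph.edges["source"].isin(train_sources)
        train_edges, test_edges = graph.edges[in_train], graph.edges[~in_train]
        sampler = SamplerConfig(num_samples=tuple(config.num_samples), seed=stage_seed["model"])
        tcfg = TrainConfig(
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            split=config.train_fraction,
            seed=stage_seed["model"],
        )
        model, history = train_link_model(graph, train_edges, test_edges, sampler, tcfg)
        model_path = outdir / "model.npz"
        model.save(model_path)
        hist_path = outdir / "history.json"
        hist_path.write_text(json.dumps(asdict(history), indent=1), encoding="utf-8")
        record("model", [model_path, hist_path], t0)

        t0 = time.time()
        hinsage_scores = predict_links(model, graph, test_edges, sampler)
        X, y = flatten_for_baselines(graph)
        pos = {pid: i for i, pid in enumerate(graph.edges["source"])}
        train_idx = np.array([pos[s] for s in train_edges["source"]])
        test_idx = np.array([pos[s] for s in test_edges["source"]])
        base = run_baselines(X, y, train_idx, test_idx, seed=stage_seed["scores"], rf_trees=config.rf_trees)
        scores_path = outdir / "scores.csv"
        import pandas as pd

        frame = pd.DataFrame(
            {"patient": test_edges["source"].to_numpy(), "outcome": y[test_idx], "HinSAGE": hinsage_scores, **base}
        )
        frame.to_csv(scores_path, index=False)
        record("scores", [scores_path], t0)

        t0 = time.time()
        y_test = y[test_idx]
        model_scores = {"RF": (y_test, base["RF"]), "ANN": (y_test, base["ANN"]),
                        "HinSAGE": (y_test, hinsage_scores), "LR": (y_test, base["LR"])}
        report_dir = outdir / "report"
        compare_report(model_scores, report_dir, n_boot=config.n_boot, seed=stage_seed["report"])
        record("report", sorted(report_dir.iterdir()), t0)
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
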