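"""Model evaluation: AUROC/AUPRC with bootstrap CIs, baselines, reports.

AUROC follows the Mann-Whitney formulation (probability a random positive
outscores a random negative, ties counted 1/2); AUPRC is average precision.
Confidence intervals are stratified percentile bootstraps: positives and
negatives are resampled separately so no resample can lose a class.

Baselines mirror common tabular practice on the flattened patient+diagnosis
feature matrix: a 500-tree random forest, L2-regularized logistic
regression (standardized inputs), and a two-hidden-layer neural network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import MetricError


def _check_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise MetricError("labels and scores must be aligned")
    if not np.isfinite(scores).all():
        raise MetricError("scores must be finite")
    return labels, scores


def auroc(labels, scores) -> float:
    """Area under the ROC curve; requires both classes present."""
    labels, scores = _check_scores(labels, scores)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUROC is undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Average precision (step-wise precision-recall integral)."""
    labels, scores = _check_scores(labels, scores)
    if not (np.asarray(labels) == 1).any():
        raise MetricError("AUPRC is undefined without positives")
    return float(average_precision_score(labels, scores))


def bootstrap_ci(
    metric, labels, scores, n_boot: int = 1000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for a (labels, scores) metric."""
    labels, scores = _check_scores(labels, scores)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels != 1)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        stats[b] = metric(labels[take], scores[take])
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class ModelResult:
    name: str
    labels: np.ndarray
    scores: np.ndarray
    auroc: float = 0.0
    auroc_ci: tuple = (0.0, 0.0)
    auprc: float = 0.0
    auprc_ci: tuple = (0.0, 0.0)
    roc_points: tuple = ()  # (fpr array, tpr array)


@dataclass
class EvalReport:
    """Comparison table inputs plus per-model curves and distributions."""

    results: list[ModelResult] = field(default_factory=list)
    n_test: int = 0
    n_positive: int = 0

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "model": r.name,
                "AUROC": round(r.auroc, 3),
                "AUROC_CI_low": round(r.auroc_ci[0], 3),
                "AUROC_CI_high": round(r.auroc_ci[1], 3),
                "AUPRC": round(r.auprc, 3),
                "AUPRC_CI_low": round(r.auprc_ci[0], 3),
                "AUPRC_CI_high": round(r.auprc_ci[1], 3),
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = ["| Model | AUROC (95% CI) | AUPRC (95% CI) |", "|---|---|---|"]
        for r in self.results:
            lines.append(
                f"| {r.name} | {r.auroc:.2f} [{r.auroc_ci[0]:.2f}, {r.auroc_ci[1]:.2f}] "
                f"| {r.auprc:.2f} [{r.auprc_ci[0]:.2f}, {r.auprc_ci[1]:.2f}] |"
            )
        return "\n".join(lines)


def run_baselines(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int = 42,
    rf_trees: int = 500,
) -> dict[str, np.ndarray]:
    """Held-out probability scores for RF / LR / ANN on a shared split."""
    if len(np.unique(y[train_idx])) < 2:
        raise MetricError("training split is single-class; baselines cannot be fit")
    models = {
        "RF": RandomForestClassifier(n_estimators=rf_trees, random_state=seed, n_jobs=1),
        "LR": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
        ),
        "ANN": make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(32, 32), max_iter=300, random_state=seed, early_stopping=False
            ),
        ),
    }
    scores = {}
    for name, model in models.items():
        model.fit(X[train_idx], y[train_idx])
        scores[name] = model.predict_proba(X[test_idx])[:, 1]
    return scores


def compare_report(
    model_scores: dict[str, tuple[np.ndarray, np.ndarray]],
    outdir=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Metrics + CIs per model; optionally writes table and figures.

    ``model_scores`` maps model name -> (labels, scores) on the held-out
    split.  When ``outdir`` is given, writes ``table.csv``, ``table.md``,
    ``roc_curves.png`` and ``outcome_distribution.png`` (0.5 threshold).
    """
    if not model_scores:
        raise MetricError("at least one model result is required")
    report = EvalReport()
    for name, (labels, scores) in model_scores.items():
        res = ModelResult(name, np.asarray(labels), np.asarray(scores, dtype=float))
        res.auroc = auroc(labels, scores)
        res.auroc_ci = bootstrap_ci(auroc, labels, scores, n_boot=n_boot, seed=seed)
        res.auprc = auprc(labels, scores)
        res.auprc_ci = bootstrap_ci(auprc, labels, scores, n_boot=n_boot, seed=seed)
        fpr, tpr, _ = roc_curve(labels, scores)
        res.roc_points = (fpr, tpr)
        report.results.append(res)
    first = report.results[0]
    report.n_test = len(first.labels)
    report.n_positive = int((first.labels == 1).sum())

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.table().to_csv(outdir / "table.csv", index=False)
        (outdir / "table.md").write_text(report.to_markdown() + "\n", encoding="utf-8")

        fig, ax = plt.subplots(figsize=(5, 5))
        for res in report.results:
            fpr, tpr = res.roc_points
            ax.plot(fpr, tpr, label=f"{res.name} (AUROC {res.auroc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate (1 - specificity)")
        ax.set_ylabel("True positive rate (sensitivity)")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(outdir / "roc_curves.png", dpi=120)
        plt.close(fig)

        fig, axes = plt.subplots(1, len(report.results), figsize=(4 * len(report.results), 3.2), squeeze=False)
        for ax, res in zip(axes[0], report.results):
            true_counts = [int((res.labels == 0).sum()), int((res.labels == 1).sum())]
            pred = (res.scores >= 0.5).astype(int)
            pred_counts = [int((pred == 0).sum()), int((pred == 1).sum())]
            x = np.arange(2)
            ax.bar(x - 0.18, true_counts, width=0.36, label="true")
            ax.bar(x + 0.18, pred_counts, width=0.36, label="predicted")
            ax.set_xticks(x, ["0", "1"])
            ax.set_title(res.name)
            ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "outcome_distribution.png", dpi=120)
        plt.close(fig)
    return report
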