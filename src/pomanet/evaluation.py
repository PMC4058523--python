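"""Biomarker evaluation: per-miRNA ROC analysis and hierarchical clustering
of samples on candidate-miRNA expression.

ROC curves are oriented by each miRNA's differential-expression direction
(a down-regulated miRNA scores cases by *low* expression) rather than by
auto-flipping to AUC >= 0.5, avoiding optimistic bias.  AUC follows the
rank / Mann–Whitney formulation with midrank tie handling; the reported
operating point maximizes Youden's J = sensitivity + specificity − 1, with
sensitivity, specificity and accuracy quoted at that threshold.

Clustering mirrors the standard expression-heatmap recipe: per-feature
z-scoring, Euclidean distance between samples, complete linkage, cut into
two groups; agreement with the case/control labels is the best accuracy
over the two possible group-to-class assignments (hence always in [0.5, 1]).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn import metrics

from .data_io import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    mirna_id: str
    auc: float
    threshold: float  # on the original expression scale
    sensitivity: float
    specificity: float
    accuracy: float
    curve: pd.DataFrame = field(repr=False)  # columns: threshold, fpr, tpr


def evaluate_roc(
    scores, labels, direction: str = "up", mirna_id: str = ""
) -> RocResult:
    """ROC/AUC of one miRNA's expression as a case-vs-control classifier.

    ``direction`` is the miRNA's outlier direction: "up" means higher
    expression indicates case; "down" flips the orientation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == "case"
    if y.all() or not y.any():
        raise ValueError("both classes must be present for ROC analysis")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    s = scores if direction == "up" else -scores
    if np.ptp(s) == 0:
        # constant scores: flat diagonal curve, chance AUC by the midrank convention
        auc = 0.5
    else:
        auc = float(metrics.roc_auc_score(y, s))
    fpr, tpr, thr = metrics.roc_curve(y, s, drop_intermediate=False)
    j = tpr - fpr
    idx = int(np.argmax(j))  # first maximizer -> most stringent threshold
    thr_star = thr[idx]
    pred = s >= thr_star
    accuracy = float(np.mean(pred == y))
    thr_orig = thr_star if direction == "up" else -thr_star
    curve = pd.DataFrame(
        {"threshold": thr if direction == "up" else -thr, "fpr": fpr, "tpr": tpr}
    )
    return RocResult(
        mirna_id=mirna_id,
        auc=auc,
        threshold=float(thr_orig),
        sensitivity=float(tpr[idx]),
        specificity=float(1.0 - fpr[idx]),
        accuracy=accuracy,
        curve=curve,
    )


@dataclass
class ClusteringResult:
    sample_ids: list
    linkage: np.ndarray  # scipy linkage matrix (merge order + heights)
    assignments: np.ndarray  # group 1/2 per sample
    agreement: float  # max-matching accuracy vs class labels


def cluster_samples(
    m: ExpressionMatrix, ann: SampleAnnotation
) -> ClusteringResult:
    """Hierarchical clustering of samples on (candidate) feature expression.

    Rows are z-scored (zero-variance rows contribute zeros), samples are
    clustered with Euclidean distance and complete linkage, and the tree is
    cut into 2 groups.
    """
    if m.n_features < 2:
        raise ValueError("cluster_samples requires >= 2 features")
    if m.n_samples < 3:
        raise ValueError("cluster_samples requires >= 3 samples")
    Z = zscore_rows(m.values)
    X = Z.T  # samples × features
    link = hierarchy.linkage(X, method="complete", metric="euclidean")
    groups = hierarchy.fcluster(link, t=2, criterion="maxclust")
    labels = ann.labels_for(m.sample_ids)
    acc1 = np.mean((groups == 1) == (labels == "case"))
    acc2 = np.mean((groups == 2) == (labels == "case"))
    return ClusteringResult(
        sample_ids=list(m.sample_ids),
        linkage=link,
        assignments=groups,
        agreement=float(max(acc1, acc2)),
    )


def zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def evaluation_summary(roc_results: list[RocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "auc": r.auc,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "accuracy": r.accuracy,
            }
            for r in roc_results
        ],
        columns=["mirna_id", "auc", "sensitivity", "specificity", "accuracy"],
    )


def _safe_name(s: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", s)


def report(
    candidates: pd.DataFrame,
    roc_results: list[RocResult],
    clustering: ClusteringResult | None,
    out_dir,
    expr: ExpressionMatrix | None = None,
    ann: SampleAnnotation | None = None,
    make_plots: bool = False,
) -> list:
    """Write the evaluation artifacts; returns the written paths.

    Files: candidates.tsv, evaluation_summary.tsv, roc_<mirna>.tsv per
    candidate, clustering_assignments.tsv, evaluation_report.txt (ranges in
    min–max form), optional roc_curves.png / heatmap.png.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "candidates.tsv"
    candidates.to_csv(p, sep="\t", index=False)
    written.append(p)

    summ = evaluation_summary(roc_results)
    p = out / "evaluation_summary.tsv"
    summ.to_csv(p, sep="\t", index=False)
    written.append(p)

    for r in roc_results:
        p = out / f"roc_{_safe_name(r.mirna_id)}.tsv"
        r.curve.to_csv(p, sep="\t", index=False)
        written.append(p)

    if clustering is not None:
        p = out / "clustering_assignments.tsv"
        pd.DataFrame(
            {"sample_id": clustering.sample_ids, "cluster": clustering.assignments}
        ).to_csv(p, sep="\t", index=False)
        written.append(p)

    lines = [f"candidates\t{len(roc_results)}"]
    if roc_results:
        lines.append(
            f"auc_range\t{summ['auc'].min():.3f}-{summ['auc'].max():.3f}"
        )
        lines.append(
            "accuracy_range\t"
            f"{100 * summ['accuracy'].min():.1f}%-{100 * summ['accuracy'].max():.1f}%"
        )
    else:
        lines.append("note\t0 candidates; ROC and clustering skipped")
    if clustering is not None:
        lines.append(f"clustering_agreement\t{clustering.agreement:.3f}")
    p = out / "evaluation_report.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)

    if make_plots and roc_results:
        written += _plots(roc_results, clustering, expr, ann, out)
    return written


def _plots(roc_results, clustering, expr, ann, out):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, ax = plt.subplots(figsize=(5, 5))
    for r in roc_results:
        ax.plot(r.curve["fpr"], r.curve["tpr"], lw=1,
                label=f"{r.mirna_id} (AUC={r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=6, loc="lower right")
    p = out / "roc_curves.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    if expr is not None and ann is not None and expr.n_features >= 2:
        import seaborn as sns

        labels = ann.labels_for(expr.sample_ids)
        col_colors = ["firebrick" if l == "case" else "seagreen" for l in labels]
        cg = sns.clustermap(
            pd.DataFrame(zscore_rows(expr.values), index=expr.feature_ids,
                         columns=expr.sample_ids),
            method="complete", metric="euclidean", col_colors=col_colors,
            cmap="RdBu_r", figsize=(7, 5),
        )
        p = out / "heatmap.png"
        cg.savefig(p, dpi=120)
        import matplotlib.pyplot as plt2

        plt2.close("all")
        written.append(p)
    return written
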