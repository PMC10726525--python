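"""Downstream analyses of predicted response matrices.

Mirrors the model's two application workflows: ranking drugs by the median
of their predicted LN IC50 across samples (most/least effective candidates),
and hierarchically clustering samples by Euclidean distance on (optionally
Z-scored) predictions, then summarising pathway activity per cluster —
e.g. proliferation-related pathway scores explaining why one cluster is
more drug-sensitive than another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pathway_features import PathwayScoreMatrix
from .response_scaling import zscore

LINKAGE_METHODS = ("complete", "average", "ward")


@dataclass
class PredictionMatrix:
    """Samples × drugs matrix of predicted LN IC50 with labelled axes."""

    values: np.ndarray
    sample_ids: list[str]
    drug_ids: list[str]
    metadata: pd.DataFrame | None = None  # indexed by sample_id (group labels etc.)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.drug_ids)):
            raise ValueError("prediction matrix shape does not match id axes")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("prediction matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.drug_ids)


@dataclass
class ClusterResult:
    labels: dict[str, int]  # sample_id → cluster index in 1..k
    linkage: np.ndarray = field(repr=False)
    k: int = 3
    metric: str = "euclidean"
    method: str = "complete"

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster]


def rank_drugs_by_median(pred: PredictionMatrix) -> pd.DataFrame:
    """Drugs in ascending order of median predicted LN IC50 (ties: drug id).

    The head of the ranking is the most effective candidates (lowest
    predicted LN IC50), the tail the least effective.
    """
    if pred.values.size == 0:
        raise ValueError("empty prediction matrix")
    medians = np.median(pred.values, axis=0)
    df = pd.DataFrame({"drug_id": pred.drug_ids, "median_ln_ic50": medians})
    return df.sort_values(["median_ln_ic50", "drug_id"], kind="mergesort").reset_index(drop=True)


def top_drugs(ranking: pd.DataFrame, n: int = 6, lowest: bool = True) -> pd.DataFrame:
    """Head/tail of the ranking: n lowest (default) or n highest medians."""
    return (ranking.head(n) if lowest else ranking.tail(n)).reset_index(drop=True)


def hierarchical_cluster(
    pred: PredictionMatrix,
    k: int,
    zscore_first: bool = True,
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of samples on Euclidean distances.

    With ``zscore_first`` each drug column is standardised (mean 0, sd 1)
    before computing distances, so drugs with large LN IC50 spread do not
    dominate.  Cluster indices are relabelled so cluster 1 has the highest
    mean prediction (most resistant) and cluster k the lowest.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(pred.sample_ids):
        raise ValueError("k exceeds the number of samples")
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}")
    values = zscore(pred.values, axis="columns") if zscore_first else pred.values
    Z = hierarchy.linkage(pdist(values, metric="euclidean"), method=method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # order clusters by descending mean prediction: 1 = most resistant
    means = {c: pred.values[raw == c].mean() for c in np.unique(raw)}
    order = sorted(means, key=lambda c: -means[c])
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = {s: remap[c] for s, c in zip(pred.sample_ids, raw)}
    return ClusterResult(labels=labels, linkage=Z, k=int(len(order)), method=method)


def summarize_cluster_pathways(
    clusters: ClusterResult,
    scores: PathwayScoreMatrix,
    pathway_subset: list[str],
) -> pd.DataFrame:
    """Per-cluster distribution of the subset's scores, pooled over samples
    and pathways — the table behind a per-cluster boxplot."""
    unknown = sorted(set(pathway_subset) - set(scores.pathway_ids))
    if unknown:
        raise ValueError(f"unknown pathway name(s): {unknown}")
    missing = sorted(set(clusters.labels) - set(scores.cell_line_ids))
    if missing:
        raise ValueError(f"clustered sample(s) missing from score matrix: {missing}")
    rows = []
    p_idx = [scores.pathway_ids.index(p) for p in pathway_subset]
    for c in sorted(set(clusters.labels.values())):
        samples = clusters.members(c)
        s_idx = [scores.cell_line_ids.index(s) for s in samples]
        pool = scores.values[np.ix_(p_idx, s_idx)].ravel()
        rows.append(
            {
                "cluster": c,
                "n_samples": len(samples),
                "n_values": pool.size,
                "mean": pool.mean(),
                "median": np.median(pool),
                "q1": np.percentile(pool, 25),
                "q3": np.percentile(pool, 75),
            }
        )
    return pd.DataFrame(rows)


def render_reports(
    pred: PredictionMatrix,
    ranking: pd.DataFrame,
    clusters: ClusterResult,
    summaries: pd.DataFrame,
    out_dir: str | Path,
) -> list[Path]:
    """Write ranking CSV, cluster CSV, prediction heatmap and pathway boxplot."""
    if pred.values.size == 0:
        raise ValueError("empty prediction matrix; nothing to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    p = out_dir / "drug_ranking.csv"
    ranking.to_csv(p, index=False)
    paths.append(p)

    p = out_dir / "cluster_assignment.csv"
    pd.DataFrame(
        {"sample_id": list(clusters.labels), "cluster": list(clusters.labels.values())}
    ).to_csv(p, index=False)
    paths.append(p)

    # heatmap ordered by the clustering dendrogram
    order = hierarchy.leaves_list(clusters.linkage)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(pred.values[order], aspect="auto", cmap="coolwarm")
    ax.set_xlabel("drugs")
    ax.set_ylabel("samples (dendrogram order)")
    ax.set_title("Predicted LN IC50")
    fig.colorbar(im, ax=ax, label="LN IC50")
    p = out_dir / "prediction_heatmap.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(summaries["cluster"], summaries["mean"],
           yerr=(summaries["q3"] - summaries["q1"]) / 2, capsize=4)
    ax.set_xlabel("cluster")
    ax.set_ylabel("pathway score (mean ± IQR/2)")
    ax.set_title("Pathway-subset activity per cluster")
    p = out_dir / "cluster_pathway_boxplot.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
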