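"""juDGE analysis: junction logFC versus gene logFC.

Each point pairs one junction's log2 fold change (y) with its gene's
log2 fold change (x), so all junctions of a gene share an x coordinate.
The juDGE score, stdev(x)/stdev(y), summarizes whether a treatment acts
mostly on splicing (tall, narrow cloud; low score) or on expression
(wide cloud; high score). The module also clusters comparisons by their
feature-level logFC vectors, restricted to features significant in at
least one comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class JudgeSummary:
    score: float | None  # None when stdev_y == 0 (undefined, not infinity)
    n_points: int
    stdev_x: float
    stdev_y: float


def judge_points(junction_results: pd.DataFrame,
                 gene_results: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Join junction and gene logFC into plot points.

    Returns (points, n_dropped) where points has columns junction_id,
    gene_id, x (gene logFC), y (junction logFC); junctions whose gene is
    absent from the gene table are dropped and counted.
    """
    if junction_results.empty:
        return pd.DataFrame(columns=["junction_id", "gene_id", "x", "y"]), 0
    gene_lfc = gene_results.set_index("feature_id")["logFC"]
    jr = junction_results.rename(columns={"feature_id": "junction_id",
                                          "logFC": "y"})
    jr = jr[["junction_id", "gene_id", "y"]].copy()
    jr["x"] = jr["gene_id"].map(gene_lfc)
    dropped = int(jr["x"].isna().sum())
    if dropped:
        logger.warning("judge_points: %d junctions dropped (gene missing from "
                       "gene results)", dropped)
    points = jr.dropna(subset=["x"])[["junction_id", "gene_id", "x", "y"]]
    if points.empty:
        logger.warning("judge_points: empty junction/gene intersection")
    return points.reset_index(drop=True), dropped


def judge_score(points: pd.DataFrame) -> JudgeSummary:
    """Population stdev of x over population stdev of y.

    A score near 0 means variation is almost entirely at the junction
    (splicing) level. Undefined (score None) when all y are equal.
    """
    if len(points) < 2:
        raise ValueError("judge_score needs at least 2 points")
    sx = float(np.std(points["x"].to_numpy()))  # population (ddof=0)
    sy = float(np.std(points["y"].to_numpy()))
    score = None if sy == 0 else sx / sy
    return JudgeSummary(score=score, n_points=len(points), stdev_x=sx, stdev_y=sy)


def cluster_comparisons(logfc: pd.DataFrame, fdr: pd.DataFrame,
                        fdr_cutoff: float = 0.05
                        ) -> tuple[list[str], np.ndarray, pd.DataFrame, str]:
    """Hierarchically cluster comparisons on significant-feature logFC.

    ``logfc`` and ``fdr`` are comparisons x features frames with equal
    shape and labels. Features with fdr < *fdr_cutoff* in at least one
    comparison are kept; comparisons are clustered on the filtered logFC
    vectors with correlation distance (1 - Pearson r) and average
    linkage. Comparison rows are sorted by name first so merge-order
    ties break lexicographically.

    Returns (leaf-ordered comparison names, linkage matrix, filtered
    logFC frame, newick-like nesting string).
    """
    if logfc.shape[0] < 2:
        raise ValueError("need at least 2 comparisons to cluster")
    if logfc.shape != fdr.shape:
        raise ValueError("logfc and fdr matrices must have identical shape")
    keep = (fdr < fdr_cutoff).any(axis=0)
    if not keep.any():
        raise ValueError(
            f"no feature passes the significance filter (fdr < {fdr_cutoff} "
            "in at least one comparison)")
    filtered = logfc.loc[sorted(logfc.index), keep]
    dist = pdist(filtered.to_numpy(), metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)  # constant vectors: treat as uncorrelated
    linkage = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(linkage)
    names = [filtered.index[i] for i in leaves]
    newick = _linkage_to_newick(linkage, list(filtered.index))
    return names, linkage, filtered, newick


def pairwise_correlation_distance(logfc: pd.DataFrame) -> pd.DataFrame:
    """Comparisons x comparisons matrix of 1 - Pearson r (brute-force view)."""
    d = squareform(np.nan_to_num(pdist(logfc.to_numpy(), metric="correlation"), nan=1.0))
    return pd.DataFrame(d, index=logfc.index, columns=logfc.index)


def _linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    for i, (a, b, height, _cnt) in enumerate(linkage):
        nodes[n + i] = f"({nodes[int(a)]},{nodes[int(b)]}):{height:.6g}"
    return nodes[n + len(linkage) - 1] + ";"


def write_judge_tsv(path, points: pd.DataFrame, summary: JudgeSummary) -> None:
    with open(path, "w") as fh:
        score = "NA" if summary.score is None else f"{summary.score:.6g}"
        fh.write(f"# score={score}\tn={summary.n_points}\t"
                 f"stdev_x={summary.stdev_x:.6g}\tstdev_y={summary.stdev_y:.6g}\n")
        points.to_csv(fh, sep="\t", index=False)


def plot_judge(path, points: pd.DataFrame, summary: JudgeSummary,
               title: str = "juDGE") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(points["x"], points["y"], s=4, alpha=0.4, color="#1f6fb4",
               edgecolors="none")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("gene logFC")
    ax.set_ylabel("junction logFC")
    score = "undefined" if summary.score is None else f"{summary.score:.3g}"
    ax.set_title(f"{title} (score = {score}, n = {summary.n_points})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
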