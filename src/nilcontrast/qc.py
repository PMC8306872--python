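"""Quality control: replicate correlation and unsupervised sample clustering.

Both views run on log2(FPKM + 1). Pearson correlation between biological
replicates of the same design cell is the sequencing-quality readout (the
study's accepted range was roughly 0.94–0.995); hierarchical clustering of
samples reveals the dominant axis of variation — in this design the cadmium
treatment, which splits the dendrogram's two top branches into control vs
treated samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import ExpressionMatrix


@dataclass
class CorrelationReport:
    """All within-condition replicate-pair Pearson correlations."""

    pairs: pd.DataFrame  # sample_a, sample_b, genotype, treatment, r
    min_r: float
    max_r: float

    def values(self) -> np.ndarray:
        return self.pairs["r"].to_numpy(float)


@dataclass
class ClusterResult:
    """Deterministic two-way hierarchical clustering of the expression matrix."""

    column_order: list[int]
    row_order: list[int]
    column_linkage: np.ndarray
    row_linkage: np.ndarray
    clustered_contigs: list[str]
    sample_ids: list[str]
    distance_columns: str = "euclidean (z-scored log2(FPKM+1))"
    distance_rows: str = "1 - Pearson"
    linkage_method: str = "average"

    def ordered_samples(self) -> list[str]:
        return [self.sample_ids[i] for i in self.column_order]

    def column_partition(self, k: int = 2) -> list[set[str]]:
        """Sample-id groups from cutting the column dendrogram into k clusters."""
        flat = hierarchy.fcluster(self.column_linkage, t=k, criterion="maxclust")
        return [
            {sid for sid, c in zip(self.sample_ids, flat) if c == lab}
            for lab in sorted(set(flat))
        ]


def replicate_correlation(matrix: ExpressionMatrix) -> CorrelationReport:
    """Pearson r of log2(FPKM + 1) for every within-condition replicate pair.

    A zero-variance sample leaves its pairs' r undefined; those are reported
    as NaN with a warning and excluded from the min/max summary.
    """
    log = np.log2(matrix.values.to_numpy(float) + 1.0)
    cols = {s.sample_id: i for i, s in enumerate(matrix.samples)}
    records = []
    for g, t in matrix.conditions():
        ids = [s.sample_id for s in matrix.samples_for(g, t)]
        if len(ids) < 2:
            raise ValueError(f"condition ({g}, {t}) needs >= 2 replicates for QC")
        for a, b in combinations(ids, 2):
            x, y = log[:, cols[a]], log[:, cols[b]]
            if x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"zero-variance sample in pair ({a}, {b}); correlation undefined",
                    RuntimeWarning,
                    stacklevel=2,
                )
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            records.append({"sample_a": a, "sample_b": b,
                            "genotype": g, "treatment": t, "r": r})
    pairs = pd.DataFrame(records)
    finite = pairs["r"].dropna()
    return CorrelationReport(
        pairs=pairs,
        min_r=float(finite.min()) if len(finite) else float("nan"),
        max_r=float(finite.max()) if len(finite) else float("nan"),
    )


def cluster_heatmap(matrix: ExpressionMatrix) -> ClusterResult:
    """Two-way average-linkage clustering of the log2(FPKM + 1) matrix.

    Genes are z-scored across samples; zero-variance genes are dropped from
    clustering. Columns (samples) use Euclidean distance on the z-scores,
    rows (genes) use 1 − Pearson correlation. Deterministic given input
    order.
    """
    if matrix.n_samples < 2:
        raise ValueError("clustering needs >= 2 samples")
    log = np.log2(matrix.values.to_numpy(float) + 1.0)
    sd = log.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("no gene has non-zero variance; nothing to cluster")
    z = (log[keep] - log[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    contigs = [c for c, k in zip(matrix.contig_ids, keep) if k]

    col_linkage = hierarchy.linkage(pdist(z.T, metric="euclidean"), method="average")
    col_order = list(hierarchy.leaves_list(col_linkage))

    if len(contigs) >= 2:
        row_dist = pdist(z, metric="correlation")  # 1 - Pearson
        row_linkage = hierarchy.linkage(np.clip(row_dist, 0, None), method="average")
        row_order = list(hierarchy.leaves_list(row_linkage))
    else:
        row_linkage = np.empty((0, 4))
        row_order = [0] * len(contigs) if contigs else []

    return ClusterResult(
        column_order=col_order,
        row_order=row_order,
        column_linkage=col_linkage,
        row_linkage=row_linkage,
        clustered_contigs=contigs,
        sample_ids=[s.sample_id for s in matrix.samples],
    )


def plot_heatmap(matrix: ExpressionMatrix, result: ClusterResult, path) -> None:
    """Optional rendering of the clustered matrix (the testable artifact is
    the ClusterResult itself)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    log = np.log2(matrix.values.loc[result.clustered_contigs].to_numpy(float) + 1.0)
    z = (log - log.mean(axis=1, keepdims=True)) / log.std(axis=1, keepdims=True)
    ordered = z[np.ix_(result.row_order, result.column_order)]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(ordered, aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(result.column_order)))
    ax.set_xticklabels(result.ordered_samples(), rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(result.clustered_contigs)} contigs (clustered)")
    fig.colorbar(im, ax=ax, label="z-scored log2(FPKM+1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_correlation_table(report: CorrelationReport, path) -> None:
    report.pairs.to_csv(path, sep="\t", index=False)
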