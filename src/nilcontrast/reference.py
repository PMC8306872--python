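"""Reference-gene candidates for qRT-PCR normalisation.

Stably expressed contigs are ranked by coefficient of variation (CV =
sample sd / mean) computed across ALL samples — both genotypes and both
treatments — because a normalisation gene must be stable across every
condition of the experiment. Only contigs whose overall mean FPKM exceeds
``min_mean`` (default 25) are considered, so low-abundance genes with
unstable ratios never rank.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix


def coefficient_of_variation(values) -> float:
    """Sample-sd (n−1) over mean; needs >= 2 values and a positive mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean)


def rank_reference_candidates(
    matrix: ExpressionMatrix, min_mean: float = 25.0, top_k: int = 3
) -> pd.DataFrame:
    """Top-k lowest-CV contigs among those with overall mean FPKM > min_mean.

    Ties on CV break lexicographically by contig id. Returns a DataFrame with
    columns ``contig_id, mean_fpkm, cv, rank`` (empty, not an error, when no
    contig passes the abundance gate).
    """
    if matrix.n_samples < 2:
        raise ValueError("reference ranking needs >= 2 samples")
    arr = matrix.values.to_numpy(float)
    mean = arr.mean(axis=1)
    keep = mean > min_mean
    if not keep.any():
        return pd.DataFrame(columns=["contig_id", "mean_fpkm", "cv", "rank"])
    sd = arr[keep].std(axis=1, ddof=1)
    out = pd.DataFrame(
        {
            "contig_id": np.asarray(matrix.contig_ids)[keep],
            "mean_fpkm": mean[keep],
            "cv": sd / mean[keep],
        }
    )
    out = out.sort_values(["cv", "contig_id"], kind="mergesort").head(top_k)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def write_reference_table(candidates: pd.DataFrame, path) -> None:
    candidates.to_csv(path, sep="\t", index=False)
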