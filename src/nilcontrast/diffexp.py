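"""Fold changes, Welch t-tests, Benjamini–Hochberg FDR and DEG flags.

A contig is called differentially expressed (DEG) between two conditions when

* the BH-adjusted two-sided Welch p-value (q) is below ``q_threshold``
  (default 0.001),
* the condition-mean fold change reaches ``fc_threshold`` in either direction
  (default 2, inclusive), and
* the FPKM level reaches ``min_fpkm`` (default 5) in at least one of the two
  conditions.

The Welch test runs on log2(FPKM + 1)-transformed replicate values by default
(variance stabilisation; raw-scale testing is available via
``log_transform=False``), whereas fold changes are always ratios of raw
condition means with a floored denominator so that zero-expression baselines
yield large finite ratios instead of infinities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataModelError, ExpressionMatrix

DEFAULT_Q = 0.001
DEFAULT_FC = 2.0
DEFAULT_MIN_FPKM = 5.0
DEFAULT_FLOOR = 0.01


def fold_change(mean_ref: float, mean_alt: float, floor: float = DEFAULT_FLOOR) -> float:
    """``mean_alt / max(mean_ref, floor)``; means must be non-negative."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if mean_ref < 0 or mean_alt < 0:
        raise ValueError("FPKM means must be non-negative")
    return mean_alt / max(mean_ref, floor)


def fold_change_vector(mean_ref: np.ndarray, mean_alt: np.ndarray,
                       floor: float = DEFAULT_FLOOR) -> np.ndarray:
    if floor <= 0:
        raise ValueError("floor must be > 0")
    ref = np.asarray(mean_ref, dtype=float)
    alt = np.asarray(mean_alt, dtype=float)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("FPKM means must be non-negative")
    return alt / np.maximum(ref, floor)


def _welch_arrays(a: np.ndarray, b: np.ndarray):
    """Vectorised Welch t-test along the last axis.

    Sign convention: t > 0 when mean(b) > mean(a). Degenerate rows where both
    groups have zero variance get p = 1 if the means are equal (no evidence of
    difference) and p = 0 otherwise (the separation is exact); df is reported
    as n_a + n_b − 2 for those rows.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[-1], b.shape[-1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 replicate values")
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    va, vb = a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    equal = np.isclose(ma, mb)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(equal, 0.0, np.inf * np.sign(mb - ma)), t)
    df = np.where(degenerate, na + nb - 2, df)
    p = np.where(
        degenerate,
        np.where(equal, 1.0, 0.0),
        2.0 * stats.t.sf(np.abs(t), df),
    )
    return t, df, np.clip(p, 0.0, 1.0)


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided Welch t-test with Welch–Satterthwaite df.

    Returns ``(t_stat, df, p_value)``; t > 0 means group_b has the larger
    mean. Both-groups-zero-variance with equal means returns p = 1 by
    convention.
    """
    t, df, p = _welch_arrays(np.asarray(group_a, float), np.asarray(group_b, float))
    return float(t[0]), float(df[0]), float(p[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} min(1, m p_(j) / j) over the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_differential(
    matrix: ExpressionMatrix,
    condition_ref: tuple[str, str],
    condition_alt: tuple[str, str],
    q_threshold: float = DEFAULT_Q,
    fc_threshold: float = DEFAULT_FC,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    fc_floor: float = DEFAULT_FLOOR,
    log_transform: bool = True,
    min_fpkm_scope: str = "condition_mean",
) -> pd.DataFrame:
    """Per-contig differential results for one contrast (alt vs ref).

    BH correction runs across all contigs of this contrast. ``min_fpkm_scope``
    decides whether the abundance gate uses condition means (default) or any
    single replicate sample of the two conditions.

    Returns a DataFrame indexed by contig with columns ``group_a_mean,
    group_b_mean, fold_change, log2_fc, t_stat, df, p_value, q_value, is_deg,
    direction``.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    if min_fpkm_scope not in ("condition_mean", "sample"):
        raise ValueError("min_fpkm_scope must be 'condition_mean' or 'sample'")
    block_a = matrix.condition_values(*condition_ref)
    block_b = matrix.condition_values(*condition_alt)
    if block_a.shape[1] < 2 or block_b.shape[1] < 2:
        raise DataModelError(
            f"contrast {condition_ref} vs {condition_alt}: "
            "both conditions need >= 2 replicates"
        )
    a = block_a.to_numpy(float)
    b = block_b.to_numpy(float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ta, tb = (np.log2(a + 1.0), np.log2(b + 1.0)) if log_transform else (a, b)
    t, df, p = _welch_arrays(ta, tb)
    q = bh_adjust(p)
    fc = fold_change_vector(mean_a, mean_b, fc_floor)
    with np.errstate(divide="ignore"):
        log2_fc = np.log2(fc)
    if min_fpkm_scope == "condition_mean":
        abundant = (mean_a >= min_fpkm) | (mean_b >= min_fpkm)
    else:
        abundant = (a.max(axis=1) >= min_fpkm) | (b.max(axis=1) >= min_fpkm)
    up = fc >= fc_threshold
    down = fc <= 1.0 / fc_threshold
    is_deg = (q < q_threshold) & (up | down) & abundant
    direction = np.where(is_deg & up, "up", np.where(is_deg & down, "down", "none"))
    return pd.DataFrame(
        {
            "group_a_mean": mean_a,
            "group_b_mean": mean_b,
            "fold_change": fc,
            "log2_fc": log2_fc,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "q_value": q,
            "is_deg": is_deg,
            "direction": direction,
        },
        index=matrix.values.index.copy(),
    )


def expressed_contigs(matrix: ExpressionMatrix, threshold: float = 5.0) -> set[str]:
    """Contigs whose condition mean exceeds ``threshold`` (strict) in at
    least one design cell — the 'expressed in at least one condition' filter."""
    from .data_model import condition_means

    means = condition_means(matrix)
    if means.empty or means.shape[1] == 0:
        return set()
    keep = (means.to_numpy(float) > threshold).any(axis=1)
    return set(means.index[keep])


def write_differential_table(result: pd.DataFrame, path) -> None:
    out = result.copy()
    out.index.name = "contig_id"
    out.to_csv(path, sep="\t")
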