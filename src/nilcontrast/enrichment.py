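"""Hypergeometric over-representation of annotation terms in a contig set.

A generic one-sided enrichment test over a user-supplied annotation table:
for each category term with K annotated contigs in the universe (N contigs),
a query of n contigs overlapping the term in k members gets the upper-tail
probability P(X >= k) under Hypergeometric(N, K, n), BH-adjusted across the
tested terms. The universe defaults, at the pipeline level, to the expressed
contigs — the genes actually tested.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats

from .data_model import AnnotationTable
from .diffexp import bh_adjust


def hypergeometric_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P(X >= k) for drawing n from N with K successes."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def over_representation(
    query: Iterable[str],
    annotation: AnnotationTable,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term-level enrichment of ``query`` against ``universe``.

    Returns a DataFrame sorted by p with columns ``term, k, K, n, N, p_value,
    q_value, significant``. Terms absent from the universe (K = 0) are
    skipped. The query must be a subset of the universe.
    """
    query = set(query)
    universe = set(universe)
    outside = query - universe
    if outside:
        raise ValueError(
            f"query contigs outside the universe: {sorted(outside)}"
        )
    N, n = len(universe), len(query)
    term_members: dict[str, set[str]] = {}
    for cid in universe:
        for term in annotation.terms_for(cid):
            term_members.setdefault(term, set()).add(cid)
    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        k = len(members & query)
        rows.append(
            {"term": term, "k": k, "K": K, "n": n, "N": N,
             "p_value": hypergeometric_tail(k, N, K, n)}
        )
    result = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value"])
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].to_numpy())
        result["significant"] = result["p_value"] < alpha
        result = result.sort_values(["p_value", "term"], kind="mergesort")
        result = result.reset_index(drop=True)
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result


def write_enrichment_table(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False)
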