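"""The eight hypothesis-driven contrast filters over a NIL × treatment design.

Each filter formalises one question about genes separating the low- and
high-cadmium near-isogenic lines:

* H1/H2 — constitutively expressed in one genotype (> ``high`` FPKM in both of
  its conditions) while silent in the other (< ``low`` FPKM in both).
* H3/H4 — expressed well above background in one genotype's control samples
  (>= ``background_multiple`` × background) and significantly higher than the
  other genotype's controls under the DEG rule.
* H5/H6 — cadmium-regulated (treated vs control DEG) in exactly one genotype,
  split by direction.
* H7 — cadmium-regulated in both genotypes; its "strongly upregulated only in
  L" refinement keeps members whose L fold change exceeds the H fold change
  by ``ratio_threshold``.
* H8 — shared responders restricted to a user-supplied annotation term list
  (the study inspected shared-up transcription factors this way).

Every result is a :class:`ContrastSet` that records the thresholds that
produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import (
    AnnotationTable,
    ExpressionMatrix,
    condition_means,
)
from .diffexp import (
    DEFAULT_FC,
    DEFAULT_FLOOR,
    DEFAULT_MIN_FPKM,
    DEFAULT_Q,
    call_differential,
    fold_change_vector,
)


@dataclass(frozen=True)
class ContrastSet:
    hypothesis_id: str
    members: frozenset[str]
    parameters: dict = field(default_factory=dict, compare=False)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class SubsetProfile:
    """Column-wise arithmetic means over a contig set: the four condition
    means plus the per-genotype fold-change means (rounding to one decimal is
    left to report time)."""

    n_members: int
    mean_ctrl_L: float
    mean_treated_L: float
    mean_fc_L: float
    mean_ctrl_H: float
    mean_treated_H: float
    mean_fc_H: float

    def rounded(self) -> dict[str, float]:
        return {
            "mean_ctrl_L": round(self.mean_ctrl_L, 1),
            "mean_treated_L": round(self.mean_treated_L, 1),
            "mean_fc_L": round(self.mean_fc_L, 1),
            "mean_ctrl_H": round(self.mean_ctrl_H, 1),
            "mean_treated_H": round(self.mean_treated_H, 1),
            "mean_fc_H": round(self.mean_fc_H, 1),
        }


def _other(genotype: str) -> str:
    return "H" if genotype == "L" else "L"


def exclusive_set(
    summaries: pd.DataFrame,
    on_genotype: str,
    high: float = 25.0,
    low: float = 5.0,
) -> ContrastSet:
    """H1/H2: constitutive in ``on_genotype`` (> high in both of its
    conditions), silent in the other genotype (< low in both).

    ``summaries`` is the wide condition-mean frame from
    :func:`nilcontrast.data_model.condition_means` (contigs × (genotype,
    treatment)).
    """
    if high <= low:
        raise ValueError(f"high ({high}) must exceed low ({low})")
    other = _other(on_genotype)
    needed = [(on_genotype, "control"), (on_genotype, "cadmium"),
              (other, "control"), (other, "cadmium")]
    missing = [c for c in needed if c not in summaries.columns]
    if missing:
        raise ValueError(f"condition means missing for {missing}")
    on = summaries[[(on_genotype, "control"), (on_genotype, "cadmium")]].to_numpy(float)
    off = summaries[[(other, "control"), (other, "cadmium")]].to_numpy(float)
    keep = (on > high).all(axis=1) & (off < low).all(axis=1)
    hid = "H1" if on_genotype == "L" else "H2"
    return ContrastSet(
        hypothesis_id=hid,
        members=frozenset(summaries.index[keep]),
        parameters={"on_genotype": on_genotype, "high": high, "low": low},
        provenance=f"constitutive in {on_genotype} (> {high} FPKM both conditions), "
                   f"silent in {other} (< {low} FPKM both conditions)",
    )


def baseline_biased_set(
    matrix: ExpressionMatrix,
    favored_genotype: str,
    background: float = 5.0,
    background_multiple: float = 5.0,
    q_threshold: float = DEFAULT_Q,
    fc_threshold: float = DEFAULT_FC,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    fc_floor: float = DEFAULT_FLOOR,
) -> ContrastSet:
    """H3/H4: strong control-sample expression in the favored genotype
    (mean >= background_multiple × background) and a DEG-rule significant
    excess over the other genotype's control samples."""
    if background <= 0:
        raise ValueError("background must be > 0")
    other = _other(favored_genotype)
    de = call_differential(
        matrix,
        condition_ref=(other, "control"),
        condition_alt=(favored_genotype, "control"),
        q_threshold=q_threshold,
        fc_threshold=fc_threshold,
        min_fpkm=min_fpkm,
        fc_floor=fc_floor,
    )
    strong = de["group_b_mean"] >= background_multiple * background
    keep = strong & de["is_deg"] & (de["direction"] == "up")
    hid = "H3" if favored_genotype == "L" else "H4"
    return ContrastSet(
        hypothesis_id=hid,
        members=frozenset(de.index[keep]),
        parameters={
            "favored_genotype": favored_genotype,
            "background": background,
            "background_multiple": background_multiple,
            "q_threshold": q_threshold,
            "fc_threshold": fc_threshold,
            "min_fpkm": min_fpkm,
        },
        provenance=f"control mean >= {background_multiple} x background "
                   f"({background} FPKM) in {favored_genotype} and DEG vs "
                   f"{other} control samples",
    )


def response_sets(
    matrix: ExpressionMatrix,
    genotype: str,
    q_threshold: float = DEFAULT_Q,
    fc_threshold: float = DEFAULT_FC,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    fc_floor: float = DEFAULT_FLOOR,
) -> tuple[ContrastSet, ContrastSet]:
    """Treated-vs-control DEGs of one genotype, split into (up, down)."""
    de = call_differential(
        matrix,
        condition_ref=(genotype, "control"),
        condition_alt=(genotype, "cadmium"),
        q_threshold=q_threshold,
        fc_threshold=fc_threshold,
        min_fpkm=min_fpkm,
        fc_floor=fc_floor,
    )
    params = {
        "genotype": genotype,
        "q_threshold": q_threshold,
        "fc_threshold": fc_threshold,
        "min_fpkm": min_fpkm,
    }
    up = ContrastSet(
        f"response_up_{genotype}",
        frozenset(de.index[de["direction"] == "up"]),
        dict(params),
        f"cadmium-vs-control DEGs up in {genotype}",
    )
    down = ContrastSet(
        f"response_down_{genotype}",
        frozenset(de.index[de["direction"] == "down"]),
        dict(params),
        f"cadmium-vs-control DEGs down in {genotype}",
    )
    return up, down


def specific_response_sets(
    up_L: ContrastSet, up_H: ContrastSet, down_L: ContrastSet, down_H: ContrastSet
) -> tuple[ContrastSet, ContrastSet, ContrastSet, ContrastSet]:
    """H5/H6: genotype-specific responders (set differences)."""
    def diff(hid, a, b, text):
        return ContrastSet(hid, a.members - b.members,
                           {"minuend": a.hypothesis_id, "subtrahend": b.hypothesis_id},
                           text)

    return (
        diff("H5_up_only_L", up_L, up_H, "up in L only"),
        diff("H6_up_only_H", up_H, up_L, "up in H only"),
        diff("H5_down_only_L", down_L, down_H, "down in L only"),
        diff("H6_down_only_H", down_H, down_L, "down in H only"),
    )


def shared_response_sets(
    up_L: ContrastSet, up_H: ContrastSet, down_L: ContrastSet, down_H: ContrastSet
) -> tuple[ContrastSet, ContrastSet]:
    """H7: responders shared by both genotypes (intersections)."""
    shared_up = ContrastSet(
        "H7_shared_up", up_L.members & up_H.members, {}, "up in both genotypes"
    )
    shared_down = ContrastSet(
        "H7_shared_down", down_L.members & down_H.members, {},
        "down in both genotypes",
    )
    return shared_up, shared_down


def strong_subset(
    shared: ContrastSet,
    fc_L: Mapping[str, float],
    fc_H: Mapping[str, float],
    ratio_threshold: float = 10.0,
) -> ContrastSet:
    """Members of a shared set whose L fold change exceeds the H fold change
    ``ratio_threshold``-fold — 'strongly upregulated only in the L line'."""
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must exceed 1")
    missing = [c for c in shared.members if c not in fc_L or c not in fc_H]
    if missing:
        raise ValueError(f"fold changes missing for members: {sorted(missing)}")
    keep = {
        c for c in shared.members
        if fc_H[c] > 0 and fc_L[c] / fc_H[c] >= ratio_threshold
    }
    return ContrastSet(
        "H7_strong_L",
        frozenset(keep),
        {"ratio_threshold": ratio_threshold, **shared.parameters},
        f"members of {shared.hypothesis_id} with FC_L/FC_H >= {ratio_threshold}",
    )


def annotation_matched_set(
    shared: ContrastSet,
    annotation: AnnotationTable,
    terms: Iterable[str],
    match_description: bool = True,
) -> ContrastSet:
    """H8: shared responders whose annotation matches any requested term.

    A contig matches when one of its category terms equals a requested term,
    or (with ``match_description``) when a term appears as a case-insensitive
    substring of its description.
    """
    wanted = [str(t) for t in terms]
    keep = set()
    for cid in shared.members:
        cats = annotation.terms_for(cid)
        desc = annotation.description(cid).lower()
        if any(t in cats for t in wanted):
            keep.add(cid)
        elif match_description and any(t.lower() in desc for t in wanted if t):
            keep.add(cid)
    return ContrastSet(
        "H8_term_matched",
        frozenset(keep),
        {"terms": sorted(wanted), "source": shared.hypothesis_id},
        f"members of {shared.hypothesis_id} annotated with {sorted(wanted)}",
    )


def genotype_fold_changes(
    matrix: ExpressionMatrix, fc_floor: float = DEFAULT_FLOOR
) -> tuple[pd.Series, pd.Series]:
    """Per-contig treated/control condition-mean fold changes (FC_L, FC_H)."""
    means = condition_means(matrix)
    fc_L = pd.Series(
        fold_change_vector(means[("L", "control")], means[("L", "cadmium")], fc_floor),
        index=means.index,
    )
    fc_H = pd.Series(
        fold_change_vector(means[("H", "control")], means[("H", "cadmium")], fc_floor),
        index=means.index,
    )
    return fc_L, fc_H


def subset_profile(
    members: Iterable[str],
    summaries: pd.DataFrame,
    fc_L: Mapping[str, float],
    fc_H: Mapping[str, float],
) -> SubsetProfile:
    """Arithmetic column means over a contig set (the printed 'Mean' row of
    the study's archetype tables); every member must carry all four condition
    means and both fold changes."""
    members = sorted(set(members))
    for cid in members:
        if cid not in summaries.index:
            raise ValueError(f"member {cid!r} has no condition means")
        if cid not in fc_L or cid not in fc_H:
            raise ValueError(f"member {cid!r} has no fold-change values")
    if not members:
        raise ValueError("subset_profile needs a non-empty member set")
    sub = summaries.loc[members]
    return SubsetProfile(
        n_members=len(members),
        mean_ctrl_L=float(sub[("L", "control")].mean()),
        mean_treated_L=float(sub[("L", "cadmium")].mean()),
        mean_fc_L=float(np.mean([fc_L[c] for c in members])),
        mean_ctrl_H=float(sub[("H", "control")].mean()),
        mean_treated_H=float(sub[("H", "cadmium")].mean()),
        mean_fc_H=float(np.mean([fc_H[c] for c in members])),
    )


def write_contrast_set(cset: ContrastSet, path) -> None:
    """One hypothesis TSV: parameter echo as '#' comment lines, then members."""
    with open(path, "w") as fh:
        fh.write(f"# hypothesis_id: {cset.hypothesis_id}\n")
        fh.write(f"# provenance: {cset.provenance}\n")
        for key in sorted(cset.parameters):
            fh.write(f"# {key}: {cset.parameters[key]}\n")
        fh.write("contig_id\n")
        for cid in cset.sorted_members():
            fh.write(f"{cid}\n")
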