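"""Core containers and TSV I/O for replicate-level FPKM expression data.

The pipeline's sole primary input is a contigs × samples FPKM matrix plus a
sample sheet assigning every sample to one cell of the 2 genotypes
(L = low grain cadmium, H = high grain cadmium) × 2 treatments
(control, cadmium) design. All downstream filters operate on the
condition-level summary (per-contig mean/sd/n per design cell).
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOTYPES = ("L", "H")
TREATMENTS = ("control", "cadmium")

#: four design cells in canonical order (L-CTRL, L-Cd, H-CTRL, H-Cd)
CONDITIONS = tuple((g, t) for g in GENOTYPES for t in TREATMENTS)

_GENOTYPE_ALIASES = {
    "l": "L", "l-cd": "L", "lcd": "L", "low": "L",
    "h": "H", "h-cd": "H", "hcd": "H", "high": "H",
}
_TREATMENT_ALIASES = {
    "control": "control", "ctrl": "control",
    "cadmium": "cadmium", "cd": "cadmium", "+cd": "cadmium", "treated": "cadmium",
}


class DataModelError(ValueError):
    """Raised for malformed expression/metadata/annotation inputs."""


def _canon_genotype(value: str) -> str:
    try:
        return _GENOTYPE_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise DataModelError(
            f"unknown genotype {value!r}; expected one of {GENOTYPES}"
        ) from None


def _canon_treatment(value: str) -> str:
    try:
        return _TREATMENT_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise DataModelError(
            f"unknown treatment {value!r}; expected one of {TREATMENTS}"
        ) from None


@dataclass(frozen=True)
class Sample:
    """One sequenced RNA library."""

    sample_id: str
    genotype: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", _canon_genotype(self.genotype))
        object.__setattr__(self, "treatment", _canon_treatment(self.treatment))
        if int(self.replicate) < 1:
            raise DataModelError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )
        object.__setattr__(self, "replicate", int(self.replicate))

    @property
    def condition(self) -> tuple[str, str]:
        return (self.genotype, self.treatment)


@dataclass
class ExpressionMatrix:
    """Contigs × samples FPKM matrix with its sample sheet.

    ``values`` is a pandas DataFrame indexed by contig id with one column per
    sample, column order following ``samples``. All entries are finite and
    non-negative (FPKM is an abundance, not a count).
    """

    values: pd.DataFrame
    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataModelError(f"duplicate sample ids: {dupes}")
        if list(self.values.columns) != ids:
            raise DataModelError(
                "expression columns do not match sample sheet order: "
                f"{list(self.values.columns)} vs {ids}"
            )
        if self.values.index.has_duplicates:
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise DataModelError(f"duplicate contig ids: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise DataModelError(
                f"invalid FPKM {arr[r, c]!r} at contig {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r} (values must be finite and >= 0)"
            )
        self.values = self.values.astype(float)

    @property
    def contig_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_contigs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_for(self, genotype: str, treatment: str) -> list[Sample]:
        g, t = _canon_genotype(genotype), _canon_treatment(treatment)
        return [s for s in self.samples if s.condition == (g, t)]

    def condition_values(self, genotype: str, treatment: str) -> pd.DataFrame:
        """Replicate columns of one design cell (error if the cell is empty)."""
        cols = [s.sample_id for s in self.samples_for(genotype, treatment)]
        if not cols:
            raise DataModelError(
                f"no samples for condition ({genotype!r}, {treatment!r})"
            )
        return self.values[cols]

    def conditions(self) -> list[tuple[str, str]]:
        """Design cells observed in the sample sheet, canonical order."""
        seen = {s.condition for s in self.samples}
        return [c for c in CONDITIONS if c in seen]

    def subset(self, contigs: Iterable[str]) -> "ExpressionMatrix":
        keep = [c for c in self.contig_ids if c in set(contigs)]
        return ExpressionMatrix(self.values.loc[keep], list(self.samples))


def condition_summary(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-contig, per-(genotype, treatment) mean/sd/n of replicate FPKM.

    Returns a tidy frame with columns ``contig_id, genotype, treatment,
    mean_fpkm, sd_fpkm, n``. The sd uses the n−1 denominator and is 0 when
    n = 1. These condition means are the quantities every hypothesis filter
    consumes.
    """
    records = []
    for g, t in matrix.conditions():
        block = matrix.condition_values(g, t)
        n = block.shape[1]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1) if n > 1 else pd.Series(0.0, index=block.index)
        records.append(
            pd.DataFrame(
                {
                    "contig_id": block.index,
                    "genotype": g,
                    "treatment": t,
                    "mean_fpkm": mean.to_numpy(),
                    "sd_fpkm": sd.to_numpy(),
                    "n": n,
                }
            )
        )
    if not records:
        return pd.DataFrame(
            columns=["contig_id", "genotype", "treatment", "mean_fpkm", "sd_fpkm", "n"]
        )
    return pd.concat(records, ignore_index=True)


def condition_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Wide view of condition means: contigs × (genotype, treatment) columns."""
    tidy = condition_summary(matrix)
    if tidy.empty:
        return pd.DataFrame(index=matrix.values.index)
    wide = tidy.pivot(index="contig_id", columns=["genotype", "treatment"],
                      values="mean_fpkm")
    wide = wide.reindex(index=matrix.values.index)
    wide = wide[[c for c in CONDITIONS if c in wide.columns]]
    return wide


# ---------------------------------------------------------------------------
# TSV I/O (tab-separated, UTF-8, '.' decimal, mandatory header)
# ---------------------------------------------------------------------------

def read_metadata_table(path: str | Path) -> list[Sample]:
    """Read the sample sheet: sample_id, genotype, treatment, replicate."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "treatment", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise DataModelError(f"metadata {path}: missing columns {sorted(missing)}")
    return [
        Sample(row.sample_id, row.genotype, row.treatment, int(row.replicate))
        for row in meta.itertuples(index=False)
    ]


def read_expression_table(
    path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    """Read expression + metadata TSVs into a validated :class:`ExpressionMatrix`.

    Column order follows metadata order. Every metadata sample must appear in
    the expression header and vice versa; duplicate contig ids, NaN and
    negative FPKM are rejected with the offending record named.
    """
    samples = read_metadata_table(metadata_path)
    table = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    table.index = table.index.astype(str)
    meta_ids = [s.sample_id for s in samples]
    missing = [sid for sid in meta_ids if sid not in table.columns]
    if missing:
        raise DataModelError(
            f"expression table {path}: samples missing from header: {missing}"
        )
    extra = [c for c in table.columns if c not in set(meta_ids)]
    if extra:
        raise DataModelError(
            f"metadata {metadata_path}: samples missing from metadata: {extra}"
        )
    return ExpressionMatrix(table[meta_ids], samples)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    """Write the matrix and sample sheet in the dialect ``read_expression_table``
    accepts; float formatting uses Python repr so a round trip is bit-exact."""
    out = matrix.values.copy()
    out.index.name = "contig_id"
    out.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in matrix.samples],
            "genotype": [s.genotype for s in matrix.samples],
            "treatment": [s.treatment for s in matrix.samples],
            "replicate": [s.replicate for s in matrix.samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


@dataclass
class AnnotationTable:
    """Contig → (description, optional AGI code, category terms).

    Contigs absent from the table are treated as unannotated, never dropped.
    """

    records: pd.DataFrame  # index contig_id; columns description, agi_code
    terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def description(self, contig_id: str) -> str:
        if contig_id in self.records.index:
            return str(self.records.loc[contig_id, "description"])
        return ""

    def terms_for(self, contig_id: str) -> frozenset[str]:
        return self.terms.get(contig_id, frozenset())

    def contigs_with_term(self, term: str) -> set[str]:
        return {c for c, ts in self.terms.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.terms.values():
            out |= ts
        return out

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[str, str | None, Iterable[str]]]
    ) -> "AnnotationTable":
        idx, desc, agi, terms = [], [], [], {}
        for cid, (d, a, ts) in mapping.items():
            idx.append(cid)
            desc.append(d)
            agi.append(a if a else "")
            terms[cid] = frozenset(ts)
        records = pd.DataFrame(
            {"description": desc, "agi_code": agi}, index=pd.Index(idx, name="contig_id")
        )
        return cls(records, terms)


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read ``contig_id<TAB>description<TAB>agi_code<TAB>term1;term2;...``."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"contig_id", "description"}
    missing = required - set(table.columns)
    if missing:
        raise DataModelError(f"annotation {path}: missing columns {sorted(missing)}")
    if table["contig_id"].duplicated().any():
        dupes = sorted(table.loc[table["contig_id"].duplicated(), "contig_id"])
        raise DataModelError(f"annotation {path}: duplicate contig ids {dupes}")
    if "agi_code" not in table.columns:
        table["agi_code"] = ""
    raw_terms = table["terms"] if "terms" in table.columns else pd.Series(
        "", index=table.index
    )
    terms = {
        cid: frozenset(t for t in str(raw).split(";") if t)
        for cid, raw in zip(table["contig_id"], raw_terms)
    }
    records = table.set_index("contig_id")[["description", "agi_code"]]
    return AnnotationTable(records, terms)


def write_annotation_table(annotation: AnnotationTable, path: str | Path) -> None:
    out = annotation.records.copy()
    out["terms"] = [
        ";".join(sorted(annotation.terms_for(c))) for c in out.index
    ]
    out.to_csv(path, sep="\t")
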