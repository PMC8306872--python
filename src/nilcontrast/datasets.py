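"""Published condition-level FPKM archetypes bundled as worked examples.

These are the four small gene tables the source study prints for its durum
wheat near-isogenic lines (L-Cd / H-Cd, control vs 0.5 µM cadmium):

* :func:`table1` — five contigs constitutively expressed in L, silent in H
  (the H1 archetype; includes the HMT1-like ABC transporter).
* :func:`table2` — nine contigs constitutive in H, silent in L (H2; includes
  two aquaporins).
* :func:`table3` — twenty-two nicotianamine synthase (NAS) contigs induced by
  cadmium in both genotypes but ~160-fold in L against ~9-fold in H.
* :func:`table4` — five NAAT/DMAS contigs of the mugineic-acid pathway with
  the same asymmetric induction.

Each frame carries the printed condition means (FPKM, one value per design
cell) and, for tables 3–4, the printed per-genotype fold changes. The tables
double as single-replicate fixtures via :func:`tables_expression_matrix`.
"""

from __future__ import annotations

import pandas as pd

from .data_model import ExpressionMatrix, Sample

_CONDITION_COLS = ["L_ctrl", "L_cd", "H_ctrl", "H_cd"]

_TABLE1 = [
    # contig, L-CTRL, L+Cd, H-CTRL, H+Cd, annotation
    ("contig19712", 27.4, 31.2, 2.4, 2.1, "Cyclophilin"),
    ("contig23984", 76.5, 49.8, 0.1, 0.1, "no hits - unknown"),
    ("contig5761", 36.4, 25.7, 4.9, 4.0, "3-mercaptopyruvate sulfurtransferase"),
    ("contig90107", 57.1, 30.7, 0.0, 0.0, "no hits - unknown"),
    ("contig9490", 53.2, 43.9, 2.8, 0.2, "ABC transporter 3-like (HMT1)"),
]

_TABLE2 = [
    ("contig13191", 0.1, 0.3, 97.8, 34.2, "aquaporin pip1-2"),
    ("contig17660", 0.3, 0.2, 148.0, 65.1, "aquaporin pip1-5"),
    ("contig17681", 0.0, 0.1, 33.2, 27.0, "no hits - unknown"),
    ("contig20402", 0.1, 0.0, 62.1, 58.1, "no hits - unknown"),
    ("contig35423", 0.0, 0.1, 70.6, 43.7, "Ribosomal protein"),
    ("contig3675", 0.4, 0.4, 104.1, 84.4, "no hits - unknown"),
    ("contig48835", 4.4, 4.4, 62.9, 103.4, "no hits - unknown"),
    ("contig5342", 3.3, 3.9, 52.2, 67.4, "RNA ligase"),
    ("contig1280", 3.1, 1.9, 30.9, 32.6, "transcription elongation factor"),
]

_TABLE3 = [
    # contig, L-CTRL, L+Cd, FC_L, H-CTRL, H+Cd, FC_H, annotation
    ("contig26634", 7.8, 604.5, 77.1, 24.3, 240.7, 9.9, "NAS 1"),
    ("contig55580", 3.6, 707.5, 195.8, 20.5, 383.4, 18.7, "NAS 1"),
    ("contig44671", 5.4, 774.2, 143.6, 49.4, 437.2, 8.8, "NAS 2"),
    ("contig18293", 1.8, 502.3, 278.2, 11.1, 149.3, 13.5, "NAS 2"),
    ("contig18375", 23.5, 653.3, 27.8, 64.6, 386.0, 6.0, "NAS 2"),
    ("contig18424", 10.6, 1178.3, 111.5, 41.5, 522.9, 12.6, "NAS 3"),
    ("contig33892", 1.1, 623.2, 572.5, 10.0, 262.0, 26.3, "NAS 3"),
    ("contig40805", 9.8, 629.4, 64.2, 55.9, 348.5, 6.2, "NAS 3"),
    ("contig5670", 1.1, 179.2, 158.9, 5.2, 23.2, 4.5, "NAS 3"),
    ("contig6866", 7.6, 663.0, 87.8, 51.9, 281.9, 5.4, "NAS 3"),
    ("contig16879", 0.8, 155.6, 204.0, 5.2, 68.2, 13.0, "NAS 4"),
    ("contig36649", 7.8, 482.7, 61.8, 19.6, 183.5, 9.4, "NAS 4"),
    ("contig13016", 2.1, 391.5, 186.2, 30.2, 114.6, 3.8, "NAS 4"),
    ("contig18348", 2.4, 626.8, 264.5, 25.2, 257.9, 10.2, "NAS 4"),
    ("contig27606", 7.4, 321.2, 43.7, 31.3, 106.5, 3.4, "NAS 4"),
    ("contig46013", 7.5, 1488.7, 197.4, 64.4, 306.9, 4.8, "NAS 4"),
    ("contig51008", 1.2, 369.2, 318.0, 19.5, 85.3, 4.4, "NAS 4"),
    ("contig5669", 12.5, 845.6, 67.6, 44.2, 248.1, 5.6, "NAS 4"),
    ("contig56695", 1.7, 169.2, 102.4, 12.5, 75.1, 6.0, "NAS 4"),
    ("contig62096", 6.4, 778.0, 122.2, 39.4, 270.5, 6.9, "NAS 4"),
    ("contig6432", 5.3, 1071.6, 200.7, 81.6, 218.6, 2.7, "NAS 4"),
    ("contig35044", 10.3, 691.1, 67.3, 49.2, 419.8, 8.5, "NAS 5B"),
]

_TABLE4 = [
    ("contig24852", 0.7, 246.9, 356.6, 23.8, 103.0, 4.3, "NAAT"),
    ("contig7573", 1.0, 209.9, 209.6, 10.9, 117.3, 10.7, "NAAT"),
    ("contig20039", 3.2, 462.9, 145.4, 49.6, 287.9, 5.8, "NAAT"),
    ("contig40067", 21.9, 274.7, 12.6, 33.9, 175.8, 5.2, "DMAS"),
    ("contig10233", 11.4, 253.8, 22.3, 22.9, 139.9, 6.1, "DMAS"),
]


def table1() -> pd.DataFrame:
    """L-exclusive archetype: condition means + annotation, contig-indexed."""
    return pd.DataFrame(
        _TABLE1, columns=["contig_id", *_CONDITION_COLS, "annotation"]
    ).set_index("contig_id")


def table2() -> pd.DataFrame:
    """H-exclusive archetype."""
    return pd.DataFrame(
        _TABLE2, columns=["contig_id", *_CONDITION_COLS, "annotation"]
    ).set_index("contig_id")


def table3() -> pd.DataFrame:
    """NAS archetype with printed per-genotype fold changes (fc_L, fc_H)."""
    return pd.DataFrame(
        _TABLE3,
        columns=["contig_id", "L_ctrl", "L_cd", "fc_L", "H_ctrl", "H_cd", "fc_H",
                 "annotation"],
    ).set_index("contig_id")


def table4() -> pd.DataFrame:
    """NAAT/DMAS archetype with printed fold changes."""
    return pd.DataFrame(
        _TABLE4,
        columns=["contig_id", "L_ctrl", "L_cd", "fc_L", "H_ctrl", "H_cd", "fc_H",
                 "annotation"],
    ).set_index("contig_id")


def condition_mean_frame(*tables: pd.DataFrame) -> pd.DataFrame:
    """Stack printed tables into the wide condition-mean layout used by the
    contrast filters (contigs × (genotype, treatment))."""
    stacked = pd.concat([t[_CONDITION_COLS] for t in tables])
    stacked.columns = pd.MultiIndex.from_tuples(
        [("L", "control"), ("L", "cadmium"), ("H", "control"), ("H", "cadmium")]
    )
    return stacked


def tables_expression_matrix(*tables: pd.DataFrame) -> ExpressionMatrix:
    """Published tables as a single-replicate-per-condition ExpressionMatrix.

    With one sample per design cell the condition means equal the printed
    values exactly, so threshold-only filters (H1/H2, expressed, profiles)
    reproduce the worked examples; replicate-based stages need >= 2 reps and
    are skipped on this fixture.
    """
    if not tables:
        tables = (table1(), table2())
    values = pd.concat([t[_CONDITION_COLS] for t in tables])
    values.index.name = "contig_id"
    samples = [
        Sample("L_CTRL_r1", "L", "control", 1),
        Sample("L_Cd_r1", "L", "cadmium", 1),
        Sample("H_CTRL_r1", "H", "control", 1),
        Sample("H_Cd_r1", "H", "cadmium", 1),
    ]
    values = values.copy()
    values.columns = [s.sample_id for s in samples]
    return ExpressionMatrix(values, samples)
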