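"""Synthetic replicate-level FPKM datasets with planted gene classes.

The generator emulates the study design the pipeline targets: two durum-wheat
near-isogenic lines (L = low grain cadmium, H = high) × two treatments
(control / 0.5 µM cadmium) × three biological replicates. Each planted block
fixes the four condition-level base means of its genes; replicate values are
the base mean times mean-one lognormal noise, so condition means are unbiased
and the log-scale noise sd directly controls within-condition replicate
Pearson correlation.

Blocks are archetypes of the gene classes the contrast filters are designed
to find: genotype-exclusive genes, cadmium-induced genes with
genotype-dependent fold changes (strong in L, modest in H), genotype-specific
responders, a low-CV housekeeping block, and a null background whose per-gene
abundances span a realistic lognormal range but carry no genotype or
treatment effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path


import numpy as np
import pandas as pd
import yaml

from .data_model import (
    CONDITIONS,
    AnnotationTable,
    ExpressionMatrix,
    Sample,
    write_annotation_table,
    write_expression_table,
)

BLOCK_LABELS = (
    "exclusive_L",
    "exclusive_H",
    "induced_both_strongL",
    "induced_L_only",
    "induced_H_only",
    "repressed_H_only",
    "housekeeping",
    "null_background",
)


class GeneratorError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class PlantedBlock:
    """One planted gene class.

    ``base_mean`` gives the four condition base means in canonical order
    (L-control, L-cadmium, H-control, H-cadmium). ``base_spread`` (log2-scale
    sd) scatters a per-gene abundance offset applied identically to all four
    conditions, so it widens the between-gene abundance distribution without
    creating genotype or treatment effects.
    """

    label: str
    n_genes: int
    base_mean: tuple[float, float, float, float]
    description: str = ""
    base_spread: float = 0.0
    terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise GeneratorError(f"block {self.label!r}: n_genes must be >= 0")
        if len(self.base_mean) != 4:
            raise GeneratorError(
                f"block {self.label!r}: base_mean needs 4 values "
                "(L-control, L-cadmium, H-control, H-cadmium)"
            )
        if any(m < 0 for m in self.base_mean):
            raise GeneratorError(f"block {self.label!r}: base means must be >= 0")
        if self.base_spread < 0:
            raise GeneratorError(f"block {self.label!r}: base_spread must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    blocks: tuple[PlantedBlock, ...]
    replicates_per_condition: int = 3
    noise_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [b.label for b in self.blocks]
        if len(set(labels)) != len(labels):
            raise GeneratorError(f"duplicate block labels: {sorted(labels)}")
        if self.replicates_per_condition < 1:
            raise GeneratorError("replicates_per_condition must be >= 1")
        if self.noise_sigma < 0:
            raise GeneratorError("noise_sigma must be >= 0")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.blocks)

    @property
    def n_genes(self) -> int:
        return sum(b.n_genes for b in self.blocks)


@dataclass
class TruthTable:
    """Ground-truth block membership of every generated contig."""

    assignments: pd.Series  # index contig_id, values block label
    labels: tuple[str, ...]

    def label_of(self, contig_id: str) -> str:
        return str(self.assignments.loc[contig_id])

    def counts(self) -> dict[str, int]:
        return {lab: int((self.assignments == lab).sum()) for lab in self.labels}


def truth_sets(truth: TruthTable, label: str) -> set[str]:
    """Contigs planted under ``label`` (error for a label not in the config)."""
    if label not in truth.labels:
        raise GeneratorError(
            f"unknown block label {label!r}; known labels: {sorted(truth.labels)}"
        )
    return set(truth.assignments.index[truth.assignments == label])


def default_blocks() -> tuple[PlantedBlock, ...]:
    """The default planted catalogue.

    Base means are transcribed from the condition-level FPKM archetypes the
    study prints: L-exclusive genes around 50/0.5 FPKM, H-exclusive around
    0.5/55, cadmium-induced genes shared by both genotypes with ~105-fold
    induction in L against ~7-fold in H (means 6→630 vs 35→245), plus
    genotype-specific responders, a flat housekeeping block and a lognormal
    null background (log2 FPKM ~ N(3.5, 1.25), no design effect).
    """
    return (
        PlantedBlock("exclusive_L", 5, (50.0, 40.0, 0.5, 0.4),
                     "constitutive in L, silent in H", terms=frozenset({"transporter"})),
        PlantedBlock("exclusive_H", 9, (0.5, 0.4, 60.0, 50.0),
                     "constitutive in H, silent in L", terms=frozenset({"aquaporin"})),
        PlantedBlock("induced_both_strongL", 22, (6.0, 630.0, 35.0, 245.0),
                     "Cd-induced in both, ~15x stronger fold change in L",
                     terms=frozenset({"NAS", "metal_homeostasis"})),
        PlantedBlock("induced_L_only", 30, (8.0, 200.0, 8.0, 8.0),
                     "Cd-induced only in L", terms=frozenset({"peroxidase"})),
        PlantedBlock("induced_H_only", 10, (10.0, 10.0, 12.0, 150.0),
                     "Cd-induced only in H"),
        PlantedBlock("repressed_H_only", 12, (40.0, 38.0, 45.0, 4.5),
                     "Cd-repressed only in H"),
        PlantedBlock("housekeeping", 6, (80.0, 80.0, 80.0, 80.0),
                     "stable across genotypes and treatments",
                     terms=frozenset({"housekeeping"})),
        PlantedBlock("null_background", 2000, (1.0, 1.0, 1.0, 1.0),
                     "no genotype or treatment effect", base_spread=1.25,
                     terms=frozenset()),
    )


def default_config(seed: int = 0, noise_sigma: float = 0.15,
                   replicates_per_condition: int = 3) -> GeneratorConfig:
    cfg = GeneratorConfig(default_blocks(), replicates_per_condition,
                          noise_sigma, seed)
    # background base mean 1.0 is a placeholder scaled by the lognormal draw;
    # recentre it at 2^3.5 ≈ 11.3 FPKM so the spread straddles the expressed
    # threshold like a real FPKM distribution.
    blocks = tuple(
        replace(b, base_mean=(11.3137085,) * 4) if b.label == "null_background" else b
        for b in cfg.blocks
    )
    return GeneratorConfig(blocks, replicates_per_condition, noise_sigma, seed)


def fig3_like_config(seed: int = 0, noise_sigma: float = 0.15) -> GeneratorConfig:
    """Catalogue in which the cadmium treatment is the dominant axis of
    variation: a large shared-induction block responds strongly in both
    genotypes (still somewhat stronger in L), genotype-specific blocks stay
    small, and the background is 200 genes. Unsupervised sample clustering
    then splits control from cadmium-treated samples, as in the study's
    heatmap, with genotype structure nested inside each branch."""
    blocks = (
        PlantedBlock("exclusive_L", 5, (50.0, 40.0, 0.5, 0.4)),
        PlantedBlock("exclusive_H", 9, (0.5, 0.4, 60.0, 50.0)),
        PlantedBlock("induced_both_strongL", 40, (8.0, 400.0, 8.0, 280.0),
                     "strong shared induction, modestly stronger in L"),
        PlantedBlock("induced_L_only", 10, (8.0, 60.0, 8.0, 8.0)),
        PlantedBlock("induced_H_only", 10, (10.0, 10.0, 12.0, 80.0)),
        PlantedBlock("repressed_H_only", 10, (40.0, 38.0, 45.0, 6.0)),
        PlantedBlock("housekeeping", 6, (80.0,) * 4),
        PlantedBlock("null_background", 200, (11.3137085,) * 4, base_spread=1.25),
    )
    return GeneratorConfig(blocks, 3, noise_sigma, seed)


def _make_samples(replicates: int) -> list[Sample]:
    label = {"control": "CTRL", "cadmium": "Cd"}
    return [
        Sample(f"{g}_{label[t]}_r{r}", g, t, r)
        for (g, t) in CONDITIONS
        for r in range(1, replicates + 1)
    ]


def generate_dataset(config: GeneratorConfig) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw one replicate-level FPKM dataset plus its truth table.

    Each value is ``base_mean_condition × 2**offset_gene × exp(σZ − σ²/2)``
    with Z standard normal; the lognormal multiplier has mean one, so the
    expected replicate value equals the (offset-scaled) condition base mean.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    samples = _make_samples(config.replicates_per_condition)
    reps = config.replicates_per_condition
    sigma = config.noise_sigma

    rows, ids, labels = [], [], []
    gene_no = 0
    for block in config.blocks:
        base = np.asarray(block.base_mean, dtype=float)
        for _ in range(block.n_genes):
            gene_no += 1
            cid = f"synthcontig{gene_no:05d}"
            offset = 2.0 ** rng.normal(0.0, block.base_spread) if block.base_spread else 1.0
            means = np.repeat(base * offset, reps)  # one entry per sample
            if sigma > 0:
                noise = np.exp(sigma * rng.standard_normal(means.size) - sigma**2 / 2)
            else:
                noise = 1.0
            rows.append(means * noise)
            ids.append(cid)
            labels.append(block.label)

    values = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(ids), len(samples)),
        index=pd.Index(ids, name="contig_id"),
        columns=[s.sample_id for s in samples],
    )
    matrix = ExpressionMatrix(values, samples)
    truth = TruthTable(
        pd.Series(labels, index=values.index, name="label"), config.labels
    )
    return matrix, truth


def annotation_for_truth(truth: TruthTable,
                         config: GeneratorConfig) -> AnnotationTable:
    """Annotation table mirroring the planted design: each contig carries its
    block description and the block's category terms, so enrichment and the
    term-matched (H8-style) filter can be exercised against ground truth."""
    by_label = {b.label: b for b in config.blocks}
    mapping = {
        cid: (
            by_label[lab].description or lab,
            None,
            by_label[lab].terms,
        )
        for cid, lab in truth.assignments.items()
    }
    return AnnotationTable.from_mapping(mapping)


# ---------------------------------------------------------------------------
# config and truth-table serialisation
# ---------------------------------------------------------------------------

def config_from_dict(payload: dict) -> GeneratorConfig:
    blocks = tuple(
        PlantedBlock(
            label=b["label"],
            n_genes=int(b["n_genes"]),
            base_mean=tuple(float(x) for x in b["base_mean"]),
            description=b.get("description", ""),
            base_spread=float(b.get("base_spread", 0.0)),
            terms=frozenset(b.get("terms", ())),
        )
        for b in payload["blocks"]
    )
    return GeneratorConfig(
        blocks=blocks,
        replicates_per_condition=int(payload.get("replicates_per_condition", 3)),
        noise_sigma=float(payload.get("noise_sigma", 0.15)),
        seed=int(payload["seed"]),
    )


def read_generator_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def write_generator_config(config: GeneratorConfig, path: str | Path) -> None:
    payload = {
        "blocks": [
            {
                "label": b.label,
                "n_genes": b.n_genes,
                "base_mean": list(b.base_mean),
                "description": b.description,
                "base_spread": b.base_spread,
                "terms": sorted(b.terms),
            }
            for b in config.blocks
        ],
        "replicates_per_condition": config.replicates_per_condition,
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    out = truth.assignments.rename("label").to_frame()
    out.index.name = "contig_id"
    out.to_csv(path, sep="\t")


def read_truth_table(path: str | Path) -> TruthTable:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    series = table["label"]
    return TruthTable(series, tuple(dict.fromkeys(series)))


def write_dataset(matrix: ExpressionMatrix, truth: TruthTable, outdir: str | Path,
                  annotation: AnnotationTable | None = None) -> dict[str, Path]:
    """Write expression.tsv / metadata.tsv / truth.tsv (+ annotation.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_table(matrix, paths["expression"], paths["metadata"])
    write_truth_table(truth, paths["truth"])
    if annotation is not None:
        paths["annotation"] = outdir / "annotation.tsv"
        write_annotation_table(annotation, paths["annotation"])
    return paths
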