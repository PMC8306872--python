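"""End-to-end orchestration: a fitted-model view of the contrast analysis.

:class:`CadmiumContrastModel` holds an FPKM matrix (real or synthetic) plus
every threshold of the analysis; ``fit()`` runs QC, the expressed-gene
filter, the Welch/BH DEG contrasts, the eight hypothesis filters, the
reference-gene ranking and (when annotation is available) term enrichment,
returning a :class:`ContrastResults` that carries all stage outputs, a
``summary()`` table and a ``write()`` method producing the TSV/JSON report
bundle. :func:`run_pipeline` is the config-file driver used by the CLI.

Thresholds default to the source study's rules: DEG = q < 0.001 and a
two-fold condition-mean change and >= 5 FPKM in at least one condition;
exclusive filters at > 25 / < 5 FPKM; expressed at > 5 FPKM; background 5
FPKM with a 5x multiple; strong-vs-modest induction at a 10x fold-change
ratio; reference candidates above 25 FPKM; enrichment alpha 0.05.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import simulate
from .contrasts import (
    ContrastSet,
    annotation_matched_set,
    baseline_biased_set,
    exclusive_set,
    genotype_fold_changes,
    response_sets,
    shared_response_sets,
    specific_response_sets,
    strong_subset,
    subset_profile,
    write_contrast_set,
)
from .data_model import (
    AnnotationTable,
    ExpressionMatrix,
    condition_means,
    read_annotation_table,
    read_expression_table,
)
from .diffexp import call_differential, expressed_contigs, write_differential_table
from .enrichment import over_representation, write_enrichment_table
from .qc import (
    cluster_heatmap,
    plot_heatmap,
    replicate_correlation,
    write_correlation_table,
)
from .reference import rank_reference_candidates, write_reference_table

logger = logging.getLogger("nilcontrast")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, with the study's defaults."""

    # exclusive filters (H1/H2)
    high: float = 25.0
    low: float = 5.0
    # DEG rule
    q_threshold: float = 0.001
    fc_threshold: float = 2.0
    min_fpkm: float = 5.0
    fc_floor: float = 0.01
    log_transform: bool = True
    # expressed-gene filter
    expressed_threshold: float = 5.0
    # baseline bias (H3/H4)
    background: float = 5.0
    background_multiple: float = 5.0
    # strong shared induction (H7 refinement)
    ratio_threshold: float = 10.0
    # reference genes
    cv_min_mean: float = 25.0
    top_k: int = 3
    # enrichment
    enrichment_alpha: float = 0.05
    # H8 term matching
    h8_terms: tuple[str, ...] = ()
    # rendering
    render_heatmap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.high <= self.low:
            raise ValueError("high must exceed low")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must exceed 1")
        if self.background <= 0:
            raise ValueError("background must be > 0")
        self.h8_terms = tuple(self.h8_terms)

    def to_dict(self) -> dict[str, Any]:
        payload = dataclasses.asdict(self)
        payload["h8_terms"] = list(self.h8_terms)
        return payload

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown pipeline options: {sorted(unknown)}")
        return cls(**payload)


class CadmiumContrastModel:
    """The contrast analysis, statsmodels-style: data in, ``fit()`` out.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Replicate-level FPKM values with their sample sheet.
    annotation : AnnotationTable, optional
        Contig annotation used for H8 term matching and enrichment.
    config : PipelineConfig, optional
        All analysis thresholds (study defaults when omitted).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        annotation: AnnotationTable | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.matrix = matrix
        self.annotation = annotation
        self.config = config or PipelineConfig()
        self.truth: simulate.TruthTable | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_tables(
        cls,
        expression_path: str | Path,
        metadata_path: str | Path,
        annotation_path: str | Path | None = None,
        config: PipelineConfig | None = None,
    ) -> "CadmiumContrastModel":
        matrix = read_expression_table(expression_path, metadata_path)
        annotation = (
            read_annotation_table(annotation_path) if annotation_path else None
        )
        return cls(matrix, annotation, config)

    @classmethod
    def from_synthetic(
        cls,
        generator_config: simulate.GeneratorConfig | None = None,
        config: PipelineConfig | None = None,
        seed: int | None = None,
    ) -> "CadmiumContrastModel":
        if generator_config is None:
            generator_config = simulate.default_config(seed=seed or 0)
        elif seed is not None:
            generator_config = dataclasses.replace(generator_config, seed=seed)
        matrix, truth = simulate.generate_dataset(generator_config)
        annotation = simulate.annotation_for_truth(truth, generator_config)
        model = cls(matrix, annotation, config)
        model.truth = truth
        return model

    # -- fitting -----------------------------------------------------------
    def _has_replicates(self) -> bool:
        return all(
            len(self.matrix.samples_for(g, t)) >= 2
            for (g, t) in self.matrix.conditions()
        )

    def fit(self) -> "ContrastResults":
        """Run every stage; replicate-based stages are skipped (and listed in
        ``results.skipped``) when some condition has a single sample."""
        cfg = self.config
        matrix = self.matrix
        skipped: list[str] = []
        replicated = self._has_replicates()

        def stage(name, func, *args, **kwargs):
            try:
                return func(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {err}") from err

        logger.info("thresholds: %s", cfg.to_dict())
        means = stage("condition_summary", condition_means, matrix)
        expressed = stage("expressed", expressed_contigs, matrix,
                          cfg.expressed_threshold)
        fc_L, fc_H = stage("fold_changes", genotype_fold_changes, matrix,
                           cfg.fc_floor)

        qc_report = None
        cluster = None
        if replicated:
            qc_report = stage("qc_correlation", replicate_correlation, matrix)
        else:
            skipped.append("qc_correlation")
        if matrix.n_samples >= 2 and matrix.n_contigs >= 1:
            try:
                cluster = cluster_heatmap(matrix)
            except ValueError:
                skipped.append("clustering")
        else:
            skipped.append("clustering")

        h1 = stage("H1", exclusive_set, means, "L", cfg.high, cfg.low)
        h2 = stage("H2", exclusive_set, means, "H", cfg.high, cfg.low)

        deg_tables: dict[str, pd.DataFrame] = {}
        sets: dict[str, ContrastSet] = {"H1": h1, "H2": h2}
        profile = None
        enrichments: dict[str, pd.DataFrame] = {}

        if replicated:
            deg_kwargs = dict(
                q_threshold=cfg.q_threshold,
                fc_threshold=cfg.fc_threshold,
                min_fpkm=cfg.min_fpkm,
                fc_floor=cfg.fc_floor,
                log_transform=cfg.log_transform,
            )
            for genotype in ("L", "H"):
                deg_tables[f"{genotype}_cd_vs_ctrl"] = stage(
                    f"deg_{genotype}", call_differential, matrix,
                    (genotype, "control"), (genotype, "cadmium"), **deg_kwargs,
                )
            deg_tables["ctrl_H_vs_L"] = stage(
                "deg_ctrl", call_differential, matrix,
                ("L", "control"), ("H", "control"), **deg_kwargs,
            )

            sets["H3"] = stage(
                "H3", baseline_biased_set, matrix, "L", cfg.background,
                cfg.background_multiple, cfg.q_threshold, cfg.fc_threshold,
                cfg.min_fpkm, cfg.fc_floor,
            )
            sets["H4"] = stage(
                "H4", baseline_biased_set, matrix, "H", cfg.background,
                cfg.background_multiple, cfg.q_threshold, cfg.fc_threshold,
                cfg.min_fpkm, cfg.fc_floor,
            )
            up_L, down_L = stage("response_L", response_sets, matrix, "L",
                                 cfg.q_threshold, cfg.fc_threshold,
                                 cfg.min_fpkm, cfg.fc_floor)
            up_H, down_H = stage("response_H", response_sets, matrix, "H",
                                 cfg.q_threshold, cfg.fc_threshold,
                                 cfg.min_fpkm, cfg.fc_floor)
            sets["up_L"], sets["down_L"] = up_L, down_L
            sets["up_H"], sets["down_H"] = up_H, down_H
            only_L_up, only_H_up, only_L_down, only_H_down = stage(
                "H5_H6", specific_response_sets, up_L, up_H, down_L, down_H
            )
            sets["H5_up_only_L"] = only_L_up
            sets["H5_down_only_L"] = only_L_down
            sets["H6_up_only_H"] = only_H_up
            sets["H6_down_only_H"] = only_H_down
            shared_up, shared_down = stage(
                "H7", shared_response_sets, up_L, up_H, down_L, down_H
            )
            sets["H7_shared_up"] = shared_up
            sets["H7_shared_down"] = shared_down
            sets["H7_strong_L"] = stage(
                "H7_strong", strong_subset, shared_up, fc_L, fc_H,
                cfg.ratio_threshold,
            )
            if sets["H7_strong_L"].members:
                profile = stage(
                    "subset_profile", subset_profile,
                    sets["H7_strong_L"].members, means, fc_L, fc_H,
                )
            if self.annotation is not None:
                sets["H8_term_matched"] = stage(
                    "H8", annotation_matched_set, shared_up, self.annotation,
                    cfg.h8_terms,
                )
                universe = expressed if expressed else set(matrix.contig_ids)
                for name in ("H5_up_only_L", "H6_up_only_H", "H7_shared_up"):
                    query = sets[name].members & universe
                    enrichments[name] = stage(
                        f"enrichment_{name}", over_representation, query,
                        self.annotation, universe, cfg.enrichment_alpha,
                    )
        else:
            skipped.extend(
                ["deg_contrasts", "H3", "H4", "H5", "H6", "H7", "H8", "enrichment"]
            )

        reference = None
        if matrix.n_samples >= 2:
            reference = stage("reference_genes", rank_reference_candidates,
                              matrix, cfg.cv_min_mean, cfg.top_k)
        else:
            skipped.append("reference_genes")

        return ContrastResults(
            model=self,
            config=cfg,
            condition_means=means,
            expressed=expressed,
            fc_L=fc_L,
            fc_H=fc_H,
            qc=qc_report,
            cluster=cluster,
            deg_tables=deg_tables,
            sets=sets,
            strong_profile=profile,
            reference_candidates=reference,
            enrichments=enrichments,
            skipped=skipped,
        )


@dataclass
class ContrastResults:
    """Everything ``CadmiumContrastModel.fit()`` computed."""

    model: CadmiumContrastModel
    config: PipelineConfig
    condition_means: pd.DataFrame
    expressed: set[str]
    fc_L: pd.Series
    fc_H: pd.Series
    qc: Any
    cluster: Any
    deg_tables: dict[str, pd.DataFrame]
    sets: dict[str, ContrastSet]
    strong_profile: Any
    reference_candidates: pd.DataFrame | None
    enrichments: dict[str, pd.DataFrame]
    skipped: list[str] = field(default_factory=list)

    # -- summaries ---------------------------------------------------------
    def set_counts(self) -> dict[str, int]:
        return {name: len(cset) for name, cset in self.sets.items()}

    def deg_counts(self) -> dict[str, int]:
        return {
            name: int(table["is_deg"].sum()) for name, table in self.deg_tables.items()
        }

    def summary_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "n_contigs": self.model.matrix.n_contigs,
            "n_samples": self.model.matrix.n_samples,
            "expressed_count": len(self.expressed),
            "set_counts": self.set_counts(),
            "deg_counts": self.deg_counts(),
            "skipped_stages": list(self.skipped),
        }
        if self.qc is not None:
            out["qc_min_r"] = self.qc.min_r
            out["qc_max_r"] = self.qc.max_r
        if self.reference_candidates is not None and len(self.reference_candidates):
            out["reference_candidates"] = [
                {"contig_id": r.contig_id, "cv": round(float(r.cv), 4),
                 "mean_fpkm": round(float(r.mean_fpkm), 2)}
                for r in self.reference_candidates.itertuples(index=False)
            ]
        if self.strong_profile is not None:
            out["strong_subset_profile"] = self.strong_profile.rounded()
        return out

    def summary(self) -> str:
        """Human-readable run summary."""
        info = self.summary_dict()
        lines = [
            "Cadmium NIL contrast analysis",
            "=" * 34,
            f"contigs: {info['n_contigs']}   samples: {info['n_samples']}",
            f"expressed (> {self.config.expressed_threshold} FPKM in >= 1 "
            f"condition): {info['expressed_count']}",
        ]
        if "qc_min_r" in info:
            lines.append(
                f"replicate Pearson r: {info['qc_min_r']:.3f} .. {info['qc_max_r']:.3f}"
            )
        lines.append("hypothesis set sizes:")
        for name in sorted(self.sets):
            lines.append(f"  {name:<18} {len(self.sets[name]):>6}")
        if self.deg_tables:
            lines.append("DEG counts per contrast:")
            for name, count in self.deg_counts().items():
                lines.append(f"  {name:<18} {count:>6}")
        if info.get("reference_candidates"):
            lines.append("reference-gene candidates (lowest CV):")
            for rec in info["reference_candidates"]:
                lines.append(
                    f"  {rec['contig_id']:<18} CV={rec['cv']:.4f} "
                    f"mean={rec['mean_fpkm']:.1f} FPKM"
                )
        if self.strong_profile is not None:
            prof = self.strong_profile.rounded()
            lines.append(
                "strong shared-up profile (means): "
                f"L {prof['mean_ctrl_L']} -> {prof['mean_treated_L']} "
                f"(FC {prof['mean_fc_L']}); "
                f"H {prof['mean_ctrl_H']} -> {prof['mean_treated_H']} "
                f"(FC {prof['mean_fc_H']})"
            )
        if self.skipped:
            lines.append(f"skipped stages (need replicates): {', '.join(self.skipped)}")
        return "\n".join(lines)

    # -- report bundle -----------------------------------------------------
    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full report bundle; deterministic given data and config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        for name, table in self.deg_tables.items():
            p = outdir / f"deg_{name}.tsv"
            write_differential_table(table, p)
            paths[f"deg_{name}"] = p
        for name, cset in self.sets.items():
            p = outdir / f"hypothesis_{name}.tsv"
            write_contrast_set(cset, p)
            paths[f"hypothesis_{name}"] = p
        if self.strong_profile is not None:
            p = outdir / "subset_profile.tsv"
            pd.DataFrame([self.strong_profile.rounded()]).to_csv(p, sep="\t",
                                                                 index=False)
            paths["subset_profile"] = p
        if self.reference_candidates is not None:
            p = outdir / "reference_candidates.tsv"
            write_reference_table(self.reference_candidates, p)
            paths["reference_candidates"] = p
        if self.qc is not None:
            p = outdir / "qc_correlations.tsv"
            write_correlation_table(self.qc, p)
            paths["qc_correlations"] = p
        if self.cluster is not None:
            p = outdir / "cluster_columns.txt"
            p.write_text("\n".join(self.cluster.ordered_samples()) + "\n")
            paths["cluster_columns"] = p
            if self.config.render_heatmap:
                hp = outdir / "heatmap.png"
                plot_heatmap(self.model.matrix, self.cluster, hp)
                paths["heatmap"] = hp
        for name, table in self.enrichments.items():
            p = outdir / f"enrichment_{name}.tsv"
            write_enrichment_table(table, p)
            paths[f"enrichment_{name}"] = p

        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["summary"] = summary_path

        config_path = outdir / "resolved_config.yaml"
        with open(config_path, "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)
        paths["config"] = config_path
        return paths


def run_pipeline(
    config: PipelineConfig,
    expression_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    generator_config: simulate.GeneratorConfig | None = None,
    outdir: str | Path | None = None,
) -> ContrastResults:
    """Config-driven end-to-end run: load or simulate, fit, optionally write."""
    if expression_path is not None:
        if metadata_path is None:
            raise PipelineError("stage 'load': metadata_path required with "
                                "expression_path")
        model = CadmiumContrastModel.from_tables(
            expression_path, metadata_path, annotation_path, config
        )
    else:
        model = CadmiumContrastModel.from_synthetic(
            generator_config,
            config,
            seed=None if generator_config is not None else config.seed,
        )
    results = model.fit()
    if outdir is not None:
        results.write(outdir)
    return results
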