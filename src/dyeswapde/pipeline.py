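"""End-to-end model: slides + design in, called genes and a run report out.

`DyeSwapExperiment` is the modelling entry point: construct it from slide
tables and a design (or paths), call :meth:`~DyeSwapExperiment.fit`, and the
returned :class:`DyeSwapResults` carries every intermediate (normalized
slides, ratio matrix with provenance, SAM results, enrichment table) plus a
:class:`RunReport` of per-stage counts. Identical inputs, parameters and seed
give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from .enrich import hypergeometric_enrichment, summarize_categories
from .errors import PipelineError
from .io import (
    ExperimentDesign,
    GeneSetCollection,
    SlideTable,
    read_design,
    read_gene_sets,
    read_slide_table,
)
from .preprocess import lowess_normalize, write_normalized
from .ratios import (
    STATUS_CONCORDANCE,
    STATUS_KEPT,
    STATUS_MISSING,
    STATUS_PATTERN,
    RatioMatrix,
    build_ratio_matrix,
    concordance_filter,
    orient_and_collapse,
    pair_ratios,
    pattern_consistency_filter,
    summarize_patient,
    write_ratio_matrix,
)
from .sam import SAMOneClass, SAMResults


@dataclass
class RunConfig:
    """Every stage parameter of one pipeline run, in one place."""

    z_threshold: float = -2.0
    span: float = 0.3
    robust_iters: int = 3
    outlier_k: float = 3.0
    outlier_policy: str = "downweight"
    background: str = "subtract"
    collapse: str = "mean"
    k_sd: float = 3.0
    s0: float | str = "auto"
    permutations: int | str = "exhaustive"
    granularity: str = "patient"
    sam_universe: str = "complete"
    fdr_max: float = 0.0
    pi0: float = 1.0
    universe: str = "filtered"
    adjust_p: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Per-stage counts of one run; the audit trail of every filter."""

    n_slides: int = 0
    n_spots_per_slide: int = 0
    spots_flagged_low_intensity: int = 0
    spots_flagged_lowess_outlier: int = 0
    genes_total: int = 0
    genes_dropped_concordance: int = 0
    genes_dropped_missing: int = 0
    genes_dropped_pattern: int = 0
    genes_into_sam: int = 0
    called_total: int = 0
    called_up: int = 0
    called_down: int = 0
    s0: float = 0.0
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    version: str = _pkg_version

    def validate(self) -> None:
        if self.called_up + self.called_down != self.called_total:
            raise PipelineError(
                "report inconsistent: called_up + called_down != called_total"
            )
        chain = [
            self.genes_total,
            self.genes_total - self.genes_dropped_concordance,
            self.genes_total - self.genes_dropped_concordance
            - self.genes_dropped_missing,
            self.genes_into_sam,
            self.called_total,
        ]
        if any(b > a for a, b in zip(chain, chain[1:])):
            raise PipelineError("report inconsistent: filter chain grew")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class DyeSwapExperiment:
    """Dye-swap two-color differential-expression model.

    Parameters
    ----------
    slides : list of SlideTable
        One spot table per hybridization.
    design : ExperimentDesign
        Slide -> patient / swap-pair / dye-orientation mapping.
    gene_sets : GeneSetCollection, optional
        Flat annotation sets for post-hoc enrichment.
    """

    def __init__(
        self,
        slides: list[SlideTable],
        design: ExperimentDesign,
        gene_sets: GeneSetCollection | None = None,
    ):
        known = {s.slide_id for s in slides}
        missing = [sid for sid in design.slide_ids if sid not in known]
        if missing:
            raise PipelineError(f"design references absent slides: {missing}")
        self.slides = {s.slide_id: s for s in slides}
        self.design = design
        self.gene_sets = gene_sets

    @classmethod
    def from_paths(
        cls, slide_paths, design_path, gene_sets_path=None
    ) -> "DyeSwapExperiment":
        slides = [read_slide_table(p) for p in slide_paths]
        design = read_design(design_path)
        gene_sets = (
            read_gene_sets(gene_sets_path) if gene_sets_path else None
        )
        return cls(slides, design, gene_sets=gene_sets)

    def fit(self, config: RunConfig | None = None, **overrides) -> "DyeSwapResults":
        """Run normalize -> orient/collapse -> concordance -> consistency ->
        SAM -> enrichment and return the full results object."""
        if config is None:
            config = RunConfig()
        if overrides:
            config = dataclasses.replace(config, **overrides)

        norm = {}
        for sid in self.design.slide_ids:
            norm[sid] = lowess_normalize(
                self.slides[sid],
                span=config.span,
                robust_iters=config.robust_iters,
                outlier_k=config.outlier_k,
                outlier_policy=config.outlier_policy,
                z_threshold=config.z_threshold,
                background=config.background,
            )

        oriented = orient_and_collapse(norm, self.design,
                                       collapse=config.collapse)
        pairs = [
            concordance_filter(p, k_sd=config.k_sd)
            for p in pair_ratios(oriented, self.design)
        ]
        summaries = [summarize_patient(p) for p in pairs]
        matrix = build_ratio_matrix(pairs, summaries)
        matrix = pattern_consistency_filter(matrix)

        kept = matrix.kept
        if kept.empty:
            raise PipelineError("no genes survive the filter chain")

        # The sign-flip permutation null is only exchangeable for genes that
        # were NOT selected on their value signs, so by default SAM runs on
        # every gene with complete concordant data and the pattern filter
        # then restricts the call set (sam_universe="kept" reproduces the
        # literal filter-then-test ordering instead).
        if config.sam_universe == "complete":
            candidates = matrix.status.isin([STATUS_KEPT, STATUS_PATTERN])
            sam_gene_index = matrix.values.index[candidates]
        elif config.sam_universe == "kept":
            sam_gene_index = kept.index
        else:
            raise PipelineError(
                f"unknown sam_universe mode {config.sam_universe!r}")
        if config.granularity == "patient":
            sam_input = matrix.values.loc[sam_gene_index]
        elif config.granularity == "slide":
            sam_input = oriented.loc[sam_gene_index]
        else:
            raise PipelineError(
                f"unknown granularity mode {config.granularity!r}")

        sam_results = SAMOneClass(sam_input).fit(
            s0=config.s0,
            permutations=config.permutations,
            seed=config.seed,
            fdr_max=config.fdr_max,
            pi0=config.pi0,
        )
        kept_ids = set(kept.index)
        called = sam_results.called.loc[
            sam_results.called["gene_id"].isin(kept_ids)
        ].reset_index(drop=True)

        enrichment = None
        if self.gene_sets is not None:
            if config.universe == "filtered":
                universe = set(kept.index)
            elif config.universe == "all":
                universe = set(matrix.values.index)
            else:
                raise PipelineError(
                    f"unknown universe mode {config.universe!r}")
            enrichment = hypergeometric_enrichment(
                set(called["gene_id"]) & universe, universe, self.gene_sets,
                adjust=config.adjust_p,
            )

        status = matrix.status
        report = RunReport(
            n_slides=len(self.design.slide_ids),
            n_spots_per_slide=next(iter(self.slides.values())).n_spots,
            spots_flagged_low_intensity=int(sum(
                n.data["low_intensity"].sum() for n in norm.values()
            )),
            spots_flagged_lowess_outlier=int(sum(
                n.data["lowess_outlier"].sum() for n in norm.values()
            )),
            genes_total=len(status),
            genes_dropped_concordance=int((status == STATUS_CONCORDANCE).sum()),
            genes_dropped_missing=int((status == STATUS_MISSING).sum()),
            genes_dropped_pattern=int((status == STATUS_PATTERN).sum()),
            genes_into_sam=int((status == STATUS_KEPT).sum()),
            called_total=len(called),
            called_up=int((called["direction"] == "up").sum()),
            called_down=int((called["direction"] == "down").sum()),
            s0=float(sam_results.s0),
            parameters=config.to_dict(),
            seed=config.seed,
        )
        report.validate()
        return DyeSwapResults(
            model=self,
            config=config,
            normalized=norm,
            oriented=oriented,
            pairs=pairs,
            ratio_matrix=matrix,
            sam=sam_results,
            called_genes=called,
            enrichment=enrichment,
            report=report,
        )


@dataclass
class DyeSwapResults:
    """All intermediates and outcomes of one fitted pipeline run."""

    model: DyeSwapExperiment
    config: RunConfig
    normalized: dict
    oriented: pd.DataFrame
    pairs: list
    ratio_matrix: RatioMatrix
    sam: SAMResults
    called_genes: pd.DataFrame
    enrichment: pd.DataFrame | None
    report: RunReport

    @property
    def called(self) -> pd.DataFrame:
        """Called genes surviving every filter (SAM calls ∩ kept genes)."""
        return self.called_genes

    def category_summary(self, category_map) -> pd.DataFrame:
        directions = dict(
            zip(self.called["gene_id"], self.called["direction"]))
        return summarize_categories(directions, category_map)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Dye-swap differential expression run",
            "====================================",
            f"slides:                   {r.n_slides} "
            f"({r.n_spots_per_slide} spots each)",
            f"low-intensity spots:      {r.spots_flagged_low_intensity}",
            f"LOWESS outlier spots:     {r.spots_flagged_lowess_outlier}",
            f"genes on array:           {r.genes_total}",
            f"  dropped (concordance):  {r.genes_dropped_concordance}",
            f"  dropped (missing):      {r.genes_dropped_missing}",
            f"  dropped (pattern):      {r.genes_dropped_pattern}",
            f"genes into SAM:           {r.genes_into_sam}",
            f"s0 (fudge factor):        {r.s0:.6g}",
            f"called at FDR <= {self.config.fdr_max:g}:       "
            f"{r.called_total} (up {r.called_up}, down {r.called_down})",
        ]
        return "\n".join(lines)

    def write_outputs(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, n in self.normalized.items():
            write_normalized(n, outdir / f"normalized_{sid}.tsv")
        write_ratio_matrix(self.ratio_matrix, outdir / "ratio_matrix.tsv")
        self.sam.write(outdir / "sam_genes.tsv")
        self.sam.delta_table.to_csv(
            outdir / "sam_delta_table.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
        self.called.to_csv(
            outdir / "called_genes.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
        if self.enrichment is not None:
            self.enrichment.to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
        (outdir / "report.json").write_text(self.report.to_json() + "\n")


def run_pipeline(
    slide_paths,
    design_path,
    outdir,
    gene_sets_path=None,
    config: RunConfig | None = None,
) -> DyeSwapResults:
    """File-level wrapper: read inputs, fit, write every stage output.

    On a stage failure a ``FAILED`` marker naming the stage is left in the
    output directory alongside whatever was already written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        experiment = DyeSwapExperiment.from_paths(
            slide_paths, design_path, gene_sets_path
        )
        results = experiment.fit(config)
        results.write_outputs(outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return results
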