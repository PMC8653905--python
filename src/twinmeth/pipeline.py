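"""End-to-end orchestration: qc -> ewas -> regions -> coexpr -> enrich.

A single global seed fans out to per-stage seeds derived by hashing the
stage name, so toggling one stage never shifts another stage's random
stream.  Every run writes a machine-readable manifest (resolved config,
stage counts, seed, package versions) and is byte-reproducible: rerunning
the same config yields identical output files.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    assign_members,
    clr_transform,
    contrast_cluster,
    fit_gmm,
    paired_de,
    size_factors,
)
from .enrichment_stats import fisher_enrichment
from .io_formats import (
    ValidationError,
    read_design,
    read_gene_model,
    read_gmt,
    read_manifest,
    read_matrix,
    BetaMatrix,
    CountMatrix,
    write_regions_bed,
    write_run_manifest,
    write_table,
)
from .paired_ewas import (
    beta_to_m,
    call_dmps,
    estimate_surrogates,
    fit_moderated,
    pair_differences,
)
from .probe_qc import filter_probes, quantile_normalize
from .region_caller import (
    annotate_probes,
    chain_regions,
    classify_concordance,
    summarize_context,
)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "derive_seed"]

logger = logging.getLogger("twinmeth")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    return zlib.crc32(f"{stage}:{seed}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    """Resolved inputs, thresholds and flags of one pipeline run."""

    beta: str
    detp: str
    manifest: str
    design: str
    out_dir: str
    counts: Optional[str] = None
    genes: Optional[str] = None
    gmt: Optional[str] = None
    detp_threshold: float = 0.01
    dmp_p: float = 0.005
    max_gap: int = 1000
    min_probes: int = 2
    tau: float = 0.9
    de_fdr: float = 0.1
    k_min: int = 2
    k_max: int = 25
    gmm_restarts: int = 5
    promoter_up: int = 1500
    promoter_down: int = 500
    run_sva: bool = True
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 < self.detp_threshold < 1:
            raise ValidationError("detp_threshold must lie in (0, 1)")
        if not 0 < self.dmp_p < 1:
            raise ValidationError("dmp_p must lie in (0, 1)")
        if not 0 < self.tau < 1:
            raise ValidationError("tau must lie in (0, 1)")
        if not 0 < self.de_fdr < 1:
            raise ValidationError("de_fdr must lie in (0, 1)")
        if self.max_gap < 1 or self.min_probes < 2:
            raise ValidationError("max_gap >= 1 and min_probes >= 2 required")
        if not 1 <= self.k_min <= self.k_max:
            raise ValidationError("need 1 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every configured stage and write tables plus a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int | float] = {}

    # ---- load & pre-flight ---------------------------------------------
    stage = "load"
    try:
        beta = read_matrix(config.beta, "beta")
        detp = read_matrix(config.detp, "detp")
        bm = BetaMatrix(beta, detp)
        manifest = read_manifest(config.manifest)
        design = read_design(config.design)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    if set(bm.samples) != set(design.sample_ids):
        raise PipelineStageError(
            stage, "sample sets of beta matrix and design table differ"
        )

    # ---- qc -------------------------------------------------------------
    stage = "qc"
    try:
        filtered, report = filter_probes(bm, manifest, config.detp_threshold)
        normalized = quantile_normalize(filtered)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    stage_counts["probes_in"] = report.n_input_probes
    stage_counts["probes_retained"] = report.n_retained
    logger.info("qc: %d/%d probes retained", report.n_retained, report.n_input_probes)
    write_table(
        normalized.beta.reset_index().rename(columns={"index": "probe_id"}),
        out / "filtered_beta.tsv",
    )
    with open(out / "qc_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    # ---- ewas -----------------------------------------------------------
    stage = "ewas"
    try:
        m = beta_to_m(normalized)
        diffs = pair_differences(m, design)
        surrogates = None
        if config.run_sva:
            surrogates = estimate_surrogates(
                diffs, seed=derive_seed(config.seed, "sva")
            )
            stage_counts["surrogate_variables"] = surrogates.q
            logger.info("ewas: %d surrogate variable(s)", surrogates.q)
        prior, table = fit_moderated(diffs, surrogates)
        dmp_table = call_dmps(
            table, normalized, design, config.dmp_p, manifest=manifest
        )
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    dmps = dmp_table[dmp_table["significant"]]
    stage_counts["probes_tested"] = len(dmp_table)
    stage_counts["dmps"] = len(dmps)
    logger.info("ewas: %d DMPs at p < %g", len(dmps), config.dmp_p)
    write_table(dmp_table.reset_index(), out / "ewas_full.tsv")
    write_table(dmps.reset_index(), out / "dmps.tsv")

    # ---- regions --------------------------------------------------------
    stage = "regions"
    try:
        regions = chain_regions(dmps, manifest, config.max_gap, config.min_probes)
        regions = [classify_concordance(r, dmps) for r in regions]
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    stage_counts["regions"] = len(regions)
    stage_counts["concordant_regions"] = sum(bool(r.concordant) for r in regions)
    logger.info(
        "regions: %d chained, %d concordant",
        len(regions),
        stage_counts["concordant_regions"],
    )
    write_regions_bed(regions, out / "regions.bed")
    region_table = pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_probes": r.n_probes,
                "min_p": r.min_p,
                "concordant": r.concordant,
                "direction": r.direction,
                "probe_ids": ",".join(r.probe_ids),
            }
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "n_probes", "min_p",
            "concordant", "direction", "probe_ids",
        ],
    )
    write_table(region_table, out / "regions.tsv")

    annotation = None
    if config.genes:
        try:
            gene_model = read_gene_model(config.genes)
            annotation = annotate_probes(
                manifest, gene_model, config.promoter_up, config.promoter_down
            )
            if len(dmps):
                ctx = summarize_context(dmps, dmp_table.index, annotation)
                ctx_table = pd.DataFrame(
                    {
                        "context": list(ctx.dmp_fractions),
                        "dmp_fraction": list(ctx.dmp_fractions.values()),
                        "background_fraction": list(ctx.background_fractions.values()),
                    }
                )
                write_table(ctx_table, out / "context.tsv")
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

    # ---- coexpr ---------------------------------------------------------
    if config.counts:
        stage = "coexpr"
        try:
            counts = CountMatrix(read_matrix(config.counts, "counts"))
            if set(counts.samples) != set(design.sample_ids):
                raise ValidationError(
                    "sample sets of count matrix and design table differ"
                )
            sf = size_factors(counts)
            clr = clr_transform(counts, sf)
            model = fit_gmm(
                clr,
                K_grid=range(config.k_min, config.k_max + 1),
                restarts=config.gmm_restarts,
                seed=derive_seed(config.seed, "gmm"),
            )
            assignment = assign_members(model, config.tau)
            norm_expr = counts.counts / sf
            contrast = contrast_cluster(assignment, norm_expr, design)
            de = paired_de(counts, design, config.de_fdr)
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc
        stage_counts["clusters"] = model.K
        stage_counts["assigned_genes"] = int((assignment != -1).sum())
        logger.info(
            "coexpr: K=%d, %d genes assigned at tau > %g",
            model.K,
            stage_counts["assigned_genes"],
            config.tau,
        )
        write_table(
            assignment.rename("cluster").reset_index(), out / "assignment.tsv"
        )
        write_table(contrast, out / "contrast.tsv")
        write_table(model.selection.reset_index(), out / "gmm_selection.tsv")
        write_table(de.reset_index(), out / "de.tsv")

        # ---- enrich -----------------------------------------------------
        if config.gmt and annotation is not None:
            stage = "enrich"
            try:
                sets = read_gmt(config.gmt)
                dmp_genes = sorted(
                    g
                    for g in annotation.loc[
                        annotation.index.intersection(dmps.index), "gene"
                    ].unique()
                    if g
                )
                universe = sorted(
                    g for g in annotation["gene"].unique() if g
                )
                if dmp_genes:
                    enrich = fisher_enrichment(dmp_genes, universe, sets)
                    write_table(enrich, out / "enrichment.tsv")
                    stage_counts["enriched_sets_nominal"] = int(
                        (enrich["p"] < 0.05).sum()
                    )
            except Exception as exc:
                raise PipelineStageError(stage, str(exc)) from exc

    # ---- manifest -------------------------------------------------------
    manifest_info = {
        "config": asdict(config),
        "stage_counts": stage_counts,
        "versions": {
            "twinmeth": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    write_run_manifest(manifest_info, out / "run_manifest.json")
    return out
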