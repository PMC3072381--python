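"""End-to-end orchestration: simulate -> compose -> score -> classify -> evaluate.

Every stage is a pure function of (inputs, config, seed); the resolved
configuration is written beside the outputs so runs are auditable, and
the report records each filter's in/out window counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from nucret import evaluate, genes as genes_mod, profiles, retention, seqcomp, synthdata

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage id."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All pipeline parameters, with the published defaults."""

    seed: int = 0
    window_bp: int = 150
    shift_bp: int = 75
    min_total_reads: int = 5
    tss_max_dist: int = 50
    rpkm_threshold: float = 0.5
    presence_min_donors: int = 7
    distal_min_dist: int = 1000
    caller_window_bp: int = 300
    caller_step_bp: int = 150
    caller_alpha: float = 0.05
    caller_correction: str = "bh"
    kmer: int = 20
    island_min_len: int = 200
    island_min_gc: float = 0.5
    island_min_oe: float = 0.6
    profile_span_bp: int = 4000
    synth: synthdata.SyntheticConfig = field(default_factory=synthdata.SyntheticConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def retention_params(self) -> retention.RetentionParams:
        return retention.RetentionParams(
            shift_bp=self.shift_bp,
            window_bp=self.window_bp,
            min_total_reads=self.min_total_reads,
            caller_window_bp=self.caller_window_bp,
            caller_step_bp=self.caller_step_bp,
            caller_alpha=self.caller_alpha,
            caller_correction=self.caller_correction,
            subsample_seed=self.seed,
        )


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic pipeline and return the run report.

    The report lists per-stage record counts, the filters applied, and
    the headline statistics (ROC AUC, methylation precision/recall,
    breadth-trend chi-square).  When ``outdir`` is given, tracks,
    regions, annotations, and the resolved config are written there.
    """
    report: dict = {"config": config.to_dict(), "stages": {}}
    synth = config.synth
    if synth.seed != config.seed:
        synth = synthdata.SyntheticConfig(**{**synth.to_dict(), "seed": config.seed})

    # --- simulate ---------------------------------------------------------
    genome, gene_models, class_of = synthdata.generate_genome(synth)
    nuc_reads, input_reads = synthdata.simulate_reads(genome, synth)
    report["stages"]["simulate"] = {
        "chromosomes": len(genome.names),
        "genome_bp": sum(genome.length(c) for c in genome.names),
        "genes": len(gene_models),
        "nuc_reads": len(nuc_reads),
        "input_reads": len(input_reads),
    }

    # --- compose ----------------------------------------------------------
    grid = seqcomp.make_windows(genome, config.window_bp)
    comp = seqcomp.window_base_counts(genome, grid)
    comp.unique = seqcomp.kmer_uniqueness_mask(genome, grid, config.kmer)
    islands = seqcomp.detect_cpg_islands(
        genome, config.island_min_len, config.island_min_gc, config.island_min_oe
    )
    islands_df = seqcomp.islands_to_dataframe(islands)
    report["stages"]["compose"] = {
        "windows": grid.n_windows,
        "windows_with_n": int(comp.has_n.sum()),
        "windows_non_unique": int((~comp.unique).sum()),
        "cpg_islands": len(islands),
    }

    # --- score ------------------------------------------------------------
    if len(nuc_reads) > len(input_reads):
        nuc_scored = retention.subsample_reads(
            nuc_reads, len(input_reads), config.seed
        )
    else:
        nuc_scored = nuc_reads
    nuc_counts = retention.count_centers_in_windows(
        nuc_scored, grid, config.shift_bp
    )
    input_counts = retention.count_centers_in_windows(
        input_reads, grid, config.shift_bp
    )
    track = retention.retention_score_track(
        nuc_counts, input_counts, grid,
        min_total=config.min_total_reads,
        excluded=~comp.analysis_mask(),
    )
    report["stages"]["score"] = {
        "nuc_reads_scored": len(nuc_scored),
        "nuc_centers_in_windows": int(nuc_counts.sum()),
        "input_centers_in_windows": int(input_counts.sum()),
        "windows_low_coverage": int(track.low_coverage.sum()),
        "windows_excluded": int(track.excluded.sum()),
    }

    # --- regions ----------------------------------------------------------
    regions = retention.call_enriched_regions(
        nuc_reads, input_reads, genome, config.retention_params()
    )
    report["stages"]["regions"] = {"regions_called": len(regions)}

    # --- classify ---------------------------------------------------------
    islands_df, rpkm, presence = synthdata.simulate_labels(
        islands_df, regions, class_of, synth
    )
    classes = genes_mod.classify_genes(
        rpkm,
        {g.gene_id: g.go_terms for g in gene_models},
        threshold=config.rpkm_threshold,
    )
    retained = genes_mod.tss_retained_flags(
        gene_models, regions, config.tss_max_dist
    )
    gene_table = classes.copy()
    gene_table["retained"] = pd.Series(
        retained, index=[g.gene_id for g in gene_models]
    ).reindex(gene_table.index)
    location = (
        genes_mod.classify_regions(regions, gene_models, config.tss_max_dist)
        if len(regions)
        else pd.Series(dtype=object)
    )
    report["stages"]["classify"] = {
        "genes_retained_at_tss": int(gene_table["retained"].sum()),
        "region_locations": location.value_counts().to_dict(),
        "class_sizes": {
            k: int(classes[k].sum())
            for k in ("housekeeping", "tissue_specific", "developmental_TF")
        },
    }

    # --- evaluate ---------------------------------------------------------
    try:
        keep = track.analysis_mask()
        labels = evaluate.windows_overlapping_regions(grid, regions)
        roc = evaluate.roc_auc(comp.gc_count[keep], labels[keep])
        roc_cpg = evaluate.roc_auc(comp.cpg_count[keep], labels[keep])
        island_windows = evaluate.windows_overlapping_regions(
            grid,
            islands_df.rename(columns=str)[["chrom", "start", "end"]],
        )
        sens, spec = evaluate.binary_predictor_point(
            island_windows[keep], labels[keep]
        )
    except evaluate.UndefinedStatisticError as exc:
        raise PipelineStageError("roc", str(exc)) from exc

    try:
        table, precision, recall = evaluate.methylation_overlap_stats(
            islands_df, regions
        )
    except (seqcomp.ParameterError, evaluate.UndefinedStatisticError) as exc:
        raise PipelineStageError("methyl-eval", str(exc)) from exc

    trend_bins = (
        gene_table.dropna(subset=["retained"])
        .groupby("breadth")
        .agg(total=("retained", "size"), successes=("retained", "sum"))
        .reset_index()
    )
    chi2, pval = evaluate.cochran_armitage_trend(
        trend_bins["total"], trend_bins["successes"], trend_bins["breadth"]
    )

    report["headline"] = {
        "auc_gc": roc.auc,
        "auc_cpg": roc_cpg.auc,
        "island_sensitivity": sens,
        "island_specificity": spec,
        "methyl_precision": precision,
        "methyl_recall": recall,
        "methyl_contingency": table.as_array().tolist(),
        "trend_chi2": chi2,
        "trend_p": pval,
        "windows_in_roc": int(keep.sum()),
    }

    # --- profile ----------------------------------------------------------
    score_vals = np.where(track.analysis_mask(), track.score, np.nan)
    by_class: dict[str, dict] = {}
    for label in ("housekeeping", "tissue_specific", "developmental_TF"):
        members = [g for g in gene_models if class_of[g.gene_id] == label]
        if not members:
            continue
        anchors = [(g.chrom, g.tss, g.strand) for g in members]
        prof = profiles.meta_profile(
            score_vals, grid, anchors, span=config.profile_span_bp
        )
        by_class[label] = {
            "n_genes": len(members),
            "center_mean": float(prof.mean[len(prof.mean) // 2]),
        }
    report["stages"]["profile"] = by_class

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(outdir / "genome.fa")
        genes_mod.genes_to_tsv(gene_models, outdir / "genes.tsv")
        nuc_reads.to_csv(outdir / "nuc_reads.tsv", sep="\t", index=False)
        input_reads.to_csv(outdir / "input_reads.tsv", sep="\t", index=False)
        comp.to_tsv(outdir / "windows.tsv")
        track.to_dataframe().to_csv(outdir / "retention.tsv", sep="\t", index=False)
        regions.to_csv(outdir / "regions.bed", sep="\t", index=False, header=False)
        islands_df.to_csv(outdir / "cpg_islands.tsv", sep="\t", index=False)
        synthdata.write_expression_tsv(rpkm, outdir / "expression.tsv")
        synthdata.write_presence_tsv(presence, outdir / "presence.tsv")
        with open(outdir / "run_config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
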