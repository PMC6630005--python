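"""End-to-end orchestration: scan both traits, combine, validate expression.

Given two summary tables, a reference panel, gene annotation and any number
of expression datasets, :func:`run_pipeline` produces per-trait gene tables,
the shared-gene (pleiotropy) table sorted by combined p-value, and one
differential-expression table per dataset, all written as TSV alongside a
run log. A fixed seed makes the whole run byte-identical on rerun.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .cross_trait import (
    FusionMap,
    bonferroni_threshold,
    build_shared_records,
    pleiotropy_table,
)
from .expression import screen_candidates
from .gene_test import GeneTestResult, run_scan
from .io import AnalysisConfig, ExpressionDataset, GeneModel, ReferencePanel, SnpAssociation

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "InputBundle", "run_pipeline", "run_pipeline_from_paths"]


@dataclass
class InputBundle:
    """File paths of one pipeline run (the shape the CLI assembles)."""

    summary_a: str
    summary_b: str
    panel: str
    genes: str
    expression: list[tuple[str, str, str | None]] = field(default_factory=list)
    # each expression entry: (matrix_path, labels_path, optional mapping_path)
    fusion_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PipelineResult:
    results_a: list[GeneTestResult]
    results_b: list[GeneTestResult]
    n_shared: int
    threshold: float | None
    shared_table: pd.DataFrame
    expression_tables: dict[str, pd.DataFrame]
    n_distinct_flagged: int
    n_distinct_after_fusion: int


def _gene_results_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "chrom": r.chrom,
                "n_snps": r.n_snps,
                "statistic": r.statistic,
                "p_gene": r.p_gene,
                "top_snp": r.top_snp,
                "top_snp_p": r.top_snp_p,
                "n_sims": r.n_sims_used,
            }
            for r in results
        ],
        columns=[
            "gene", "chrom", "n_snps", "statistic", "p_gene",
            "top_snp", "top_snp_p", "n_sims",
        ],
    )


def run_pipeline(
    snps_a: list[SnpAssociation],
    snps_b: list[SnpAssociation],
    panel: ReferencePanel,
    genes: list[GeneModel],
    expression_datasets: list[ExpressionDataset] | None = None,
    config: AnalysisConfig | None = None,
    fusion_map: FusionMap | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pleiotropy analysis on in-memory inputs.

    Candidate genes for the expression stage are the distinct genes flagged
    by the Bonferroni cutoff in the shared-gene table. When ``out_dir`` is
    given, all tables plus ``run.log`` are written there.
    """
    config = config or AnalysisConfig()
    logger.info("scanning trait A (%d SNPs, %d genes)", len(snps_a), len(genes))
    results_a = run_scan(snps_a, genes, panel, config)
    logger.info("scanning trait B (%d SNPs, %d genes)", len(snps_b), len(genes))
    results_b = run_scan(snps_b, genes, panel, config)

    shared = build_shared_records(results_a, results_b, config.alpha_nominal)
    n_shared = len(shared)
    threshold = (
        bonferroni_threshold(n_shared, config.n_phenotypes) if n_shared else None
    )
    rows, n_flagged, n_after = pleiotropy_table(shared, fusion_map, threshold)
    shared_df = pd.DataFrame(
        [
            {
                "region": r.region,
                "gene": r.gene,
                "p_a": r.p_a,
                "top_snp_a": r.top_snp_a,
                "top_snp_a_p": r.top_snp_a_p,
                "p_b": r.p_b,
                "top_snp_b": r.top_snp_b,
                "top_snp_b_p": r.top_snp_b_p,
                "x2": r.x2,
                "p_combined": r.p_combined,
                "passes": r.passes_bonferroni,
            }
            for r in rows
        ],
        columns=[
            "region", "gene", "p_a", "top_snp_a", "top_snp_a_p",
            "p_b", "top_snp_b", "top_snp_b_p", "x2", "p_combined", "passes",
        ],
    )
    logger.info(
        "N=%d shared nominal genes; threshold=%s; %d flagged (%d after fusion collapse)",
        n_shared,
        f"{threshold:.5E}" if threshold is not None else "n/a",
        n_flagged,
        n_after,
    )

    candidates = sorted(
        shared_df.loc[shared_df["passes"].astype(bool), "gene"].tolist()
    )
    expr_tables: dict[str, pd.DataFrame] = {}
    for ds in expression_datasets or []:
        screened = screen_candidates(
            candidates, ds, config.fold_change_log2_cutoff, config.alpha_nominal
        )
        expr_tables[ds.dataset_name] = pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "p": r.p,
                    "log2fc": r.log2fc,
                    "n_transcripts": r.n_transcripts,
                    "present": r.present,
                    "significant": r.significant,
                    "large_fold_change": r.large_fold_change,
                }
                for r in screened
            ],
            columns=[
                "gene", "p", "log2fc", "n_transcripts",
                "present", "significant", "large_fold_change",
            ],
        )

    result = PipelineResult(
        results_a=results_a,
        results_b=results_b,
        n_shared=n_shared,
        threshold=threshold,
        shared_table=shared_df,
        expression_tables=expr_tables,
        n_distinct_flagged=n_flagged,
        n_distinct_after_fusion=n_after,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir), config)
    return result


def _write_bundle(result: PipelineResult, out_dir: Path, config: AnalysisConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pio.write_table(_gene_results_frame(result.results_a), out_dir / "genes_trait_a.tsv")
    pio.write_table(_gene_results_frame(result.results_b), out_dir / "genes_trait_b.tsv")
    pio.write_table(result.shared_table, out_dir / "shared_genes.tsv")
    for name, df in result.expression_tables.items():
        pio.write_table(df, out_dir / f"expression_{name}.tsv")
    log_lines = [
        f"seed\t{config.rng_seed}",
        f"alpha_nominal\t{config.alpha_nominal}",
        f"r2_proxy_threshold\t{config.r2_proxy_threshold}",
        f"flank_bp\t{config.flank_bp}",
        f"mc_schedule\t{','.join(str(n) for n in config.mc_schedule)}",
        f"n_shared\t{result.n_shared}",
        f"threshold\t{'' if result.threshold is None else format(result.threshold, '.5E')}",
        f"n_flagged\t{result.n_distinct_flagged}",
        f"n_flagged_after_fusion\t{result.n_distinct_after_fusion}",
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")


def run_pipeline_from_paths(
    bundle: InputBundle,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Load every input from disk, then :func:`run_pipeline`.

    Errors from any stage are re-raised with the stage name prefixed.
    """
    config = config or AnalysisConfig()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    snps_a = _stage("read summary A", pio.read_gwas_summary, bundle.summary_a, config.maf_min)
    snps_b = _stage("read summary B", pio.read_gwas_summary, bundle.summary_b, config.maf_min)
    panel = _stage("read panel", pio.read_reference_panel, bundle.panel)
    genes = _stage("read genes", pio.read_gene_annotation, bundle.genes)
    datasets = [
        _stage("read expression", pio.read_expression_dataset, m, l, mp)
        for m, l, mp in bundle.expression
    ]
    fusion = FusionMap(pairs=list(bundle.fusion_pairs)) if bundle.fusion_pairs else None
    return _stage(
        "analysis",
        run_pipeline,
        snps_a, snps_b, panel, genes, datasets, config, fusion, out_dir,
    )
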