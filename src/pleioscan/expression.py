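"""Case/control differential-expression screening of candidate genes.

Each transcript is tested with Welch's unequal-variance two-sample t-test
on log2-scale values; the fold change is the case-minus-control difference
of mean log2 expression. When a gene has several transcripts the one with
the smallest p-value represents the gene (its p AND its log2FC). Within a
dataset, significance is Bonferroni-corrected for the number of candidate
genes actually present there: threshold = 0.05 / n_present. A |log2FC|
above a configurable cutoff (default 1, i.e. a 2-fold change in either
direction) is flagged separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "differential_test",
    "collapse_to_gene",
    "dataset_threshold",
    "screen_candidates",
]

_P_FLOOR = np.nextafter(0.0, 1.0)  # degenerate zero-variance separation


@dataclass
class DifferentialResult:
    """Per-gene differential-expression summary for one dataset."""

    gene: str
    dataset: str
    p: float
    log2fc: float
    n_transcripts: int
    present: bool
    significant: bool = False
    large_fold_change: bool = False


def differential_test(
    values_case: np.ndarray | list[float], values_ctrl: np.ndarray | list[float]
) -> tuple[float, float]:
    """Welch two-sided t-test and log2 fold change (case mean - control mean).

    Degenerate inputs: if both groups have zero variance the test statistic
    is undefined; equal means give p = 1, unequal means give the smallest
    positive p (reported with a warning).
    """
    case = np.asarray(values_case, dtype=float)
    ctrl = np.asarray(values_ctrl, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need at least 2 samples per group")
    log2fc = float(case.mean() - ctrl.mean())
    if case.std(ddof=1) == 0 and ctrl.std(ddof=1) == 0:
        if np.isclose(log2fc, 0.0):
            return 1.0, log2fc
        logger.warning("zero-variance groups with unequal means: degenerate p")
        return float(_P_FLOOR), log2fc
    t = stats.ttest_ind(case, ctrl, equal_var=False)
    return float(t.pvalue), log2fc


def collapse_to_gene(
    transcript_results: list[tuple[str, str, float, float]],
    dataset: str = "",
) -> dict[str, DifferentialResult]:
    """Collapse (transcript, gene, p, log2fc) rows to one row per gene.

    The transcript with the smallest p-value supplies both the gene's p and
    its log2FC. Order-invariant: ties on p are broken by transcript id.
    """
    by_gene: dict[str, list[tuple[float, str, float]]] = {}
    for transcript, gene, p, log2fc in transcript_results:
        if not gene:
            continue  # unmappable symbol: excluded downstream
        by_gene.setdefault(gene, []).append((p, transcript, log2fc))
    out = {}
    for gene, rows in by_gene.items():
        p, _transcript, log2fc = min(rows)
        out[gene] = DifferentialResult(
            gene=gene,
            dataset=dataset,
            p=p,
            log2fc=log2fc,
            n_transcripts=len(rows),
            present=True,
        )
    return out


def dataset_threshold(n_present: int, alpha: float = 0.05) -> float:
    """Per-dataset Bonferroni threshold alpha / (candidate genes present)."""
    if n_present < 1:
        raise ValueError("n_present must be positive")
    return alpha / n_present


def screen_candidates(
    candidates: list[str],
    dataset: ExpressionDataset,
    fc_cutoff_log2: float = 1.0,
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Screen candidate genes for differential expression in one dataset.

    Tests every transcript of every candidate present in the dataset,
    collapses to genes by the smallest-p rule, then applies the per-dataset
    Bonferroni threshold alpha / n_present where n_present counts candidate
    genes with at least one transcript here. Candidates with no transcript
    are reported with ``present=False`` (and do not enter the denominator).
    Output order follows the candidate list.
    """
    wanted = set(candidates)
    rows = []
    for i, (transcript, gene) in enumerate(
        zip(dataset.transcript_ids, dataset.gene_symbols)
    ):
        if gene in wanted:
            case, ctrl = dataset.values_for(i)
            p, log2fc = differential_test(case, ctrl)
            rows.append((transcript, gene, p, log2fc))
    collapsed = collapse_to_gene(rows, dataset.dataset_name)

    n_present = len(collapsed)
    if n_present == 0:
        logger.warning(
            "%s: no candidate genes present in dataset", dataset.dataset_name
        )
        return []
    threshold = dataset_threshold(n_present, alpha)

    out = []
    for g in candidates:
        if g in collapsed:
            r = collapsed[g]
            r.significant = r.p < threshold
            r.large_fold_change = abs(r.log2fc) > fc_cutoff_log2
            out.append(r)
        else:
            out.append(
                DifferentialResult(
                    g, dataset.dataset_name, float("nan"), float("nan"), 0, False
                )
            )
    return out
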