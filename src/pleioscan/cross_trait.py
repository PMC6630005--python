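"""Cross-trait combination of gene-based results.

Genes nominally significant (p < 0.05) in BOTH traits form the shared set
of size N. Each shared gene's two p-values are combined by Fisher's method,

    x^2 = -2 * (ln p_A + ln p_B)   ~   chi-square with 2k df  (k = 2 traits),

and the combined p-value is judged against a Bonferroni threshold of
0.05 / (k * N), which corrects for both the number of shared genes and the
number of phenotypes. Gene pairs known to arise from the same signal (e.g.
a fusion transcript and its parent gene) can be collapsed to a single
reported gene via an explicit fusion map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gene_test import GeneTestResult

logger = logging.getLogger(__name__)

__all__ = [
    "SharedGeneRecord",
    "FusionMap",
    "overlap_shared_genes",
    "fisher_combine",
    "bonferroni_threshold",
    "build_shared_records",
    "pleiotropy_table",
]


@dataclass
class SharedGeneRecord:
    """One gene's cross-trait record: both per-trait results plus Fisher's
    combination."""

    gene: str
    p_a: float
    p_b: float
    x2: float
    p_combined: float
    k: int = 2
    region: str = ""
    top_snp_a: str = ""
    top_snp_a_p: float = float("nan")
    top_snp_b: str = ""
    top_snp_b_p: float = float("nan")
    passes_bonferroni: bool = False

    @property
    def df(self) -> int:
        return 2 * self.k


@dataclass
class FusionMap:
    """Pairs of gene symbols to be reported as one gene (fusion transcript
    and parent). Collapsing keeps the record with the smaller combined p."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def partner(self, gene: str) -> str | None:
        for a, b in self.pairs:
            if gene == a:
                return b
            if gene == b:
                return a
        return None


def overlap_shared_genes(
    results_a: list[GeneTestResult],
    results_b: list[GeneTestResult],
    alpha: float = 0.05,
) -> list[str]:
    """Genes with p strictly below ``alpha`` in BOTH traits, sorted by symbol.

    The length of the returned list is the N of the Bonferroni step.
    """
    nominal_a = {r.gene for r in results_a if r.p_gene < alpha}
    nominal_b = {r.gene for r in results_b if r.p_gene < alpha}
    return sorted(nominal_a & nominal_b)


def fisher_combine(p_values: list[float] | np.ndarray) -> tuple[float, float]:
    """Fisher's method: combine k p-values into (x2, combined p).

    x2 = -2 * sum(ln p_i) is referred to the chi-square distribution with
    2k degrees of freedom. Symmetric in its inputs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 2:
        raise ValueError("fisher_combine requires at least two p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.log(p).sum())
    return x2, float(stats.chi2.sf(x2, df=2 * p.size))


def bonferroni_threshold(n_tests: int, n_phenotypes: int = 2) -> float:
    """Family-wise threshold 0.05 / (n_phenotypes * n_tests)."""
    if n_tests < 1 or n_phenotypes < 1:
        raise ValueError("counts must be positive")
    return 0.05 / (n_phenotypes * n_tests)


def build_shared_records(
    results_a: list[GeneTestResult],
    results_b: list[GeneTestResult],
    alpha: float = 0.05,
    regions: dict[str, str] | None = None,
) -> list[SharedGeneRecord]:
    """Overlap the two scans and Fisher-combine every shared gene.

    Combination is applied only to the post-selection shared set; the
    returned list length is the N that sets the Bonferroni threshold.
    """
    shared = overlap_shared_genes(results_a, results_b, alpha)
    by_a = {r.gene: r for r in results_a}
    by_b = {r.gene: r for r in results_b}
    records = []
    for g in shared:
        ra, rb = by_a[g], by_b[g]
        x2, p_comb = fisher_combine([ra.p_gene, rb.p_gene])
        records.append(
            SharedGeneRecord(
                gene=g,
                p_a=ra.p_gene,
                p_b=rb.p_gene,
                x2=x2,
                p_combined=p_comb,
                region=(regions or {}).get(g, ""),
                top_snp_a=ra.top_snp,
                top_snp_a_p=ra.top_snp_p,
                top_snp_b=rb.top_snp,
                top_snp_b_p=rb.top_snp_p,
            )
        )
    return records


def pleiotropy_table(
    shared: list[SharedGeneRecord],
    fusion_map: FusionMap | None = None,
    threshold: float | None = None,
) -> tuple[list[SharedGeneRecord], int, int]:
    """Flag, collapse and sort the shared-gene records.

    Rows with ``p_combined < threshold`` (default 0.05/(2N) from the input
    size) are flagged; fusion pairs are collapsed to the record with the
    smaller combined p; output is sorted ascending by p_combined with ties
    broken by symbol. Returns ``(rows, n_distinct_before, n_distinct_after)``
    where the distinct counts refer to flagged genes before and after
    collapsing.
    """
    if threshold is None and shared:
        threshold = bonferroni_threshold(len(shared), 2)
    records = [
        SharedGeneRecord(**{**r.__dict__, "passes_bonferroni": r.p_combined < threshold})
        for r in shared
    ] if shared else []

    n_before = sum(r.passes_bonferroni for r in records)
    if fusion_map is not None:
        present = {r.gene for r in records}
        drop: set[str] = set()
        for a, b in fusion_map.pairs:
            if a not in present or b not in present:
                logger.warning("fusion pair (%s, %s) not fully present; not collapsed", a, b)
                continue
            ra = next(r for r in records if r.gene == a)
            rb = next(r for r in records if r.gene == b)
            loser = ra if ra.p_combined > rb.p_combined else rb
            drop.add(loser.gene)
        records = [r for r in records if r.gene not in drop]
    n_after = sum(r.passes_bonferroni for r in records)

    records.sort(key=lambda r: (r.p_combined, r.gene))
    return records, n_before, n_after
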