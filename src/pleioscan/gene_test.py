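"""Gene-based association test from GWAS summary statistics.

The test collapses all SNPs assigned to a gene into one statistic

    T = sum_j  Q_chi2(1)(1 - p_j)

where ``Q_chi2(1)`` is the quantile function of the 1-df chi-square (the
squared-z transform of a two-sided p-value). Under the null the vector of
SNP z-scores is multivariate normal with covariance equal to the LD
correlation matrix of the assigned SNPs, so the null distribution of T is
obtained by Monte Carlo: draw z ~ MVN(0, R), form sum z^2, and estimate

    p_gene = (r + 1) / (N + 1),   r = #{T_null >= T_obs}

with an adaptive simulation schedule that only escalates N for genes whose
p-value estimate is small. A gene's SNP set is its member SNPs (inside the
span, zero flank by default) plus LD proxies outside the span with
r^2 above a threshold to at least one member.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import AnalysisConfig, GeneModel, ReferencePanel, SnpAssociation

__all__ = [
    "LdMatrix",
    "GeneAssignment",
    "GeneTestResult",
    "ld_correlation_matrix",
    "map_snps_to_genes",
    "gene_statistic",
    "empirical_gene_pvalue",
    "run_scan",
]

_P_CLAMP = 1e-300  # floor applied before the chi-square transform
_EIG_FLOOR = 1e-8  # eigenvalue clip for rank-deficient panel matrices


@dataclass
class LdMatrix:
    """Regularized SNP correlation matrix estimated from a reference panel."""

    snp_ids: list[str]
    r: np.ndarray  # symmetric, unit diagonal, eigenvalues >= _EIG_FLOOR

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class GeneAssignment:
    """SNPs attributed to one gene: members inside the span plus LD proxies."""

    gene: GeneModel
    member_snps: list[str]
    proxy_snps: list[str]

    @property
    def assigned(self) -> list[str]:
        return self.member_snps + self.proxy_snps


@dataclass
class GeneTestResult:
    gene: str
    chrom: str
    n_snps: int
    statistic: float
    p_gene: float
    top_snp: str
    top_snp_p: float
    n_sims_used: int


def _regularize(r: np.ndarray) -> np.ndarray:
    """Clip eigenvalues from below, then rescale back to unit diagonal."""
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    if w.min() >= _EIG_FLOOR:
        return r
    w = np.clip(w, _EIG_FLOOR, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def ld_correlation_matrix(panel: ReferencePanel, snp_ids: list[str]) -> LdMatrix:
    """Pearson correlation of dosage columns for the requested SNPs.

    Raises for monomorphic SNPs (their correlation is undefined). Matrices
    estimated from few haplotypes are often rank-deficient; eigenvalues are
    clipped at 1e-8 and the matrix rescaled to unit diagonal so it is a
    valid MVN covariance.
    """
    idx = panel.index_of(snp_ids)
    mono = panel.monomorphic[idx]
    if mono.any():
        bad = [s for s, m in zip(snp_ids, mono) if m]
        raise ValueError(f"monomorphic SNPs have no LD: {bad}")
    cols = panel.dosages[:, idx].astype(float)
    if len(snp_ids) == 1:
        return LdMatrix(list(snp_ids), np.ones((1, 1)))
    r = np.corrcoef(cols, rowvar=False)
    return LdMatrix(list(snp_ids), _regularize(r))


def map_snps_to_genes(
    snps: list[SnpAssociation],
    genes: list[GeneModel],
    panel: ReferencePanel,
    r2_threshold: float = 0.8,
    flank_bp: int = 0,
) -> list[GeneAssignment]:
    """Assign SNPs to genes: members by position, proxies by LD.

    Members are SNPs with ``start - flank < pos <= end + flank`` (BED
    half-open vs 1-based SNP positions). Proxies are same-chromosome
    non-member SNPs whose r^2 with at least one member exceeds the
    threshold, computed from the panel. A SNP may serve several genes.
    Genes with no assigned SNP are omitted. SNPs absent from the panel (or
    monomorphic in it) cannot enter the LD null and are ignored.
    """
    panel_ids = set(panel.snps["snp_id"])
    mono = dict(zip(panel.snps["snp_id"], panel.monomorphic))
    usable = [s for s in snps if s.snp_id in panel_ids and not mono[s.snp_id]]

    by_chrom: dict[str, list[SnpAssociation]] = {}
    for s in usable:
        by_chrom.setdefault(s.chrom, []).append(s)

    out: list[GeneAssignment] = []
    for gene in genes:
        chrom_snps = by_chrom.get(gene.chrom, [])
        members = [s.snp_id for s in chrom_snps if gene.contains(s.pos, flank_bp)]
        proxies: list[str] = []
        if members:
            candidates = [s.snp_id for s in chrom_snps if s.snp_id not in set(members)]
            if candidates:
                m_idx = panel.index_of(members)
                c_idx = panel.index_of(candidates)
                m = panel.dosages[:, m_idx].astype(float)
                c = panel.dosages[:, c_idx].astype(float)
                m = (m - m.mean(0)) / m.std(0)
                c = (c - c.mean(0)) / c.std(0)
                r = (c.T @ m) / m.shape[0]  # candidates x members
                hit = (r**2 > r2_threshold).any(axis=1)
                proxies = [cid for cid, h in zip(candidates, hit) if h]
        if members:
            out.append(GeneAssignment(gene, members, proxies))
    return out


def gene_statistic(pvalues: list[float] | np.ndarray) -> float:
    """Sum of 1-df chi-square quantiles of the SNP p-values.

    p-values are clamped at 1e-300 before the transform to keep the
    quantile finite; a p of exactly 1 contributes 0.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("gene_statistic requires at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    p = np.clip(p, _P_CLAMP, 1.0)
    return float(stats.chi2.isf(p, df=1).sum())


def empirical_gene_pvalue(
    t_obs: float,
    ld: LdMatrix,
    mc_schedule: tuple[int, ...] = (10**3, 10**4, 10**5, 10**6),
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, int]:
    """Monte-Carlo p-value of the gene statistic under the MVN null.

    Draws z ~ MVN(0, R) through a symmetric eigenfactorization, forms
    T_null = sum z^2 and returns ``(r+1)/(N+1)`` with r the count of null
    statistics at or above ``t_obs``. Stages of the schedule escalate only
    while the estimate is small (p_hat <= 10 / N_stage), so cheap genes stop
    early and small p-values get enough draws for bounded relative error.
    """
    if t_obs < 0:
        raise ValueError("t_obs must be non-negative")
    w, v = np.linalg.eigh(ld.r)
    if w.min() <= 0:
        raise np.linalg.LinAlgError("LD matrix not positive definite after regularization")
    factor = v * np.sqrt(w)  # m x m; factor @ factor.T == R
    rng = np.random.default_rng(seed)
    m = ld.n_snps

    p_hat, n_used = 1.0, 0
    for stage_i, n_sims in enumerate(mc_schedule):
        hits = 0
        chunk = 200_000
        done = 0
        while done < n_sims:
            k = min(chunk, n_sims - done)
            z = rng.standard_normal((k, m)) @ factor.T
            hits += int(np.count_nonzero((z**2).sum(axis=1) >= t_obs))
            done += k
        p_hat = (hits + 1) / (n_sims + 1)
        n_used = n_sims
        if p_hat > 10.0 / n_sims:
            break  # estimate is well resolved at this stage
    return p_hat, n_used


def _gene_seed(root_seed: int, gene_symbol: str) -> np.random.SeedSequence:
    """Stable per-gene RNG stream, independent of gene ordering."""
    return np.random.SeedSequence([int(root_seed), zlib.crc32(gene_symbol.encode())])


def run_scan(
    snps: list[SnpAssociation],
    genes: list[GeneModel],
    panel: ReferencePanel,
    config: AnalysisConfig | None = None,
) -> list[GeneTestResult]:
    """Gene-based scan of one trait: assignment, statistic, MVN null.

    Returns one result per gene with at least one assigned SNP, sorted
    ascending by p-value (ties broken by symbol). The top-SNP is the
    assigned SNP with the smallest p-value (ties broken by id).
    """
    config = config or AnalysisConfig()
    p_by_snp = {s.snp_id: s.pvalue for s in snps}
    assignments = map_snps_to_genes(
        snps, genes, panel, config.r2_proxy_threshold, config.flank_bp
    )
    results: list[GeneTestResult] = []
    for a in assignments:
        ids = a.assigned
        pvals = np.array([p_by_snp[s] for s in ids])
        t_obs = gene_statistic(pvals)
        ld = ld_correlation_matrix(panel, ids)
        p_gene, n_used = empirical_gene_pvalue(
            t_obs, ld, config.mc_schedule, _gene_seed(config.rng_seed, a.gene.symbol)
        )
        top = min(zip(pvals, ids))  # ties fall through to lexicographic id
        results.append(
            GeneTestResult(
                gene=a.gene.symbol,
                chrom=a.gene.chrom,
                n_snps=len(ids),
                statistic=t_obs,
                p_gene=p_gene,
                top_snp=top[1],
                top_snp_p=float(top[0]),
                n_sims_used=n_used,
            )
        )
    results.sort(key=lambda r: (r.p_gene, r.gene))
    return results
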