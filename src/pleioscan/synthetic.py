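"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all driven by one :class:`SimulationSpec` and one seed:

* a reference panel of dosages whose haplotypes carry first-order
  autoregressive (AR(1)) correlation within LD blocks and independence
  between blocks;
* a pair of GWAS summary-statistics tables generated directly at the
  z-score level: per block, z ~ MVN(Sigma @ lambda, Sigma) where Sigma is
  the block's panel correlation matrix and lambda is zero except at planted
  causal SNPs — the standard asymptotic equivalence to individual-level
  association, which makes the gene test's null exactly the model it
  assumes and so permits sharp calibration checks;
* a transcripts x samples log2 expression matrix with planted case/control
  fold changes on selected genes.

The haplotype model is a latent-Gaussian threshold: each haplotype's latent
vector follows an AR(1) with parameter rho within a block and the allele at
a SNP is 1 when the latent value falls below the quantile of that SNP's
allele frequency. Adjacent-SNP allele correlation is then monotone in rho
(slightly attenuated relative to the latent scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gene_test import _regularize
from .io import ExpressionDataset, GeneModel, ReferencePanel, SnpAssociation

__all__ = [
    "SimulationSpec",
    "make_demo_spec",
    "simulate_reference_panel",
    "simulate_summary_pair",
    "simulate_expression_dataset",
]

_SNP_SPACING_BP = 1000  # synthetic SNP grid spacing on chromosome "1"

# fixed offsets deriving independent per-stage RNG streams from spec.seed
_STREAM_PANEL = 0
_STREAM_TRAIT_A = 1
_STREAM_TRAIT_B = 2
_STREAM_EXPRESSION = 3


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    ``blocks`` is a list of ``(n_snps, rho)`` LD blocks laid consecutively
    on one chromosome; ``genes`` are BED-convention spans over that SNP
    grid. ``shared_effect_genes`` maps a gene symbol to the non-centrality
    planted at its causal SNP for each trait; ``de_genes`` maps a gene
    symbol to a planted log2 fold change in the expression generator.
    """

    n_individuals: int = 300
    blocks: list[tuple[int, float]] = field(default_factory=lambda: [(10, 0.8)])
    maf_range: tuple[float, float] = (0.05, 0.5)
    genes: list[GeneModel] = field(default_factory=list)
    shared_effect_genes: dict[str, tuple[float, float]] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.blocks or any(n < 1 for n, _ in self.blocks):
            raise ValueError("each LD block needs at least one SNP")
        if any(not 0 <= rho < 1 for _, rho in self.blocks):
            raise ValueError("block rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_snps(self) -> int:
        return sum(n for n, _ in self.blocks)

    def rng(self, stream: int) -> np.random.Generator:
        """Named per-stage generator: reproducible independently of the
        other stages."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    def snp_positions(self) -> np.ndarray:
        """1-based positions of the SNP grid (fixed spacing)."""
        return _SNP_SPACING_BP * (np.arange(self.n_snps) + 1)

    def block_slices(self) -> list[slice]:
        edges = np.cumsum([0] + [n for n, _ in self.blocks])
        return [slice(int(a), int(b)) for a, b in zip(edges, edges[1:])]


def make_demo_spec(
    n_blocks: int = 10,
    snps_per_block: int = 10,
    rho: float = 0.8,
    n_individuals: int = 300,
    shared_gene_ncp: float = 6.0,
    n_shared_genes: int = 1,
    de_log2fc: float = 2.0,
    n_de_genes: int = 1,
    seed: int = 0,
) -> SimulationSpec:
    """A ready-made spec: one gene per LD block, the first block(s) carrying
    a planted shared association and planted differential expression."""
    blocks = [(snps_per_block, rho)] * n_blocks
    genes = []
    for b in range(n_blocks):
        # gene spans its whole block, BED half-open over the 1-based grid
        first = b * snps_per_block
        start = _SNP_SPACING_BP * (first + 1) - 1
        end = _SNP_SPACING_BP * (first + snps_per_block)
        genes.append(GeneModel(f"G{b:03d}", "1", start, end))
    shared = {
        genes[i].symbol: (shared_gene_ncp, shared_gene_ncp) for i in range(n_shared_genes)
    }
    de = {genes[i].symbol: de_log2fc for i in range(n_de_genes)}
    return SimulationSpec(
        n_individuals=n_individuals,
        blocks=blocks,
        genes=genes,
        shared_effect_genes=shared,
        de_genes=de,
        seed=seed,
    )


def simulate_reference_panel(spec: SimulationSpec) -> ReferencePanel:
    """Dosage panel with AR(1) within-block haplotype LD.

    2 * n_individuals haplotypes are drawn; each block's latent Gaussian
    follows an AR(1) with the block's rho; alleles arise by thresholding at
    the per-SNP allele-frequency quantile (frequency uniform in maf_range);
    dosage = sum of the individual's two haplotypes.
    """
    rng = spec.rng(_STREAM_PANEL)
    n_hap = 2 * spec.n_individuals
    freqs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    thresholds = stats.norm.ppf(freqs)

    latent = np.empty((n_hap, spec.n_snps))
    for sl, (n_snps, rho) in zip(spec.block_slices(), spec.blocks):
        z = np.empty((n_hap, n_snps))
        z[:, 0] = rng.standard_normal(n_hap)
        innov = rng.standard_normal((n_hap, n_snps - 1)) if n_snps > 1 else None
        for j in range(1, n_snps):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * innov[:, j - 1]
        latent[:, sl] = z

    alleles = (latent < thresholds).astype(np.int8)
    dosages = alleles[0::2] + alleles[1::2]
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{i:05d}" for i in range(spec.n_snps)],
            "chrom": "1",
            "pos": spec.snp_positions(),
        }
    )
    return ReferencePanel(snps=meta, dosages=dosages)


def _causal_indices(spec: SimulationSpec, panel: ReferencePanel) -> dict[str, int]:
    """Block-central member SNP of each planted gene."""
    pos = panel.snps["pos"].to_numpy()
    out = {}
    for gene in spec.genes:
        if gene.symbol not in spec.shared_effect_genes:
            continue
        members = np.flatnonzero((pos > gene.start) & (pos <= gene.end))
        if members.size == 0:
            raise ValueError(f"causal gene {gene.symbol} covers no panel SNP")
        out[gene.symbol] = int(members[members.size // 2])
    return out


def simulate_summary_pair(
    panel: ReferencePanel, spec: SimulationSpec
) -> tuple[list[SnpAssociation], list[SnpAssociation]]:
    """Two GWAS summary tables (trait A, trait B) over the panel's SNPs.

    Per block, z ~ MVN(Sigma @ lambda, Sigma) with Sigma the regularized
    block correlation from the panel and lambda carrying each causal SNP's
    non-centrality; p = 2 * (1 - Phi(|z|)). The two traits are drawn
    independently given their own lambda.
    """
    causal = _causal_indices(spec, panel)
    lam_a = np.zeros(spec.n_snps)
    lam_b = np.zeros(spec.n_snps)
    for sym, (ncp_a, ncp_b) in spec.shared_effect_genes.items():
        if sym not in causal:
            raise ValueError(f"planted gene {sym} not covered by the panel")
        lam_a[causal[sym]] = ncp_a
        lam_b[causal[sym]] = ncp_b

    tables = []
    for lam, stream in ((lam_a, _STREAM_TRAIT_A), (lam_b, _STREAM_TRAIT_B)):
        rng = spec.rng(stream)
        z = np.empty(spec.n_snps)
        for sl in spec.block_slices():
            cols = panel.dosages[:, sl].astype(float)
            keep = cols.std(axis=0) > 0
            sigma = np.eye(sl.stop - sl.start)
            if keep.sum() > 1:
                sub = _regularize(np.corrcoef(cols[:, keep], rowvar=False))
                sigma[np.ix_(keep, keep)] = sub
            mean = sigma @ lam[sl]
            w, v = np.linalg.eigh(sigma)
            factor = v * np.sqrt(np.clip(w, 0, None))
            z[sl] = mean + factor @ rng.standard_normal(sl.stop - sl.start)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        pvals = np.clip(pvals, np.nextafter(0.0, 1.0), 1.0)
        freqs = panel.allele_frequency
        maf = np.minimum(freqs, 1 - freqs)
        tables.append(
            [
                SnpAssociation(
                    snp_id=sid,
                    chrom=chrom,
                    pos=int(pos),
                    pvalue=float(p),
                    maf=float(m),
                )
                for sid, chrom, pos, p, m in zip(
                    panel.snps["snp_id"], panel.snps["chrom"], panel.snps["pos"], pvals, maf
                )
            ]
        )
    return tables[0], tables[1]


def simulate_expression_dataset(
    spec: SimulationSpec,
    n_case: int = 10,
    n_ctrl: int = 10,
    dataset_name: str = "synthetic",
) -> ExpressionDataset:
    """Log2 expression matrix with planted case/control fold changes.

    One transcript per gene in the spec. Controls are Normal(baseline,
    noise_sd) on the log2 scale; cases are shifted by the gene's planted
    log2 fold change (zero for non-DE genes). Baselines are drawn once per
    transcript from Normal(8, 1) — the magnitude range of log2 microarray
    intensities.
    """
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 samples per group")
    rng = spec.rng(_STREAM_EXPRESSION)
    symbols = [g.symbol for g in spec.genes]
    n_genes = len(symbols)
    baselines = rng.normal(8.0, 1.0, size=n_genes)
    shifts = np.array([spec.de_genes.get(s, 0.0) for s in symbols])

    values = rng.normal(0.0, spec.noise_sd, size=(n_genes, n_case + n_ctrl))
    values += baselines[:, None]
    values[:, :n_case] += shifts[:, None]

    return ExpressionDataset(
        values=values,
        transcript_ids=[f"{s}_t1" for s in symbols],
        gene_symbols=list(symbols),
        group_labels=["case"] * n_case + ["control"] * n_ctrl,
        dataset_name=dataset_name,
        sample_ids=[f"case{i+1}" for i in range(n_case)]
        + [f"ctrl{i+1}" for i in range(n_ctrl)],
    )
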