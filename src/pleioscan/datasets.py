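"""Bundled reference tables.

``ad_is_shared_genes`` is the published cross-trait table for Alzheimer's
disease (AD) and ischemic stroke (IS): 17 gene-level records that were
nominally significant in both traits and passed the Bonferroni cutoff
0.05/(2N) with N = 130 shared genes, each carrying the two per-trait
gene-based p-values, the top SNP per trait, and the reported combined
p-value. ANKHD1-EIF4EBP3 is a fusion transcript of ANKHD1 and is reported
as one gene with it, leaving 16 distinct pleiotropic genes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cross_trait import FusionMap

__all__ = [
    "load_ad_is_shared_genes",
    "AD_IS_FUSION_MAP",
    "AD_IS_N_SHARED",
    "AD_IS_N_GENE_TESTS",
]

#: number of genes nominally significant in both the AD and IS scans
AD_IS_N_SHARED = 130

#: genome-wide gene-test counts per trait (AD, IS)
AD_IS_N_GENE_TESTS = {"AD": 21244, "IS": 21913}

#: the fusion-transcript pair collapsed to one reported gene
AD_IS_FUSION_MAP = FusionMap(pairs=[("ANKHD1-EIF4EBP3", "ANKHD1")])


def load_ad_is_shared_genes() -> pd.DataFrame:
    """The 17-row AD/IS pleiotropic-gene table bundled with the package."""
    ref = resources.files("pleioscan").joinpath("data/ad_is_shared_genes.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
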