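import numpy as np
import pandas as pd
import pytest

from pleioscan import GeneModel, ReferencePanel, make_demo_spec


@pytest.fixture
def tiny_panel() -> ReferencePanel:
    """Four SNPs, six individuals; snpC is monomorphic, snpD duplicates snpA."""
    dosages = np.array(
        [
            [0, 0, 0, 0],
            [0, 1, 0, 0],
            [1, 1, 0, 1],
            [1, 2, 0, 1],
            [2, 2, 0, 2],
            [2, 0, 0, 2],
        ],
        dtype=np.int8,
    )
    meta = pd.DataFrame(
        {
            "snp_id": ["snpA", "snpB", "snpC", "snpD"],
            "chrom": ["1"] * 4,
            "pos": [150, 180, 250, 5150],
        }
    )
    return ReferencePanel(snps=meta, dosages=dosages)


@pytest.fixture
def demo_spec():
    return make_demo_spec(n_blocks=5, snps_per_block=8, n_individuals=200, seed=11)


def write_gwas(path, rows, header="snp_id\tchrom\tpos\tpvalue\tmaf"):
    lines = [header] + ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def gwas_writer():
    return write_gwas
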