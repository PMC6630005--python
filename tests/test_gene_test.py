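"""Gene-based test: statistic, LD matrix, MVN null, scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleioscan import (
    AnalysisConfig,
    GeneModel,
    SnpAssociation,
    empirical_gene_pvalue,
    gene_statistic,
    ld_correlation_matrix,
    map_snps_to_genes,
    run_scan,
)
from pleioscan.gene_test import LdMatrix


class TestGeneStatistic:
    # expected values frozen from numeric inversion of the 1-df chi-square
    # CDF (bisection on scipy.special.gammainc-free grid, run once)
    @pytest.mark.parametrize(
        "pvals, expected",
        [([1.0], 0.0), ([0.05], 3.8415), ([0.5, 0.5], 0.9098)],
    )
    def test_known_quantiles(self, pvals, expected):
        assert gene_statistic(pvals) == pytest.approx(expected, abs=1e-3)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            gene_statistic([])

    def test_out_of_range_p_errors(self):
        with pytest.raises(ValueError):
            gene_statistic([0.0])

    def test_tiny_p_clamped_finite(self):
        assert np.isfinite(gene_statistic([1e-320]))

    @given(
        p=st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=1, max_size=6),
        idx=st.integers(0, 5),
        factor=st.floats(0.1, 0.99),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_each_p(self, p, idx, factor):
        idx = idx % len(p)
        lowered = list(p)
        lowered[idx] = p[idx] * factor
        assert gene_statistic(lowered) >= gene_statistic(p)


class TestLdCorrelationMatrix:
    def test_identical_columns_r_is_one(self, tiny_panel):
        ld = ld_correlation_matrix(tiny_panel, ["snpA", "snpD"])
        assert ld.r[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_perfect_anticorrelation(self, tiny_panel):
        import pandas as pd
        from pleioscan import ReferencePanel

        panel = ReferencePanel(
            snps=pd.DataFrame(
                {"snp_id": ["a", "b"], "chrom": ["1", "1"], "pos": [1, 2]}
            ),
            dosages=np.array([[0, 2], [0, 2], [1, 1], [1, 1], [2, 0], [2, 0]]),
        )
        ld = ld_correlation_matrix(panel, ["a", "b"])
        assert ld.r[0, 1] == pytest.approx(-1.0, abs=1e-6)
        assert ld.r2[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_matches_hand_pearson(self):
        # oracle: Pearson r computed by the textbook formula on 4 pairs
        import pandas as pd
        from pleioscan import ReferencePanel

        x, y = [0, 1, 2, 1], [1, 0, 1, 2]
        n = 4
        sx, sy = sum(x), sum(y)
        sxx = sum(v * v for v in x)
        syy = sum(v * v for v in y)
        sxy = sum(a * b for a, b in zip(x, y))
        hand_r = (n * sxy - sx * sy) / (
            ((n * sxx - sx**2) ** 0.5) * ((n * syy - sy**2) ** 0.5)
        )
        panel = ReferencePanel(
            snps=pd.DataFrame(
                {"snp_id": ["a", "b"], "chrom": ["1", "1"], "pos": [1, 2]}
            ),
            dosages=np.array(list(zip(x, y))),
        )
        ld = ld_correlation_matrix(panel, ["a", "b"])
        assert ld.r[0, 1] == pytest.approx(hand_r, abs=1e-12)

    def test_monomorphic_snp_errors_by_name(self, tiny_panel):
        with pytest.raises(ValueError, match="snpC"):
            ld_correlation_matrix(tiny_panel, ["snpA", "snpC"])

    def test_regularized_unit_diagonal_and_psd(self, tiny_panel):
        ld = ld_correlation_matrix(tiny_panel, ["snpA", "snpB", "snpD"])
        assert np.allclose(np.diag(ld.r), 1.0)
        assert np.linalg.eigvalsh(ld.r).min() >= 1e-9


class TestMapSnpsToGenes:
    def _snps(self):
        return [
            SnpAssociation("snpA", "1", 150, 0.01, 0.3),
            SnpAssociation("snpB", "1", 180, 0.5, 0.3),
            SnpAssociation("snpC", "1", 250, 0.5, 0.3),
            SnpAssociation("snpD", "1", 5150, 0.2, 0.3),
        ]

    def test_member_inside_span(self, tiny_panel):
        genes = [GeneModel("G", "1", 100, 200)]
        (a,) = map_snps_to_genes(self._snps(), genes, tiny_panel)
        assert set(a.member_snps) == {"snpA", "snpB"}

    def test_distant_snp_in_high_ld_is_proxy(self, tiny_panel):
        # snpD is 5 kb away but duplicates snpA's dosages -> r^2 = 1 > 0.8
        genes = [GeneModel("G", "1", 100, 200)]
        (a,) = map_snps_to_genes(self._snps(), genes, tiny_panel)
        assert a.proxy_snps == ["snpD"]
        assert set(a.assigned) == {"snpA", "snpB", "snpD"}

    def test_low_ld_snp_unassigned_and_monomorphic_ignored(self, tiny_panel):
        genes = [GeneModel("G", "1", 4000, 6000)]
        (a,) = map_snps_to_genes(self._snps(), genes, tiny_panel)
        # snpD is the only member; snpA duplicates it -> proxy; snpB low LD
        assert a.member_snps == ["snpD"]
        assert a.proxy_snps == ["snpA"]

    def test_gene_without_snps_excluded(self, tiny_panel):
        genes = [GeneModel("EMPTY", "2", 100, 200)]
        assert map_snps_to_genes(self._snps(), genes, tiny_panel) == []

    def test_half_open_boundary_convention(self, tiny_panel):
        # 1-based SNP pos p is a member of BED [start, end) iff start < p <= end
        snps = [SnpAssociation("snpA", "1", 150, 0.5, 0.3)]
        assert map_snps_to_genes(snps, [GeneModel("G", "1", 150, 200)], tiny_panel) == []
        (a,) = map_snps_to_genes(snps, [GeneModel("G", "1", 100, 150)], tiny_panel)
        assert a.member_snps == ["snpA"]

    def test_flank_extends_membership(self, tiny_panel):
        snps = [SnpAssociation("snpB", "1", 180, 0.5, 0.3)]
        genes = [GeneModel("G", "1", 200, 300)]
        assert map_snps_to_genes(snps, genes, tiny_panel, flank_bp=0) == []
        (a,) = map_snps_to_genes(snps, genes, tiny_panel, flank_bp=50)
        assert a.member_snps == ["snpB"]


class TestEmpiricalGenePvalue:
    def test_t_zero_gives_p_one(self):
        ld = LdMatrix(["s"], np.eye(1))
        p, n = empirical_gene_pvalue(0.0, ld, (1000,), seed=0)
        assert p == 1.0

    def test_single_snp_matches_chi2_survival(self):
        # oracle: P(chi2_1 >= 3.8415) = 0.05
        ld = LdMatrix(["s"], np.eye(1))
        p, n = empirical_gene_pvalue(3.8415, ld, (10**5,), seed=1)
        assert n == 10**5
        assert p == pytest.approx(0.05, abs=0.005)

    def test_two_independent_snps_match_2df_survival(self):
        # oracle: P(chi2_2 >= T) = exp(-T/2); T = 5.9915 -> 0.05
        ld = LdMatrix(["a", "b"], np.eye(2))
        p, _ = empirical_gene_pvalue(5.9915, ld, (10**5,), seed=2)
        assert p == pytest.approx(0.05, abs=0.005)

    def test_perfect_ld_collapses_to_scaled_1df(self):
        # with all r = 1, T_null ~ m * chi2_1: P(T >= T_obs) = P(chi2_1 >= T_obs/m)
        from scipy.stats import chi2

        m, t_obs = 4, 10.0
        r = np.ones((m, m))
        from pleioscan.gene_test import _regularize

        ld = LdMatrix([f"s{i}" for i in range(m)], _regularize(r))
        p, _ = empirical_gene_pvalue(t_obs, ld, (10**5,), seed=3)
        assert p == pytest.approx(chi2.sf(t_obs / m, 1), abs=0.005)

    def test_reproducible_with_fixed_seed(self):
        ld = LdMatrix(["a", "b"], np.eye(2))
        r1 = empirical_gene_pvalue(4.0, ld, (1000, 10000), seed=42)
        r2 = empirical_gene_pvalue(4.0, ld, (1000, 10000), seed=42)
        assert r1 == r2

    def test_adaptive_schedule_escalates_small_p(self):
        ld = LdMatrix(["s"], np.eye(1))
        p, n = empirical_gene_pvalue(80.0, ld, (1000, 10000), seed=0)
        assert n == 10000  # a huge statistic forces the next stage
        assert p == pytest.approx(1.0 / 10001)  # floor 1/(N+1)

    def test_cheap_gene_stops_at_first_stage(self):
        ld = LdMatrix(["s"], np.eye(1))
        _, n = empirical_gene_pvalue(1.0, ld, (1000, 10000), seed=0)
        assert n == 1000


class TestRunScan:
    def test_single_snp_gene_recovers_snp_pvalue(self, tiny_panel):
        # with one SNP the gene p equals the SNP p (1-df chi-square equivalence)
        snps = [SnpAssociation("snpA", "1", 150, 0.01, 0.3)]
        genes = [GeneModel("G", "1", 100, 160)]
        cfg = AnalysisConfig(mc_schedule=(10**5,), rng_seed=5)
        (res,) = run_scan(snps, genes, tiny_panel, cfg)
        assert res.p_gene == pytest.approx(0.01, abs=0.003)
        assert res.top_snp == "snpA" and res.n_snps == 1

    def test_gene_without_assignment_absent(self, tiny_panel):
        snps = [SnpAssociation("snpA", "1", 150, 0.01, 0.3)]
        genes = [GeneModel("G", "1", 100, 160), GeneModel("H", "2", 1, 100)]
        results = run_scan(snps, genes, tiny_panel, AnalysisConfig(mc_schedule=(1000,)))
        assert [r.gene for r in results] == ["G"]

    def test_top_snp_tie_broken_lexicographically(self, tiny_panel):
        snps = [
            SnpAssociation("snpB", "1", 180, 0.2, 0.3),
            SnpAssociation("snpA", "1", 150, 0.2, 0.3),
        ]
        genes = [GeneModel("G", "1", 100, 200)]
        (res,) = run_scan(snps, genes, tiny_panel, AnalysisConfig(mc_schedule=(1000,)))
        assert res.top_snp == "snpA"
        assert res.top_snp_p == pytest.approx(0.2)

    def test_results_sorted_by_p_then_symbol(self, demo_spec):
        from pleioscan import simulate_reference_panel, simulate_summary_pair

        panel = simulate_reference_panel(demo_spec)
        snps_a, _ = simulate_summary_pair(panel, demo_spec)
        results = run_scan(
            snps_a, demo_spec.genes, panel, AnalysisConfig(mc_schedule=(1000,), rng_seed=2)
        )
        keys = [(r.p_gene, r.gene) for r in results]
        assert keys == sorted(keys)
        assert all(r.p_gene >= 1.0 / 1001 for r in results)
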