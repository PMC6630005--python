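# Methods

## Model and procedure

The pipeline asks whether a gene is associated with two traits at once,
using only per-SNP GWAS summary p-values, a genotype reference panel for
linkage disequilibrium (LD), gene annotation, and case/control expression
matrices. Three stages:

1. **Gene-based association per trait.** Each two-sided SNP p-value is
   transformed to a 1-df chi-square quantile (the z² equivalence) and the
   gene statistic is their sum over the gene's assigned SNPs,
   T = Σⱼ Q_{χ²₁}(1 − pⱼ). Assignment takes members (SNPs with
   start < pos ≤ end against the BED half-open span, zero flank by
   default) plus proxies: same-chromosome non-members with r² > 0.8 to at
   least one member, with r² computed from the panel. Proxies contribute
   to T exactly like members and are counted in `n_snps`. The null
   distribution of T accounts for LD by simulation: z ~ MVN(0, R) with R
   the panel correlation matrix of the assigned SNPs, T₀ = Σ z², and the
   gene p-value is the permutation-style estimator (r+1)/(N+1), which can
   never return 0 and is bounded below by 1/(N+1).

2. **Cross-trait combination.** Genes strictly below p = 0.05 in *both*
   scans (N genes) are combined by Fisher's method,
   x² = −2 Σᵢ ln Pᵢ referred to a chi-square with 2k df (k = 2), and
   flagged when P_combined < 0.05/(2N). Combination is applied only to
   the post-selection shared set, so combined p-values of chance-shared
   genes are *not* uniform — the threshold logic is what controls the
   family-wise error, and the tests check the whole select-then-combine
   chain against a brute-force computation. Fusion-transcript pairs are
   collapsed only through an explicit user-supplied map (coordinate-based
   inference would be guessing); the collapse keeps the smaller combined
   p-value, and distinct-gene counts are reported before and after.

3. **Expression validation.** Welch's unequal-variance t-test (two-sided)
   on log2-scale values per transcript; the smallest-p transcript supplies
   the gene's p-value *and* its log2 fold change (case mean − control
   mean, so "upregulated" is positive). Per dataset the Bonferroni
   denominator n counts candidate genes with at least one transcript
   present; absent candidates are reported as not-present and do not enter
   n. |log2FC| > 1 (2-fold either way) is a separate flag. The
   two-group test had to be chosen here (normalized-array pipelines vary);
   Welch's t is the standard default and is documented so users can
   compare against moderated alternatives.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_nominal` | 0.05 | nominal per-trait significance for the overlap |
| `n_phenotypes` | 2 | the k of Fisher's 2k df and of 0.05/(kN) |
| `r2_proxy_threshold` | 0.8 | LD proxy assignment cutoff (strict >) |
| `flank_bp` | 0 | symmetric flank around the gene span |
| `maf_min` | 0.01 | minor-allele-frequency filter at load time |
| `mc_schedule` | 10³,10⁴,10⁵,10⁶ | adaptive Monte-Carlo stages |
| `rng_seed` | 0 | root seed; per-gene streams derived from it |
| `fold_change_log2_cutoff` | 1.0 | "large fold change" flag (2-fold) |

The Monte-Carlo schedule advances to the next stage while the estimate
satisfies p̂ ≤ 10/N_s, i.e. while fewer than ~10 null exceedances have
been seen; this bounds the relative error of small p-values at bounded
cost, and cheap (large-p) genes stop at the first stage. Per-gene RNG
streams are derived from the root seed and a CRC of the gene symbol, so
results are reproducible gene-by-gene and independent of scan order.

## Numerical choices

- Input p-values of exactly 0 are rejected at the I/O layer (kept honest,
  with a reported count) rather than clamped; inside the transform,
  p-values are clamped at 1e-300 only to keep the chi-square quantile
  finite.
- Panel correlation matrices estimated from few haplotypes are often
  rank-deficient. Eigenvalues are clipped at 1e-8 and the matrix rescaled
  to unit diagonal before factorization, giving a valid MVN covariance
  while leaving well-conditioned matrices untouched. The MVN draw uses the
  symmetric eigenfactorization V·diag(√λ).
- Monomorphic panel SNPs have undefined correlation: they are flagged at
  load, excluded from assignment, and raising an error if requested
  explicitly.
- Ties: the top-SNP of a gene breaks p-value ties lexicographically by
  SNP id; result tables sort by (p, gene symbol). Output floats are
  written with 6 significant digits in scientific notation so reruns
  compare byte-identically.
- Degenerate expression input (both groups zero-variance) returns p = 1
  for equal means and the smallest positive float, with a warning, for
  unequal means.
- Chromosome names are normalized by stripping a leading `chr` before any
  join between summary statistics, annotation and panel.

## Synthetic data: what it emulates and what it does not

The generator produces the three inputs the pipeline consumes, under the
model the gene test assumes:

- **Panel.** 2·n haplotypes per block; each haplotype's latent Gaussian
  follows an AR(1) with parameter rho and alleles arise by thresholding at
  the SNP's allele-frequency quantile (frequencies uniform in
  `maf_range`, default 0.05–0.5). Dosage = sum of two haplotypes.
  Realized allelic correlation is monotone in rho but attenuated relative
  to the latent scale (tetrachoric-style), which is all the proxy rule and
  the null need. Default n = 300 individuals, the order of a continental
  reference panel.
- **Summary statistics.** Drawn directly at the z-score level: per block,
  z ~ MVN(Σλ, Σ) with Σ the panel's (regularized) block correlation and λ
  zero except at planted causal SNPs; p = 2(1 − Φ(|z|)). The two traits
  are independent given their λ's. This is the standard asymptotic
  equivalence to individual-level regression; its value here is that the
  null of the gene test is *exactly* the generating model, so calibration
  tests are sharp. One causal SNP per planted gene, at the block-central
  member, non-centrality 6 by default in the demo spec.
- **Expression.** One transcript per gene; controls ~ Normal(baseline,
  noise_sd = 0.5) on the log2 scale with baselines ~ Normal(8, 1), cases
  shifted by the planted log2FC (default 2 for DE genes).

Not emulated: realistic human demography or coalescent genealogies,
imputation uncertainty, array probe effects, confounding or population
stratification, and between-dataset heterogeneity of expression
platforms. Passing tests therefore demonstrate internal statistical
correctness (calibration, power under the assumed model, threshold
arithmetic), not robustness to those real-data complications.

## Problem sizes used in tests and the acceptance script

Calibration pools 600 null gene tests (30 genes × 20 replicates, 200
individuals, 1000-draw MC stage) for the KS uniformity check at α = 0.01;
the discrete granularity of (r+1)/1001 p-values is an order of magnitude
below the KS critical deviation at that sample size. Planted-gene recovery
uses 50 replicates of a 10-gene study with a (10³, 10⁴) schedule — enough
resolution for the planted gene to rank first by combined p-value while
keeping the full suite in seconds. Closed-form null checks use 10⁵ draws,
within 3 binomial standard errors at p ∈ {0.5, 0.05, 0.005}.

## Known limitations

- Fisher's method ignores effect direction; a gene can combine two
  opposite-direction signals. This matches the intended use (p-value-only
  summary data) but is a known blind spot.
- The gene test cannot distinguish adjacent genes sharing the same LD
  signal; the fusion map handles only declared pairs.
- Rare variants (MAF < 0.01) are filtered at load and outside scope.
- The per-dataset expression screen is per-dataset by design; no
  meta-analysis across expression datasets is attempted.
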