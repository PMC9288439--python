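# Methods

This note records the statistical models behind `postgwas`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer would want
spelled out. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute.

## Effect standardisation and phenotype QC

A per-allele effect B with standard error SE from an N-sample quantitative
GWAS is standardised as β = Z/√(2·MAF·(1−MAF)·(N+Z²)) with Z = B/SE. This is
the per-allele effect in phenotype-SD units: under Hardy–Weinberg the
genotype variance is 2·MAF·(1−MAF), and N+Z² replaces N so the identity
β·√(2·MAF·(1−MAF)) = Z/√(N+Z²) ≈ sample correlation holds exactly. The unit
test verifies the equivalence against regressing a z-scored phenotype on
allele count on simulated genotypes; at small n the gap between HWE and
realised genotype variance dominates, so the check runs at n = 4000.

Phenotype outliers are removed beyond k = 3 median absolute deviations.
**The MAD here carries the 1.4826 normal-consistency constant by default**
(the convention of R's `mad()`): a k = 3 fence then removes ≈ 0.27% of a
normal sample, matching the sub-percent exclusion rates reported for
volumetric phenotypes, whereas the raw-MAD fence (k·MAD ≈ 2.02 SD) removes
≈ 4.3%. `scale=False` gives the literal raw-median variant. When MAD = 0
with non-constant input, every value off the median is removed with a
warning. The rule is defined as a single pass; re-application can remove
more.

## Locus definition

Clumping is greedy in ascending P, ties broken by (chromosome, position,
SNP id) — the tie rule is a package choice, as clumping tools do not
document one. Independent significant SNPs satisfy pairwise r² < 0.6 among
the genome-wide significant set; leads satisfy r² < 0.1 among the
independent set. Candidates require r² ≥ 0.6 with ≥ 1 independent SNP,
P < 10⁻⁵ and MAF > 0.005; every independent SNP is its own candidate
(r² = 1 with itself).

Risk loci merge the candidate spans of independent SNPs by union–find
(transitive closure), uniting two blocks when their independent SNPs share
r² ≥ 0.1 or their positional spans lie within 250 kb. "Within 250 kb" is
read as the gap between spans (0 when they overlap); the alternative
lead-to-lead reading is not implemented. Locus members are candidates plus
independent SNPs only — SNPs inside the span but outside the r² window are
not members. Merged spans on a chromosome never overlap (otherwise their gap
would be ≤ 0 ≤ 250 kb and they would have merged), which the property tests
assert. LD matrices are dense per region; genome-scale inputs should be
processed per LD block, not as one matrix.

## Credible sets, PIP, enrichment

Credible sets sort causal-configuration models by descending posterior and
take the minimal prefix reaching the mass (default 0.95), *including* the
crossing model, then the union of SNPs; total posterior below the mass
returns the full union with a warning. PIP(s) is the summed posterior of
models containing s; Σ_s PIP(s) equals the posterior expected number of
causal SNPs, which a property test checks on random instances.

Fisher's exact P uses the "sum of tables at most as probable" two-sided
convention (scipy's; conventions differ between tools, so this is stated).
The odds ratio is (ad)/(bc), with 0.5 added to every cell — and flagged —
iff some cell is zero. An exhaustive hypergeometric enumeration oracle
confirms exact agreement for table totals ≤ 40. Partitioned-heritability
enrichment is the ratio of a category's h² share to its SNP share; values
below 1 are depletions.

## Temporal gene-property contrast

Preprocessing, in order: drop genes without RPKM > 1 in any raw sample
column; drop missing gene ids; restrict to the supplied brain-gene list;
winsorise RPKM at 50; log₂(x+1); average same-age samples; per-gene mean
across ages as covariate. Winsorisation precedes the log; replicate
averaging follows it; the average-expression covariate is computed after
replicate averaging, consistent with the timepoint matrix. The per-step
removal counts always sum to input − output genes.

The per-timepoint model is OLS of gene Z on [1, timepoint log-expression,
average expression], one-sided upper-tail P (a positive expression–
association relationship). Gene–gene correlation induced by LD between
nearby genes, and technical covariates such as gene length, are *not*
modelled — the generator draws genes independently, where OLS is correct;
on real gene-level output this is an approximation.

The pre/post contrast treats the estimate vector as b̂ ~ MVN(b, SRS) and
tests H₀: μ_pre = μ_post via z = Dᵀb̂/√(DᵀSRSD), D = (1/K_pre, −1/K_post)
coded, two-sided P. Given its assumed covariance the test is exactly
calibrated (unit-tested by simulation from MVN(0, SRS)).

**Known limitation — the R approximation.** R is, per the published
procedure, the raw Pearson correlation of expression timepoints across
genes. But because the regressions condition on average expression, the
actual sampling correlation of the b̂_j is the correlation of the
*avg-residualised* timepoint profiles. The raw R is dominated by the shared
gene-baseline component (τ²), which the balanced contrast cancels, so the
plug-in variance is too small by roughly σ_u²/(τ²+σ_u²) (σ_u² = temporal
deviation variance) and the test is anti-conservative whenever genes differ
in overall expression — which log-normal RPKM data always do. The
reproduction script quantifies this: null rejection ≈ 0.49 at α = 0.05 with
raw R, ≈ 0.05 with `timepoint_correlation(..., partial=True)`, which
residualises on the average-expression covariate before correlating and is
the model-consistent estimator. The default remains the raw correlation to
match the published method; users testing balanced contrasts should prefer
`partial=True`.

## Winner's curse and expected replication

For a SNP selected at two-sided level α (cut-off c = Φ⁻¹(1−α/2) on |Z|),
the conditional likelihood of the observed estimate given selection is
φ((b−β)/σ)/σ divided by Φ(β/σ−c)+Φ(−β/σ−c). The default corrected estimate
is the conditional MLE, maximised over |β| ∈ [0, |b|] (sign restored).
Because the objective can be multimodal, the search brackets the global
optimum on a grid before golden-section refinement (tolerance 10⁻⁶ in
β/σ units); a grid-search oracle test pins the maximiser to 10⁻⁴. Two
alternatives are provided: the conditional-mean correction
(`method="mean"`: b − σ·A′/A with A the selection probability) and a
replication-informed joint MLE (`conditional_likelihood_correct_rep`) that
multiplies the truncated discovery likelihood by the untruncated replication
likelihood — the variant of the conditional-likelihood family that uses both
studies' estimates.

The conditional MLE has a documented pathology: for barely-significant SNPs
whose true effects are genuinely large, it collapses the estimate toward
zero. Consequences measured by this package's simulations at the modelled
design (N_disc = 27,486, N_rep = 3,906, slab variance 3.60×10⁻⁴):

- Among *threshold-selected slab effects only* (no LD), correction
  *increases* recovery error — a dedicated unit test documents this.
- Among *all GWS SNPs of the full spike-and-slab architecture with LD
  blocks* — where most GWS SNPs are proxies whose own causal effect is
  zero — shrinkage wins, and the correction reduces pooled RMSE
  (≈ 0.024 vs 0.027 on the standardised scale over 20 replicates).
- The expected-replication predictor Σ P(sig) evaluated at the corrected
  point estimates is *not* an unbiased predictor of the realised replication
  count under hard selection: the power curve is nonlinear and the MLE
  overshrinks near threshold, so the expectation runs systematically low
  (≈ 110 expected vs ≈ 125 observed per 200 leads in the calibration study;
  the conditional-mean variant errs high, the joint variant low by less).
  The acceptance suite states the stricter calibration claim and is left
  failing rather than loosened; the reproduction script reports the bias
  z-score so the effect is visible.

Expected replication counts are reported on a 37-lead reference scale
(37 × mean per-lead P(sig)) so runs of different simulated lead counts are
comparable. Observed replication requires two-sided P < α and, by default,
sign concordance with discovery (`require_sign_concordance=False` for the
bare count).

## Overlap-aware meta-analysis

Alignment flips Z signs on A1/A2 swaps (with or without strand complement),
drops unalignable variants with a log entry, flags strand-ambiguous (A/T,
C/G) variants and keeps them unless `drop_ambiguous`. Per study, variants
with minor allele count 2·N·MAF < 100 are excluded; a variant enters the
meta when present in ≥ `min_presence` studies. Z is recovered two-sidedly
from P with the sign of the effect.

The combination Z_meta = Σwᵢzᵢ/√(Σwᵢ²+2Σwᵢwⱼρᵢⱼ), wᵢ = √N_eff,i, uses the
cross-study LDSC intercept as ρᵢⱼ — the correlation induced among null Z
statistics by shared subjects. This combination formula is this package's
design (the intercept estimates exactly the needed correlation); equivalence
with any specific external meta-analysis tool is not claimed. It reduces to
unweighted Stouffer at ρ = 0 and equal weights, and to a single study's Z at
full overlap of identical studies; both limits are tested, and a simulation
with 30% shared subjects shows size ≈ 0.05 corrected vs ≈ 0.08 uncorrected.
Implied overlap counts are clipped to [0, min(N₁, N₂)] with a warning, since
noisy intercepts can exceed physical bounds. Reported N_eff_total is
ΣN_eff minus the estimated pairwise overlaps.

## Synthetic data

Summary statistics are simulated directly in Z-space: within an LD block
with signed AR(1) correlation R (ρ = e^(−decay), r² = R² ⊙ R²), marginal
statistics are Z ~ MVN(R√Nβ_true, R) — the standard distribution of marginal
GWAS statistics under LD. β_true is spike-and-slab: causal with probability
π = 4.36×10⁻⁴, effect ~ N(0, 3.60×10⁻⁴) on the standardised scale — the
point-normal architecture estimates for cerebellar volume, so simulated data
are commensurate with the modelled study; sample sizes default to its
27,486/3,906 discovery/replication split, and betas/SEs are back-transformed
through the inverse standardisation with a phenotype SD of 14,231 mm³
(mean 143,580 mm³). Under these defaults E[χ²] = 1 + Nπσ²_β ≈ 1.004 per
independent SNP, which a test checks; real-data χ² inflation is higher
because genome-wide LD tagging is not reproduced at desk scale. Shared
subjects between discovery and replication (for overlap studies) induce
noise correlation N_ov/√(N₁N₂). A tiny individual-level genotype generator
exists only inside the standardisation oracle test.

Gene-level data couple association Z to expression:
Z = e_pre·(mean prenatal log₂ expression) + e_post·(mean postnatal) + noise,
with expression log-normal on the RPKM scale — per-gene baseline
N(2, 1.5²) on the log₂ scale plus AR(1) temporal deviations (ρ = 0.85,
SD 0.6) across 25 BrainSpan-like cerebellar ages (10 prenatal; four ages
duplicated, 29 samples), plus replicate noise (SD 0.15). Dedicated
never-expressed and missing-id genes exercise the preprocessing filters.
What this does *not* emulate: gene–gene LD correlation, gene length effects,
single-donor age stages, or any real expression trajectory — so a passing
contrast test says the arithmetic is right under the stated sampling model,
not that real-data inferences are calibrated (see the R-approximation
limitation above).

Phenotypes are normal draws (defaults 143,580 ± 14,231 mm³) with outliers
injected at median ± magnitude·MAD. All generators are bit-reproducible from
their seed.

## Problem sizes

The simulation studies run at sizes chosen to keep the full suite and the
reproduction script around a minute each on one CPU while leaving
Monte-Carlo error well inside the asserted tolerances: 10,000 null
simulations for the contrast size (binomial SE ≈ 0.002), 500 replicates ×
200 leads for replication calibration, 20 replicates × 200k SNPs for
recovery error, 10,000 variants for meta size, 200 random instances for the
clumping oracle.
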