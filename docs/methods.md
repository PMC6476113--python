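# Methods

## Kinship

The pedigree is validated structurally (unique ids, both-or-neither
parentage, acyclic ancestry, father male / mother female) and ordered by
Kahn's algorithm so parents precede offspring; the iterative tabular
recursion then fills the kinship matrix Φ without recursion-depth limits:
founders get φ(i,i) = ½ and φ = 0 between founders, a non-founder i with
parents f, m gets φ(i,j) = ½[φ(f,j) + φ(m,j)] against every earlier j and
φ(i,i) = ½[1 + φ(f,m)], which accommodates inbreeding. Half-recorded
parentage is rejected rather than patched with a dummy founder, because
silent augmentation changes kinship values; identifiers are compared as
exact strings. Sex is validated for parents but plays no role in the
kinship arithmetic (autosomal model only). A Monte-Carlo gene-dropping
estimator of Φ, sharing no code with the recursion, serves as an
independent oracle in the tests; its elementwise standard errors give the
comparison bounds.

## Univariate polygenic model

The covariance Ω = 2Φ σ_a² + I σ_e² is diagonalized once through the
eigendecomposition of 2Φ. Writing Ω = σ_p² V(h²) with
V = I + h²(2Φ − I), both the fixed effects (by GLS) and σ_p² have closed
forms at any h², so maximization reduces to a one-dimensional search over
h² ∈ [0, 1): a 21-point grid brackets the optimum and bounded refinement
(absolute tolerance 1e−9 on h²) finishes it. This profiled search reaches
the same maximum as a multi-start quasi-Newton over (h², ln σ_p²) but cannot
miss the boundary. Estimation is ML, not REML; h² therefore carries a small
downward bias at modest n, which the tests' tolerance bands absorb.

The standard error of h² comes from the observed information: a central
finite-difference Hessian (step 1e−4) of the β-profiled log-likelihood in
(h², ln σ_p²) coordinates, inverted; it is reported as NaN at the boundary,
where the quadratic approximation fails. The test of h² = 0 is the
likelihood-ratio statistic referred to ½χ²₀ + ½χ²₁, the boundary null for a
non-negative variance component; Λ = 0 maps to p = 0.5. A trait that is an
exact linear function of the covariates drives σ_e² to its floor and is
flagged degenerate rather than reported as a fit.

## Bivariate model

The same eigendecomposition block-diagonalizes the 2n × 2n bivariate
covariance into n independent 2×2 blocks
C_i = d_i G + E, with G and E the genetic and environmental 2×2
covariance components, making each likelihood evaluation O(n). Both traits'
fixed effects are profiled jointly by GLS. The six remaining parameters
(ρ_g, ρ_e, and the log variance components of both traits) are maximized by
L-BFGS-B with ρ_g bounded in [−1, 1] (the boundary is meaningful: complete
pleiotropy) and ρ_e in (−1, 1); three ρ_g starts (0, ±0.5) guard against
local optima, with the environmental-correlation start taken from the
univariate GLS residuals. Traits are standardized internally and components
rescaled on output, so the correlations are exactly scale-free. ρ_g = 0 is
tested by a χ²₁ LRT against the constrained refit (an interior null); if the
estimate sits on |ρ_g| = 1 the ½-mixture is used instead and the SE is
reported as NaN. ρ_p is computed from the fitted components through its
defining identity, so the identity holds to machine precision by
construction; its SE comes from the delta method over the 6-parameter
observed information. Individuals missing either trait are dropped
(complete pairs) — simpler and slightly stricter than reference
implementations that use all partial data.

## Linkage

Each map position contributes Ω = Π̂ σ_q² + 2Φ σ_a² + I σ_e² with
σ_q² ≥ 0. Because Π̂ differs at every position, no factorization can be
shared across loci; instead σ_e² and β are profiled in closed form and the
two variance ratios (σ_q²/σ_e², σ_a²/σ_e²) are optimized by bounded
quasi-Newton over a Cholesky-based likelihood, warm-started from the
neighbouring locus. LOD = (lnL_qtl − lnL_poly)/ln 10, clipped at zero; the
polygenic model is the exact σ_q² = 0 submodel, so LOD ≥ 0 structurally.
Π̂ numerically equal to 2Φ makes σ_q² and σ_a² non-identifiable; the locus
is flagged confounded and its LOD defined as 0.

Scanning a 140 cM chromosome at 1 cM with ~1,000 individuals is dominated
by per-locus Cholesky factorizations, so the default scan mode ("fast")
holds the polygenic ratio at its null-model value — a nested submodel, so
its LOD never exceeds the full one and significance calls are conservative —
and first evaluates the analytic profile score for σ_q² at zero
(O(n²) per locus, using the precomputed null covariance inverse): loci whose
score is non-positive have their boundary optimum at σ_q² = 0 and are
assigned LOD 0 without an iterative fit. Positions within `refine_window`
(default 10 cM) of the fast-scan peak are then re-fitted with the full
two-ratio model, so the reported peak LOD and the 1-LOD interval always come
from full ML. `mode="full"` fits every locus jointly.

Peaks classify as significant at LOD ≥ 3.0 and suggestive at
2.0 ≤ LOD < 3.0 (fixed thresholds; empirical genome-wide thresholds via
null gene-dropping scans are out of scope). The 1-LOD support interval is
the maximal contiguous run of grid positions around the peak with
LOD ≥ peak − 1, clipped at chromosome ends; ties at the peak break to the
lowest cM. Physical bounds are linearly interpolated on the cM→bp map when
present. A peak with LOD ≤ 1 has no defined interval and returns the whole
chromosome with a warning. The polygenic component keeps the pedigree 2Φ at
every locus; genotype-derived empirical kinship is not implemented (a
documented limitation — see below).

## Association

QC mirrors family-study practice: autosomal SNPs only, individuals retained
at per-person call rate ≥ 95% (inclusive), minor-allele orientation and
summaries recomputed after filtering, and only SNPs with ≥ 5 observed
minor-allele copies tested. Each SNP's dosage joins the covariate design;
by default the variance components are re-estimated under both the with-SNP
and no-SNP models (full joint ML, the measured-genotype likelihood
framework), with a faster mode that holds h² at the no-SNP fit behind a
flag. The p-value is the χ²₁ LRT of the dosage coefficient; β is the GLS
coefficient at the ML variance estimates. Missing dosages are handled
complete-case per SNP, with no imputation. Multiple testing across the
region is Bonferroni at α/(SNPs actually tested) — deliberately the only
correction offered. Variance explained is reported as
100 · 2·MAF·(1−MAF)·β² divided by the covariate-adjusted residual variance
of the analyzed trait; the HWE numerator and the residual-variance basis
are both documented choices, since percent-variance bases differ between
software packages.

## Synthetic data generator

The generator emulates a single extended multigenerational pedigree study
of a weakly heritable biomarker. Its defaults are the study conditions and
are not adjusted per analysis:

* **Pedigree**: 45 founder couples, 4 generations, Poisson mean sibship 3.2,
  75% of offspring reproduce, 55% of matings within the cohort (never
  between siblings; remoter consanguinity allowed, as in isolate
  populations) and the rest with immigrant founders. The largest connected
  component is returned: ~950–1,250 members, 20–25% founders.
* **Map**: one 140 cM chromosome with a 1 cM MIBD grid and ~0.95 Mb/cM
  physical scale; 12 SNPs per cM with counted-allele frequencies uniform on
  [0.02, 0.5]; the causal variant sits at 123 cM with founder allele
  frequency 0.35.
* **Meiosis**: Haldane (no interference) — crossover count Poisson with
  mean cM/100, positions uniform. Founder haplotypes carry unique labels,
  so Π̂ on the grid is the exact IBD sharing, not an estimate, and its
  across-locus average converges to 2Φ (a tested identity).
* **Trait**: y = Xβ_cov + a + q + e on a unit-variance standardized scale
  with h² = 0.16 polygenic and a QTL share of 0.15 through the causal
  dosage (a latent Π̂-structured normal effect is available behind a flag);
  scaled to GSP-like units (mean 353.5, SD 92 µmol/L). Covariates: age
  uniform on 18–88 years, 55% female, BMI ~ N(22.3, 3.7²) kg/m², storage
  time uniform on 100–1,500 days, with modest fixed effects (e.g. 0.01 SD
  per year of age, 0.15 SD male–female difference).
* **Bivariate pair**: ρ_g = 0.35, ρ_e = 0.10, h² = 0.30 for both traits.
* **Streams**: one pseudo-random generator per purpose (pedigree, meiosis,
  founder alleles, covariates, trait noise, bivariate pair), each keyed by
  a fixed offset from the master seed, so adding traits never perturbs the
  pedigree. Everything is bit-reproducible given (seed, config).

What the generator does **not** emulate: population-level linkage
disequilibrium (founder alleles are drawn independently per SNP, so LD
exists only through within-pedigree co-segregation), genotyping error and
missingness, sex-specific maps, assay noise models, and household/shared
environment. Passing tests therefore demonstrate correctness of the
estimators under the stated generating model, not robustness to those
real-data features.

## Problem sizes in the test suite

Oracle equivalence runs on pedigrees of n ≤ 10 (dense-likelihood
comparisons at 1e−8) and n ≈ 60–80 (50,000-drop kinship oracle).
Parameter-recovery suites use a fixed ~1,200-member pedigree with 20 trait
replicates; null calibration uses a ~400-member pedigree with 500
replicates; the end-to-end QTL recovery uses 10 seeds of the full default
study. These sizes were chosen to estimate each property with useful
precision while keeping the whole suite near a quarter hour on one CPU.

## Known limitations

* Pedigree kinship is used for the linkage scan's polygenic component;
  chromosome-wide genotype-based empirical kinship (as some reference
  pipelines use) is not implemented, which slightly changes LOD scores on
  real data.
* ML rather than REML; h² and variance components carry O(p/n) downward
  bias.
* Under the fixed generator demography, a locus explaining 15% of trait
  variance at n ≈ 1,000 yields peak LODs with median around 2.8 across
  seeds: power to exceed LOD 3 at a single realization is roughly a coin
  flip, which is intrinsic to variance-component linkage at this
  relative-pair density rather than an implementation property. The 1-LOD
  interval covers the true location, and the causal SNP clears the interval
  Bonferroni threshold, essentially always in the same simulations.
* The bivariate model drops individuals missing either trait; no partial
  -data likelihood.
* No dominance, household, or threshold-trait components; additive SNP
  coding only.
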