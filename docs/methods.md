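# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `admixgwas`. Notation: π is the admixture proportion
(fraction of the genome from ancestral population 1), g ∈ {0,1,2} an allele
dosage, p₀/p₁ a variant's allele frequency in ancestral population 0/1,
d = p₁ − p₀, μ = E[π], V = Var(π).

## Generative model

Each individual draws π ~ Beta with requested mean and standard deviation
(ν = μ(1−μ)/s² − 1, shapes μν and (1−μ)ν; s = 0 is the point mass). At each
variant, each of the two allele copies descends from population 1 with
probability π (so the local-ancestry count a is Binomial(2, π)), and carries
the counted allele with probability p₁ if from population 1, else p₀.
Conditionally on π, variants are independent — there is no background LD;
all LD in a cohort is injected explicitly (below). Two local-ancestry modes
exist: `independent` (per-variant draws; sufficient for every analytic
property, which conditions only on π) and `block` (per-haplotype Poisson
crossover process at `generations` per Morgan on a uniform `cm_per_mb` map,
no interference; adds realism for block-structure questions). Both have
E[a|π] = 2π.

All randomness flows from one integer seed through named substreams
(`_rng.substream(seed, "panel")`, `…, "trait", block, …`), so any stage can
be re-run in isolation and the whole pipeline is bit-reproducible.

## Desk-scale study conditions (defaults, chosen once)

- Genome: 10 chromosomes × 10 Mb, m = 5000 variants (~1 per 20 kb).
- Frequency panel: p₀ ~ U(0.05, 0.95); 85% of variants get a signed
  ancestral difference |d| ~ U(0.2, 0.8) (clipped to [0.01, 0.99]), 15% are
  near-neutral (|d| ≤ 0.05). A desk-scale panel of 5000 variants must carry
  the genome-wide ancestry information that hundreds of thousands of array
  variants carry in a real cohort; enriching for ancestry-informative
  content puts the simulated cohorts in the same operating regime —
  |corr(PC1, π)| ≈ 0.994 at n = 500 — that real admixed cohorts occupy
  (0.993–0.998). The near-neutral minority provides the
  small-frequency-difference stratum for causal-variant selection.
- Admixture: Beta with mean 0.8, sd 0.1 (African-ancestry-proportion-like
  heterogeneity).
- Cohorts: n = 500 for PC/ancestry structure; n = 1000 for feature-flag
  diagnostics and array-style GWAS scenarios; n = 2000 for sequence-style
  collider scenarios. The loading-peak flag threshold (τ = 0.3, below) is
  calibrated for cohort-scale n: at n = 500 the best-aligned bulk noise PC
  already reaches peak |r| ≈ 0.3 over 5000 variants, at n ≥ 1000 noise peaks
  sit near 0.2.

These are the package's standing conditions; tests and the acceptance
script use them unchanged.

## Localized-LD features

An `LdFeatureSpec` ties a diploid latent factor h (population-conditional
allele frequencies `latent_freq0/1`) to one or more genomic regions,
possibly on different chromosomes. Every genotype cell at an in-region
variant is independently replaced by h with probability ρ (`coupling`), so
corr(variant, h) ≈ ρ, pairwise in-region r² ≈ ρ², and ρ = 1 makes exact
copies. Two distinct usages matter:

- **Diagnostics demo** (`sim.demo_multiregion_feature`): one latent shared
  by two 0.4 Mb regions on chromosomes 3 and 7, ρ = 0.9, ancestry-neutral
  latent. An unpruned PCA shows it as one PC with correlation peaks on both
  chromosomes; each region fits inside the default 0.5 Mb pruning window, so
  pruning leaves one weakly informative representative per region and the
  flag disappears. The shared latent is *real* cross-chromosome LD, which is
  exactly what makes it visible to PCA — but for that reason it is not used
  in trait scenarios (a causal variant inside it would genuinely associate
  with the partner chromosome under any adjustment).
- **GWAS scenarios** (`experiment.equal_size_features`): four *independent*
  single-region features on different chromosomes, each containing exactly
  20 consecutive variants (≤ 0.4 Mb), equal coupling, ancestry-differentiated
  latents (0.2/0.8). Equal variant counts make the features' PCA eigenvalues
  near-degenerate, so sample PCs 2–4 are rotations mixing the four factors.
  A mixed PC correlates with several regions at once while its orthogonal
  complement is not in the model — the precise situation in which adjusting
  for it induces collider bias. This is the desk-scale mechanism standing in
  for real cohorts, where one PC loads on multiple high-LD regions.

## Pre-PCA filtering

Order of composition: MAF floor (default 0.01) → high-LD region exclusion →
LD pruning. Region intervals are 1-based and closed at both ends (the
convention in which the bundled coordinates are printed); chromosome labels
are normalized (`chr6` ≡ `6`); BED export converts explicitly to 0-based
half-open. The bundled 18-region list is tied to genome build 38; no
liftover is provided. Pruning is a deterministic greedy forward pass in
position order per chromosome: a candidate is dropped iff its dosage r²
with any already-kept variant on the same chromosome within the physical
window exceeds the threshold (defaults r² = 0.1, 0.5 Mb; the commonly used
r² = 0.2 and windows up to 10 Mb are plain parameters). Keeping the
earlier-position variant on conflict yields a provable post-condition —
every retained same-chromosome pair within the window has r² ≤ threshold —
verified exhaustively in the tests. r² is composite LD on unphased dosages,
not haplotype LD.

## PCA and diagnostics

Standardization: x = (g − 2p̂)/√(2p̂(1−p̂)) with p̂ the sample allele
frequency; monomorphic columns are an error (filter first). PCs come from
the SVD X = UDVᵀ, computed via the n×n eigendecomposition of the genetic
relationship matrix XXᵀ/m when m > n (eigenvalues are therefore on a
variant-count-free scale); score vectors are unit-norm U columns, loadings
the V columns, and the dual routes agree to 1e-6 (tested). Signs are fixed
by making each PC's largest-magnitude score entry positive. The diagnostic
of record is the PC–genotype |correlation| profile; a PC is flagged as a
local-feature PC iff its peak |r| over variants ≥ τ (default 0.3) while
|corr(PC, π)| < ρ_floor (default 0.5). Both thresholds are configurable;
they are operating points, not estimates.

## GWAS engine

Traits follow y = β₁g₁ + β_π π + ε, ε ~ N(0,1) (the residual sd is fixed at
1 by construction; effects are in residual-sd units). Per-variant fits are
OLS of y on [1, g_j, w] with homoskedastic standard errors; the Wald
statistic β̂/se is referred to the standard normal (two-sided). The genome
scan residualizes y and all genotype columns on [1, w] once and finishes
each variant as a simple regression — algebraically identical to
per-variant OLS (Frisch–Waugh–Lovell), verified against statsmodels, and
fast enough for hundreds of replicated scans. Variants collinear with the
covariates are reported with missing statistics rather than dropped, to
keep per-chromosome bookkeeping stable. Spurious associations are counted
at the chromosome level (distinct non-causal chromosomes with ≥ 1 variant
at p < threshold, strict inequality); genomic-control λ is
median(Wald²)/median(χ²₁) with the χ²₁ median taken from scipy
(0.454936…). The artificial-PC covariate is z = w_a·std(g_a) +
w_b·std(g_b) + N(0, σ_z²) with the two variants on distinct chromosomes;
only the dependence structure is contractual, the functional form is this
package's choice, and the theory module models the identical object.

## Expected effect sizes (theory)

Under the generative model the moments of (g₁, g₂, π, z) are closed-form:
E[g] = 2(p₀ + dμ); Var(g) = 2q̄(1−q̄) + 2d²V with q̄ = p₀ + dμ;
Cov(g, π) = 2dV; Cov(g₁, g₂) = 4d₁d₂V; z-moments propagate linearly. Only
(μ, V) of the π law enter — the Beta assumption matters to the simulator,
not the theory. The large-sample E[β̂] for any adjustment is the tested
variant's coefficient in the population least-squares projection of y on
[1, g_test, w], obtained by solving the moment normal equations; this is
exact under the model and is the reference the simulators are tested
against (20 random models, 5000 replicates of n = 2000, agreement within 3
Monte-Carlo standard errors for every strategy at both variants).
Degenerate covariates (zero variance, e.g. π when V = 0) are dropped before
solving — a constant is absorbed by the intercept; a residual singular
moment matrix (e.g. a noiseless z built on one variant, tested at that
variant) raises an explicit error. The `pcs` adjustment is modeled as the
population-limit first PC — an affine transform of π, hence identical
expected coefficients to the π adjustment; finite-sample PC estimation
error is a simulation-module question, not a theory one.

Zero-bias conditions, each verified by instantiation: unadjusted/causal —
V = 0, or β_π = 0, or d₁ = 0 (bias = 2β_π d₁V / Var g₁);
unadjusted/neutral — V = 0, or d₂ = 0, or (β_π = 0 and d₁ = 0); π-adjusted —
always unbiased at both variants, as is the causal variant under [π, z];
[π, z]/neutral — w_a = 0 (z unrelated to the causal variant given π),
w_b = 0, or β₁ = 0. The collider bias is exactly linear in β₁ and grows
with the coupling weights. One qualitative expectation does **not** carry
over to this z construction: ancestral heterogeneity V scales the
*confounding* pathway (the unadjusted-model bias is strictly increasing in
V) but not the pure collider term, whose conditional covariances
Cov(g, z | π) = w·E[Var(g|π)]/sd(g) are flat-to-slightly-decreasing in V. A
covariate that couples to variants through local ancestry, rather than
directly through standardized genotypes, would restore V-monotonicity;
that variant of the construction is not implemented.

## Replicated designs

Genotypes are fixed within a replicate block and trait noise is redrawn per
replicate (matching the fixed-genotypes / simulated-traits design);
multiple blocks re-simulate the cohort so PC sampling variability is also
represented. The array-style design computes PCs per pre-processing regime,
selects causal variants by strata (top-10 |loading| per chromosome per PC,
low-loading below a cutoff, |d| > 0.6, |d| < 0.005 — the low-loading cutoff
is on the |correlation| scale, default 0.02, since V-scale loadings depend
on m), and reports mean spurious-chromosome counts per (stratum, strategy,
β) cell under both aggregation orders (pooled over replicates, and mean of
per-variant means), because strata contain unequal variant counts. The
sequence-style design contrasts [π] with [π, z] at threshold 5×10⁻⁹ and
additionally records whether the partner variant's chromosome specifically
reached significance, plus per-replicate λ.

Desk-scale consequences worth stating plainly: at n = 1000 the unadjusted
model's confounding bias (~0.1 trait units at β₁ = 4) cannot reach the
5×10⁻⁸ Wald boundary, so the unadjusted strategy shows near-zero
*genome-wide* spurious counts at desk scale even though its genomic-control
λ is visibly inflated; the full-cohort-scale expectation that "no
adjustment" produces the most genome-wide hits re-emerges only as n grows.
The contaminated-PC strategy, by contrast, produces collider biases on the
order of β₁ itself and is genome-wide significant at desk scale in
essentially every replicate. Absolute counts are therefore not comparable
to full-scale studies; orderings, calibration and the λ-insensitivity are
the contract.

## What the synthetic data does and does not emulate

Emulated: heterogeneous global ancestry; ancestry-differentiated allele
frequencies; local-ancestry block structure; localized LD features —
single- or multi-region, ancestry-neutral or -informative — that top PCs
capture; the resulting confounding and collider phenomena. Not emulated:
background distance-decaying LD (outside features, variants are independent
given π; pruning of background variants is therefore nearly a no-op,
whereas in real data it removes > 90% of variants); more than two ancestral
populations; phased haplotypes; genotyping error and missingness;
coalescent-realistic frequency spectra; relatedness. Passing tests
demonstrate the mechanisms and the correctness of the estimators under the
stated model — not that any particular real cohort's PC structure looks
this way, which is precisely why the diagnostics (not the defaults) are the
exportable lesson.

## Numerical conventions

Closed region intervals; strict inequality at significance thresholds;
deterministic PC signs; collinear variants as missing values; correlations
of zero-variance variants as missing, never zero; eigenvalue floors at 0;
condition-number guard (1e12) on the theory's moment matrix; all module
randomness seeded through named substreams.
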