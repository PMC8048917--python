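# Methods

This note documents the statistical models implemented in `mrcoloc`, the
numerical and design choices that were genuinely open, what the synthetic
data generator does and does not emulate, and the problem sizes the test
suite runs at.

## Two-sample MR estimators

For a variant *g*, exposure *X* and outcome *Y*, the observed associations
are β_GX (SD units, quantitative exposure) and β_GY (log-odds for disease
outcomes). The single-instrument causal estimate is the Wald ratio
β_XY = β_GY/β_GX.

**Wald SE.** The first-order delta method, se = |se_GY/β_GX|, is the
default: the outcome-variance term dominates whenever the instrument is
strong (|β_GX|/se_GX large), which is the regime instrument selection
enforces. A `second_order=True` option adds the exposure-variance term
β_GY²·se_GX²/β_GX⁴ for weak-instrument sensitivity checks.

**IVW with multiplicative random effects.** Point estimate Σwβ/Σw with
w = 1/se²; the residual scale φ = max(1, Q/(k−1)) multiplies the variance, so
the SE never shrinks below the fixed-effect SE. With the floor active, the
test is mildly conservative for small k (empirical size ≈4% at k = 10, ≈4.5%
at k ≥ 100); the type-I-error suite therefore runs at k = 135 instruments,
the size of a genome-wide mediator instrument set.

**Additive alternative.** A DerSimonian–Laird combiner (`ivw_additive`) is
provided for strongly heterogeneous instrument pairs: when two instruments
give genuinely different effects (e.g. a pleiotropic *trans* variant), the
multiplicative model's CI can be implausibly narrow because the weights are
dominated by the precise instrument. It is supplementary output, never the
headline combiner.

**MR-Egger.** Weighted regression of β_GY on β_GX with free intercept
(weights 1/se_GY²), after re-orienting pairs so β_GX ≥ 0. The residual scale
is floored at 1 exactly as in IVW (k−2 df); p-values switch from normal to
t(k−2) when the floor is not active. The fit itself is delegated to
`statsmodels` WLS; tests check it against explicit normal equations.

**Weighted median.** Ordered ratio estimates are interpolated at normalized
cumulative weight 0.5, with cumulative weights taken at bin midpoints
(S_i − w_i/2)/S_k. The SE is a parametric bootstrap (each ratio re-drawn
from N(β_i, se_i²)), default 1,000 draws, fully seeded; the bootstrap count
of historical analyses is not standardized, so it is a visible parameter.

**95% CIs** use the 1.96 normal quantile throughout, matching how published
CIs back-convert to log-scale SEs.

## Directionality (Steiger) filtering

An instrument is retained only when it explains more variance in the
exposure than in the outcome: z compares atanh√R²_GX and atanh√R²_GY with
variances 1/(n−3). For binary outcomes the observed-scale pseudo-R²
z²/(z² + n_eff), n_eff = 4/(1/n_case + 1/n_control), stands in for R²_GY.
At a 10% population prevalence with 1:1 case-control sampling this tracks
liability-scale R² within ~5% (the attenuation factor [φ(t)/(2K(1−K))]²);
the liability-simulation test allows 25% relative error. Variants lacking
the frequencies needed for the diagnostic are kept but flagged (no silent
exclusion on missing metadata).

## Instrument selection

"Conditionally uncorrelated" variants are selected by greedy LD clumping:
repeatedly keep the smallest-p variant and discard everything with
r² ≥ 0.001 to it. A full conditional-joint (GCTA-style) reanalysis needs
genotype-level reference data and is out of scope; at r² < 0.001 the two
procedures coincide in practice. Ties on p break on larger |z| first, then
variant ID, making the output invariant to input row order. Per-instrument
R² = 2·EAF(1−EAF)β² and F = (R²/K)/((1−R²)/(N−K−1)) are computed with K = 1
(each instrument reported alone, the convention for per-instrument strength
tables). The *cis* window for pQTL classification defaults to 1 Mb around
the gene body (closed interval), the conventional definition.

## Harmonization

The exposure record defines the reference allele pair. Identical pairs are
kept; swapped pairs flip the sign and complement the EAF; strand complements
are attempted only after both direct comparisons fail. Palindromic variants
(A/T, C/G) cannot be strand-resolved from labels, so they are label-aligned
and then retained only when every trait's EAF lies on the same side of 0.5
and at least 0.08 away from it (configurable). Indels are compared literally.
Harmonization is idempotent, logs exactly one action per variant per trait,
and drops are outcomes with reasons, never errors.

## Two-step mediation MR

Step 0 is standard MR of exposure on outcome (per-instrument Wald ratios,
Steiger-filtered, IVW-combined when ≥2 instruments survive). Step 1
instruments the exposure against the mediator. Step 2 instruments the
mediator against the outcome using mediator instruments selected at the
hematology-GWAS threshold 8.31 × 10⁻⁹, with weighted-median and MR-Egger
sensitivity analyses (≥3 instruments) and a per-exposure-instrument rerun.
Mediation is assessed qualitatively — sign(step1)·sign(step2) must equal
sign(step0) — since a quantified proportion mediated would require scale
assumptions (rare-outcome approximation, no exposure–mediator interaction)
the design does not otherwise need; a product-of-coefficients estimate is
emitted as supplementary output only. The family-wise threshold is α/m (0.05/22 = 2 × 10⁻³ at one
significant figure for the 22-trait panel). Disease-class labels
(cardiovascular/autoimmune/autoinflammatory/atopic) are report metadata; no
pooled class-level estimate is computed.

## Multi-trait colocalization

Under a single causal variant per trait per region, the evidence for each
sharing configuration (15 for three traits: null; a; b; c; a.b; …; ab.c; …;
abc) combines per-variant Wakefield log-ABFs, ½log(1−r) + r·z²/2 with
r = W/(V+W). A configuration's likelihood sums over admissible variant
assignments — shared groups take one variant, distinct groups distinct
variants — via Möbius inclusion–exclusion over partitions of the causal
groups, exact for up to six traits, in log space with signed log-sum-exp
(no subsampling approximations). Each causal variant contributes the prior
p_m for driving m traits (defaults 1e-4, 1e-6, 1e-7); the null contributes 1.

Effect-size prior scales default to W = 0.15 (quantitative) and 0.20
(binary, log-odds), the established single-trait colocalization defaults,
overridable per trait. Region eligibility follows the lead-variant-centric
design: 1 Mb window either side of the lead variant, MAF > 1% in every
trait, ≥50 shared variants, and the lead variant present in all traits —
failures surface as explicit ineligibility reasons ("lead variant absent",
"min_variants"), never silent passes.

Configuration labels use dot notation for distinct variants and
concatenation for shared ones (`ab.c` = traits a,b share one variant, c has
its own); groups are ordered by size then alphabetically.

## Synthetic data generator

`simulate_region` draws summary statistics directly:
β̂_std ~ N(R·d, se²_std·R) per trait over block-diagonal LD (constant
within-block correlation r; the emitted LD matrix holds r²), then rescales
to per-allele units by 1/√(2f(1−f)). Quantitative se_std = 1/√n; binary
(log-odds) se_std = 2/√n_eff with n_eff = 4/(1/n_case + 1/n_control), chosen
so the pseudo-R² diagnostic and the sampling model agree. Structural
coefficients propagate direct effects through the mediation DAG:
d_M ← d_M + θ_XM·d_X, d_Y ← d_Y + θ_MY·d_M + θ_XY·d_X.

Defaults are the emulated study conditions: exposure GWAS n = 3,301,
mediator GWAS n = 173,480, and a disease GWAS of 2,816 cases / 13,056
controls, a realistic scale for a JIA case-control GWAS. Allele
frequencies are uniform on (0.05, 0.95), shared across traits; one sixth of
variants are palindromic, so harmonization exercises its drop rules on
realistic input.

What the generator does **not** emulate: realistic human LD maps (blocks
are exchangeable with constant r), between-study frequency differences,
sample overlap between exposure and mediator GWAS, covariate adjustment,
imputation noise, or selection effects in case ascertainment. Passing tests
therefore demonstrate correctness of the estimators under the stated
sampling model, not robustness to those real-data complications.

`simulate_individual_oracle` is the ground-truth cross-check: genotypes from
a latent-Gaussian-copula haplotype-block sampler, phenotypes from the linear
and logistic structural models, summary statistics by explicit per-variant
regression (closed-form OLS; per-variant logistic fits). The copula's
genotype correlation is slightly below the latent r (tetrachoric
attenuation), so the cross-model agreement test runs without LD, where the
two models share identical truth; agreement is assessed as a per-trait
correlation of effect estimates > 0.95 at n = 10,000 over 100 variants.
It is capped at n ≤ 20,000 — it exists as an oracle, not a generator.

## Numerical choices and degenerate inputs

* p-values from z are computed as χ²₁ tail probabilities (precise deep into
  the tail) and clipped to the smallest positive float; the read-time p/z
  consistency check skips rows whose implied p underflows.
* LD matrices are symmetrized by averaging within 1e-8, clipped to [0, 1],
  diagonal forced to 1; larger asymmetry or out-of-range entries are format
  errors.
* Monomorphic variants in the individual-level simulator have no defined SE
  and are excluded with a log entry.
* A weighted-median bootstrap that degenerates (all estimates identical)
  reports a vanishing SE rather than dividing by zero.
* Odds-ratio conversion saturates at infinity instead of overflowing for
  absurd log-odds (which arise for null-instrument Wald ratios).
* Non-positive-definite LD blocks (e.g. constant negative correlation)
  raise a configuration error suggesting jitter.

## Test-suite problem sizes

Simulation-heavy properties run at deliberately desk-scale sizes, chosen
once as package defaults: type-I error of the IVW test at 2,000 replicates
of 135 instruments; parameter recovery (true effect 0.5) over 500 replicate
regions of 20 variants; mediation detection and null coverage over 200
replicate regions of 20 variants; colocalization recovery on a 240-variant
region; brute-force posterior enumeration on 8-variant regions. The full
suite runs in well under five minutes on one CPU.

## Known limitations

* Greedy clumping stands in for conditional-joint instrument selection
  (identical at r² < 0.001 in practice, but not in pathological LD).
* The binary-trait pseudo-R² is an observed-scale approximation; liability-
  scale Steiger filtering would need prevalence input.
* Published per-instrument estimates combined under the multiplicative
  model reproduce published combined ORs only when heterogeneity is modest
  (Q < k−1); strongly heterogeneous pairs (e.g. a cis/trans pair with
  genuinely different mediator effects) are better summarised by the
  additive combiner, and the package emits both.
* Colocalization assumes a single causal variant per trait per region; no
  SuSiE-style multi-signal extension is provided.
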