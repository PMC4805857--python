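# Methods

## Model

Each of J independent SNPs carries a per-allele effect `bx_j` on a
standardised exposure (SD units) and `by_j` on a binary outcome's log-odds,
estimated in non-overlapping GWAS samples with standard errors `se_x_j`,
`se_y_j`. The structural model behind all estimators is

    by_j = θ · bx_j + Σ_m γ_m · bc_{j,m} + α_j + ε_j,

where θ is the causal log-OR per SD of exposure, `bc_{j,m}` are the SNP's
effects on M measured covariate traits with outcome paths γ_m (measured
pleiotropy), α_j is a direct (horizontal) pleiotropic effect, and ε_j is
sampling noise with SD `se_y_j`. Conventional IVW assumes γ = 0 and
α = 0; multivariable MR estimates θ jointly with γ; MR-Egger absorbs a
nonzero mean of α into an intercept and is consistent for θ under InSIDE
(α independent of instrument strength `bx`).

## Estimation choices

- **Weights.** All regressions use `w_j = 1/se_y_j²`. Exposure-side
  uncertainty is ignored in the weights (the standard summary-data
  first-order treatment); `se_x` is kept in the data model and drives the
  parametric resampling scheme.
- **Inference.** IVW and MVMR report fixed-effect SEs straight from the
  weighted normal equations — `(XᵀWX)⁻¹` without residual rescaling — with
  normal p-values, matching the constrained-regression formulation. An
  optional dispersion-scaled IVW SE (truncated at 1) is available via
  `ivw(..., scale_by_dispersion=True)`. Egger uses the usual weighted
  least-squares variance estimate (residual dispersion on J−2 df) with t
  inference for both slope and intercept, the small-J regression
  convention; nothing in the fixed-effect alternative is defensible for an
  intercept test.
- **Egger orientation.** The Egger intercept is not invariant to allele
  orientation, so SNPs are re-oriented to `bx_j ≥ 0` (flipping `by`
  accordingly) before fitting. Estimates are invariant to how input rows
  happened to be oriented.
- **Cochran Q** uses first-order Wald-ratio SEs `se_y_j/|bx_j|` and
  df = J−1, with an upper-tail chi-square p.
- **Degenerate inputs.** Zero exposure betas raise errors for Wald ratios
  and singular-design errors for IVW; collinear MVMR designs raise a
  singularity error naming the offending columns; Egger requires J ≥ 3.

## Harmonisation

Outcome and covariate rows are aligned to the exposure effect allele by
letter matching, with strand-complement matching as a fallback. Palindromic
SNPs (A/T, G/C) are aligned by letter match only and dropped with a warning
when their letters conflict: without allele-frequency data the strand
cannot be resolved, and a conservative drop is preferred to a 50/50 guess.
Covariate rows missing for a SNP are an error by default; an explicit
opt-in imputes beta 0 with SE 10⁶ (weight-exclusion), because silent
zero-imputation with finite weight would bias MVMR.

## Resampling

`bootstrap` recomputes an estimator over B resamples. The default
*parametric* scheme perturbs every beta by normal noise at its reported SE
— a draw from the summary statistics' sampling distributions — and is the
reading we adopt of "resampling the distributions of the summary
statistics"; the *nonparametric* scheme (J SNPs drawn with replacement) is
the alternative reading and is selectable. Empirical CIs are quantiles;
the two-sided sign-based p is clamped below at 2/B. One seeded generator
drives each call with fully vectorised draws, so results are reproducible
and no parallelism is involved.

A caveat worth knowing: because `bx` enters the IVW ratio nonlinearly,
parametric perturbation of `bx` gives the resampled-estimate mean a fixed
attenuation offset of order `Σ se_x²/Σ bx²` (~0.6% of the estimate at the
default regime). The offset does not shrink with B; CIs and p-values are
unaffected at the precision used here.

`leave_k_out_scan` computes the full-data estimate and its normal-theory
CI once, then removes k distinct SNPs uniformly at random per replicate
and reports the fraction of re-estimates falling outside that CI, flagging
above 5%. k = 0 is exactly 0 by construction. Exclusions are without
replacement within a replicate (k distinct SNPs).

## Power

Prospective power uses the Brion non-centrality approximation
`z = |θ| √(N · R² · v)` with `v = cf(1−cf)` for a binary outcome of case
fraction cf (v = 1 for continuous outcomes), and two-sided power
`Φ(z − z_{1−α/2}) + Φ(−z − z_{1−α/2})`. With the published design inputs
(N = 198,598; 65,877 events; R² = 0.042; OR 1.07 per SD; α = 0.05) this
evaluates to 0.829, i.e. the published 83%, which supports adopting the
`cf(1−cf)` variance factor. Retrospective power evaluates the same formula
at the point estimate and its SE, with no bias correction.

Tertile conversion: the top and bottom tertile means of a standard normal
are ±3φ(Φ⁻¹(2/3)), a separation of 6φ(Φ⁻¹(2/3)) = 2.1816 ≈ 2.18 SDs.
The means convention (not medians) reproduces the published factor.

## Synthetic data

The generator emulates a 31-SNP instrument for a standardised exposure:

| parameter | default | rationale |
|---|---|---|
| `j` | 31 | study-scale instrument size |
| `r2` | 0.042 | instrument R² reported for an almost identical SNP set |
| `theta` | 0.17 | log of the ~1.18 per-SD OR magnitude |
| `se_y_scale` | 0.007 | log-odds SE for a ~200k case-control meta-analysis at typical allele frequencies |
| `se_x_scale` | 0.0025 | exposure effects pooled by fixed-effects meta-analysis across publications (~145k individuals), so exposure-side noise is small relative to the spread of instrument strengths; keeps regression dilution second-order, as the first-order estimators assume |
| `sigma_c` | 0.015 | covariate-pleiotropy scale on a 40% random subset of SNPs |

`true_bx` are absolute normals scaled so `E[Σ bx²] = r2` (genotypes
implicitly standardised); per-SNP SEs vary uniformly ±30% around their
scale. α is drawn `N(mu_alpha, sigma_alpha)` independently of `bx`, so
InSIDE holds by construction — Egger's favourable behaviour in the test
suite is therefore the *best case* for Egger, not evidence about
InSIDE-violating data. Covariate paths enter through `gamma`.

Because the covariate-pleiotropy draw has mean zero, the IVW bias induced
by γ ≠ 0 has random sign across datasets and averages out
unconditionally; the documented MVMR-vs-IVW ordering is a *conditional*
property. `generate_replicates` therefore fixes one latent configuration
and redraws only measurement noise, which is how the bias comparison is
tested.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, winner's-curse inflation of discovery betas, allele-frequency
structure (and hence realistic palindromic-SNP ambiguity), sample overlap
between exposure and outcome GWAS, and non-normal exposure distributions.
Passing tests show the estimators are correct under the stated model, not
that these real-data complications are handled.

## Problem sizes

The test suite and acceptance script run desk-scale simulations chosen to
give stable Monte-Carlo checks: 200 random instruments for the
weighted-least-squares oracle comparison, 1000 replicate datasets for IVW
recovery, 800 for the Egger-vs-IVW bias ordering, 2000 null datasets for
test size, 500×2000 for bootstrap coverage, and 10,000–20,000 replicates
for resampling CIs and sensitivity scans (raise via `--reps` to the
100,000 used at full study scale).

## Known limitations

- No weighted-median/mode or likelihood-based estimators; no two-stage
  least squares on individual-level data.
- No LD modelling or proxy-SNP lookup; SNPs are taken as independent.
- The MVMR covariate betas are treated as fixed regressors; their sampling
  noise induces a small attenuation of γ̂ (and, second-order, of θ̂).
- Harmonisation without allele frequencies cannot rescue
  strand-ambiguous palindromic SNPs; they are dropped.
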