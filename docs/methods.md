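# Methods

## Model and design

`mrsuite` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics. For SNP *j*, let γ_j be its per-allele effect on the
exposure (here: male pubertal timing in years) with standard error σ_{Xj},
and Γ_j its effect on an outcome (SD units or log-odds) with standard error
σ_{Yj}, the two estimated in non-overlapping samples. Under the
instrumental-variable assumptions (relevance, independence from confounders,
exclusion restriction), each valid SNP identifies the causal effect
b = Γ_j / γ_j, and the estimators below combine the per-SNP ratios with
different robustness properties when some instruments are invalid
(horizontally pleiotropic).

The package's analysis battery mirrors a fixed study design: (i) MR-PRESSO
outlier removal, with the outlier-corrected random-effects IVW estimate as
the **primary endpoint**; (ii) sensitivity estimators on the corrected SNP
set — MR-Egger, weighted median, weighted mode, MR-RAPS — plus the
uncorrected IVW; (iii) a multivariable IVW adjusting for BMI; and an
alternative overlap-free instrument (voice-break effects re-scored on the
same SNPs, filtered at F > 10). Primary-endpoint p-values are corrected
across outcomes by Benjamini–Hochberg FDR; sensitivity p-values are
reported raw.

## Estimators

**Wald ratio.** β_j = Γ_j/γ_j with first-order standard error σ_{Yj}/|γ_j|.
Second-order terms are omitted: instruments are gated at F > 10 (and the
motivating study's panel has F ≥ 29.9), where they are negligible.

**IVW.** Weighted regression of Γ on γ through the origin with weights
w_j = 1/σ_{Yj}²: b̂ = Σw_jγ_jΓ_j / Σw_jγ_j². The fixed-effect SE is
(Σw_jγ_j²)^{-1/2}; the default *multiplicative random-effects* model
multiplies it by max(1, √(Q/(n−1))), where Q = Σ(β_j − b̂)²/σ_j² is
Cochran's Q over the ratios with first-order weights. The floor at 1 means
the random-effects interval never undercovers relative to the fixed one;
under homogeneity it makes the test slightly conservative (observed type-I
error ≈ 0.03–0.06 at n = 76, within the accepted 0.05 ± 0.02 band). With a
single SNP, IVW degrades exactly to the Wald ratio and no Q is reported.

**MR-Egger.** Weighted regression Γ_j = β₀ + b γ_j with the same weights,
after internally orienting pairs so γ_j ≥ 0 (stored data are not mutated).
The intercept β₀ estimates the mean directional pleiotropic effect; its
Wald test is the directional-pleiotropy test, valid under InSIDE
(instrument strength independent of direct effects). Residual scaling of
both SEs is multiplicative, floored at 1. The regression-dilution
diagnostic I²_GX = max(0, (Q_GX − (n−1))/Q_GX) uses
Q_GX = Σ(γ_j − γ̄_w)²/σ_{Xj}²; values near 1 indicate the NOME assumption
is adequate. With no spread in γ the slope and intercept are not separable
and a degenerate result (I²_GX still reported) is returned.

**Weighted median.** Ratios are ordered; with normalized weights
w_j ∝ 1/σ_j², the estimate is the value at centered cumulative weight 0.5
(linear interpolation between bracketing ratios). Consistent when valid
instruments carry > 50% of the weight.

**Weighted mode.** The argmax of a weighted Gaussian-kernel density of the
ratios on a 512-point grid spanning the ratio range ± 3h, with bandwidth
h = φ·0.9·min(sd, IQR/1.34)·n^{−1/5} and φ = 1 by default. Exact grid ties
break toward the smaller |b| and are flagged multimodal. If all ratios
coincide (zero bandwidth) the common ratio is returned.

**Bootstrap SEs.** Median and mode use a parametric bootstrap (default
1000 replicates, seeded): γ̂*, Γ̂* are redrawn from N(γ̂, σ_X), N(Γ̂, σ_Y)
and the point estimate recomputed; the SE is the standard deviation over
replicates. Analytic SEs for these estimators are approximations of the
same bootstrap; the bootstrap is chosen for transparency and because its
cost is trivial at panel sizes of ≤ 100 SNPs.

**MR-RAPS.** Profile-score estimation with standardized residuals
t_j(b, τ²) = (Γ_j − bγ_j)/√(σ_{Yj}² + b²σ_{Xj}² + τ²), Huber score ψ with
threshold k = 1.345, and an overdispersion component τ² capturing
systematic (balanced) pleiotropy. b solves Σψ(t_j)·∂t_j/∂b = 0; τ² solves
Σ(ψ(t_j)² − E[ψ(Z)²]) = 0 (Z standard normal), floored at 0. The solver
nests a safeguarded Brent root search in b (bracket expanded from the IVW
estimate ± 10 SE) with τ² updates, tolerance 1e-8, and falls back to a
2001-point grid search if bracketing fails; persistent non-convergence
returns a structured not-computable marker. The variance is the sandwich
A⁻¹BA⁻ᵀ of the estimating equations (A by central finite differences,
step 1e-6·max(1,|θ|)); τ² is treated as a free nuisance only when estimated
off its floor.

All Wald tests use the normal reference and 95% intervals b ± 1.96·se, for
consistency across estimators and because the real analyses involve ≥ 36
SNPs, where the normal and t references are practically identical.

## MR-PRESSO

Observed statistic: for each SNP, the leave-one-out IVW slope b_{−j} is
computed and the weighted residual r_j = (Γ_j − b_{−j}γ_j)²/σ_{Yj}²
accumulated into RSS_obs. The null distribution simulates
γ*_j ~ N(γ_j, σ_{Xj}) and Γ*_j ~ N(b_{−j}γ_j, σ_{Yj}) and recomputes the
statistic — including the leave-one-out slopes — on each simulated dataset
(default 10,000 replicates; all replicates are generated as a single
(n_sim × n_snp) array, so the test is vectorized and cheap). Empirical
p-values carry the add-one correction, so the floor is 1/(n_sim+1) and no
p is ever zero. Per-SNP outlier calls compare each observed residual with
its own simulated distribution at the Bonferroni level 0.05/n_snp. The
distortion test compares the relative change of the IVW estimate after
removing the flagged set with the change after removing random sets of the
same size (two-sided empirical p). Composition rule: if the global test is
non-significant (p ≥ 0.05) nothing is removed and the corrected estimate
equals the raw one; removal is one-shot, not iterated. Requires ≥ 4 SNPs.

## Multivariable MR

With BMI effects δ_j harmonized onto the instrument orientation, the joint
model Γ_j = b·γ_j + b_BMI·δ_j is fit by weighted least squares without
intercept (weights 1/σ_{Yj}²), multiplicative residual scaling floored
at 1. The instrument set is the primary exposure's panel with BMI effects
looked up for those SNPs (no union instrument). If the adjustment column is
identically zero the model nests the univariable IVW and that fit is
returned with the adjustment coefficient flagged zero; near-collinear
designs (condition number of the whitened design > 1e8) return a structured
not-computable result. Conditional F-statistics are not computed.

## Harmonization and instrument handling

Instrument selection is greedy by ascending p-value (deterministic
tie-break on chromosome, position, identifier): a SNP below the
genome-wide threshold (5e-8) is accepted iff no accepted SNP on the same
chromosome lies strictly within the 1 Mb window. Pruning is by physical
distance only — no LD reference panel is used or needed.

Harmonization aligns outcome records onto the exposure's effect allele:
equal allele pairs copy through, swapped pairs negate Γ and reflect the
frequency, strand complements are reduced first. Palindromic (A/T, C/G)
SNPs carry no strand information in their labels, so orientation comes
from allele-frequency concordance; under the default `drop_ambiguous`
policy a palindromic SNP is dropped when either study's frequency is
missing or falls in (0.42, 0.58), a conventional ambiguity band
(configurable). `drop_all` and `infer_by_eaf` are available. Instruments
absent from the outcome are dropped and counted, matching the motivating
study's per-outcome panels (65–76 of 76 SNPs available).

Per-SNP instrument strength is F_j = (γ_j/σ_{Xj})². Total variance
explained prefers the Hardy–Weinberg form Σ2p_j(1−p_j)γ_j² (exact for a
variance-standardized exposure) and falls back to ΣF_j/(F_j+N−2) when
frequencies are missing; both are reported. Duplicated marker IDs or
positions in input tables resolve to the record with the smallest p-value
(deterministic; avoids silent multi-allelic ambiguity).

## Synthetic-data generator

The generator emulates the summary-data regime of the motivating study:
n = 76 independent instruments, MAF ~ U(0.05, 0.5), true effects jointly
rescaled so Σ2p_j(1−p_j)γ_j² equals the target R² = 0.022 exactly (both
traits variance-standardized), exposure GWAS N = 205,354, outcome GWAS
N = 300,000 by default (representative of the outcome studies' range of
16,400–1,045,957). Standard errors are the standardized-trait closed forms
σ = 1/√(2Np(1−p)); estimates are drawn from their exact sampling
distributions and p-values are two-sided normal tests.

True effects are generated as half-normal *magnitudes*: the panel is
oriented to the exposure-increasing allele, the usual reporting convention
for MR instrument panels. This matters for the pleiotropy regimes: with
signed γ a constant-mean direct effect α would flip sign in ratio space
(α/γ) and "directional" pleiotropy would degenerate into a balanced
regime, so positive orientation is what makes the directional scenario —
and the classic robustness ordering of median vs IVW under it — well
defined, matching the simulation designs of the weighted-median/mode
literature.

Invalid instruments (fraction `prop_invalid`) receive direct effects
α_j with mean μ_α (directional), SD τ_α (balanced), and correlation
ρ_inside with γ_j via a joint Gaussian construction (single-parameter
control of the InSIDE violation); valid SNPs have α_j = 0. The outcome
signal is Γ_j = b·γ_j + α_j. Calibration experiments use these fixed
regime conventions, chosen once: 30% invalid instruments, τ_α = 0.005,
and μ_α = 0.02 for the directional scenario (roughly 0.7 γ-units of ratio
shift — strong enough that pleiotropy, not sampling noise, is what the
robustness ordering probes).

`simulate_study` draws the genetic architecture and exposure estimates once
and gives each outcome independent pleiotropy and noise, mirroring one
instrument panel tested against a battery of outcome GWAS. A two-exposure
generator (`simulate_mvmr_tables`) drives the multivariable calibration:
effects on the two exposures correlated at ρ = 0.3, adjustment R² = 0.05
at N = 374,756, outcome = b₁γ₁ + b₂γ₂ plus noise.

What the generator does **not** emulate: LD between instruments (the real
panel is distance-pruned; independence is the modeled regime), sample
overlap between exposure and outcome GWAS, binary outcomes on the
liability scale (log-odds outcomes reuse the same arithmetic with
user-supplied SE scale), winner's-curse selection of instruments, and
population stratification. Passing calibrations therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to those additional real-data complications. The per-SNP F
distribution also differs from the real panel's (half-normal effect sizes
give a median F near 30 rather than 43), so F summaries on synthetic data
are diagnostics, not reproductions.

## Pipeline conventions

- The primary endpoint is literally `estimators.ivw` (random-effects) on
  the PRESSO-corrected subset — a single code path.
- The alternative-instrument (voice-break) estimate re-scores the primary
  panel with the alternative study's effects, keeps F > 10, and runs its
  own MR-PRESSO correction before IVW, since the design calls for
  outlier-corrected estimates throughout.
- Inversely coded outcomes (e.g. age at first sexual contact) are handled
  as interpretation metadata on reports; the arithmetic is never altered.
- Any stage that cannot run (too few SNPs, collinearity, non-convergence)
  yields a structured not-computable entry; a study run never aborts on a
  single stage.
- Per-outcome seeds derive deterministically from the study seed, so
  `run_study` is byte-identical across re-runs with the same seed.
- BH-FDR is the textbook step-up: q_(i) = min_{k≥i} p_(k)·m/k, clipped
  at 1, applied to primary endpoints only (default family = the study's
  outcomes; m is configurable).
- Plots (scatter with estimator lines and outlier highlighting, funnel,
  forest, leave-one-out forest) are written as SVG and 300-dpi PNG with
  deterministic names.

## Problem sizes used in tests and the acceptance script

Calibration runs use 500 replicates for type-I error, 200 for bias and
coverage at b = −0.17, 100 each for MR-PRESSO detection (n_sim = 999,
25 SNPs, one outlier shifted by 10 outcome-SEs) and false-positive control,
100 for multivariable recovery of (−0.10, +0.20), 50 seeds for the
median-vs-IVW robustness ordering, and a single 17-outcome null study for
the FDR summary — sizes at which Monte-Carlo error is well inside each
check's tolerance while a full run stays in the tens of seconds.

## Known limitations

- MR-RAPS standard errors rely on the asymptotic sandwich; at very small
  panels (n < 10) the bootstrap-based estimators are more trustworthy.
- The weighted-mode bootstrap SE is honest but large when weak-ratio SNPs
  make the kernel density flat; this reflects the estimator, not a defect.
- No Steiger filtering, bidirectional MR, LD-aware clumping, proxy-SNP
  search, or liability-scale conversion for binary traits.
- The distortion test conditions on the flagged outlier count and inherits
  MR-PRESSO's known conservatism for small outlier sets.
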