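# Methods

## Model

The package estimates the causal effect θ (log-odds of outcome per unit —
here per SD — of exposure) from two-sample GWAS summary statistics. For
each instrument i, the observed exposure effect β̂ₓᵢ ~ N(ξᵢ, σₓᵢ²) and the
observed outcome effect β̂ᵧᵢ ~ N(θξᵢ + αᵢ, σᵧᵢ²), where ξᵢ is the true
instrument effect and αᵢ is any direct (horizontally pleiotropic) effect.
Valid instruments have αᵢ = 0; the estimators differ in how they behave
when some αᵢ ≠ 0.

## Instrument selection and harmonization

- Genome-wide significance filter p < 5×10⁻⁸, strict inequality.
- LD clumping against a caller-supplied r² matrix: greedy scan in
  ascending p (ties by input order), keep a SNP iff r² < 0.01 with every
  SNP already kept. The algorithm, not any reference panel, is in scope:
  deriving r² from genotypes is a data dependency the caller resolves.
- Palindromic (A/T, C/G) SNPs with minor-allele frequency > 0.42 are
  dropped as strand-uninferable (strict inequality; MAF = 0.42 is kept).
  Alignable palindromes are oriented by frequency agreement: comparing
  |eafₓ − eafᵧ| against |eafₓ + eafᵧ − 1|, the SNP is flipped when the
  latter is smaller and dropped (`palindromic_ambiguous_freq`) when the two
  distances are within 0.01 of each other — conservative and auditable.
  Palindromes with no outcome frequency are dropped
  (`palindromic_no_freq`); non-palindromes are aligned by allele identity
  alone, which suffices when unambiguous.
- Every exclusion lands in the instrument set's `dropped` audit list with
  a machine-readable reason.

## Estimators and inference conventions

The numerically consequential conventions, all verified against the
reproduced tables:

- **First-order Delta SEs** (σᵧᵢ/|β̂ₓᵢ|) are the default everywhere; they
  reproduce the published Q values exactly. Second-order SEs are an option
  on `wald_ratio`.
- **Multiplicative random-effects IVW** scales the fixed-effects SE by
  σ = √(Q/(k−1)) with **no lower cap at 1**. This is the single most
  consequential convention: the published iron CI (0.75–0.90) and copper
  CI (1.02–1.02) are only reproducible with an unconstrained residual
  scale (a capped fixed-effects iron CI would be ≈ 0.69–0.98). At k = 1
  the estimator falls back to fixed effects.
- **Inference distributions**: IVW, ML and weighted median use the normal;
  MR-Egger uses t with k−2 df; the MR-PRESSO raw estimate uses t with k−1
  df (this reproduces the published phosphorus raw p = 0.23, where
  normal-based inference would give 0.17).
- **Maximum likelihood** maximizes the joint likelihood over (θ, ξ₁…ξ_k),
  initialized at the fixed-effects IVW solution, by BFGS followed by
  Newton polishing with the analytic block Hessian. Convergence is judged
  by the affine-invariant Newton decrement gᵀH⁻¹g < 10⁻¹² (1 + |NLL|); a
  raw gradient-norm test is meaningless here because near-exact
  instruments (σₓ → 0) make the gradient scale unbounded. The SE comes
  from the observed information via the Schur complement of the ξ block.
- **Weighted median**: ratios sorted ascending; with normalized weights
  w′ᵢ the cumulative midpoints are sᵢ = Σ_{j≤i} w′ⱼ − w′ᵢ/2 and the
  estimate linearly interpolates the ratio at s = 0.5. The SE is a
  parametric bootstrap (default 1000 replicates, mandatory seed):
  β̂ₓ and β̂ᵧ are resampled from their sampling distributions and the
  median re-estimated, weights recomputed from the resampled β̂ₓ.
- **MR-Egger** orients all SNPs to positive exposure effects, then fits
  weighted least squares (weights σᵧ⁻²) with intercept via statsmodels
  WLS; the coefficient covariance carries the unconstrained residual scale
  (may shrink below 1).

## MR-PRESSO

The observed statistic is the leave-one-out weighted residual sum
RSS = Σᵢ wᵢ(β̂ᵧᵢ − θ̂₋ᵢβ̂ₓᵢ)², wᵢ = σᵧᵢ⁻², with θ̂₋ᵢ the IVW slope
excluding SNP i. The null distribution resamples β̂ₓ*ᵢ ~ N(β̂ₓᵢ, σₓᵢ²) and
β̂ᵧ*ᵢ ~ N(θ̂₋ᵢβ̂ₓᵢ, σᵧᵢ²) and recomputes RSS (with re-estimated
leave-one-out slopes) n_sim times; empirical p-values use the (1 + #)/(n+1)
convention, so global_p ≥ 1/(n_sim+1). Per-SNP outlier tests compare each
SNP's residual contribution to its simulated null and flag at Bonferroni
0.05/k. When outliers are flagged, the corrected estimate refits the
reduced set and the distortion test compares the observed estimate shift
against shifts from removing equally many SNPs at random (two-sided).

Operational constants not stated in the reproduced analysis were fixed
once: n_sim defaults to 5000 (stabilizes empirical p to about ±0.006) with
a mandatory seed; the outlier threshold is the reference convention
0.05/k. The method requires k ≥ 4 (leave-one-out slopes need three stable
instruments); two-SNP exposures (zinc, copper) are rejected with an
explicit error, mirroring the study's "sensitivity analyses not possible
below three SNPs" rule. Internally SNPs are canonicalized by rsID before
simulation so that the seeded Monte-Carlo p-values are exactly invariant
to input row order.

## Synthetic data

The generator emulates the summary-statistic abstraction the estimators
consume, not individual-level genotypes: eafᵢ ~ U(0.05, 0.95), true
effects ξᵢ from a configurable magnitude distribution (default
U(0.05, 0.15) per-allele SD units — the typical range of genome-wide
significant micronutrient loci), SEs from the unit-variance approximation
(2·eaf·(1−eaf)·n)^(−1/2), and noise as in the model above. Defaults mirror
the scale of the source studies: n_exp = 50 000 (the largest exposure
GWAS) and n_out = 15 666 (the outcome GWAS of CAD in diabetics). Planted
outliers displace β̂ᵧ by a stated number of first-order ratio SEs.
Independent RNG streams per component (loci, pleiotropy, exposure noise,
outcome noise) make degenerate settings exactly reducible (balanced
pleiotropy with sd = 0 equals no pleiotropy).

What it does not emulate — and hence what passing recovery tests do not
show about real data: LD between instruments (instruments are independent
by construction, as post-clumping analysis assumes), winner's curse in
instrument discovery, sample overlap between the two GWASs, case/control
ascertainment, and non-collapsibility of the odds ratio.

Test and calibration problem sizes (200 replicates at k = 30 for IVW bias,
500 replicates for the Egger-intercept type-I band and the MR-PRESSO
global-test size at n_sim = 1000, the config minimum) are chosen as the
smallest sizes at which the binomial/Monte-Carlo bands are informative.

## Fixture data and known non-reproductions

The packaged fixtures transcribe the published per-SNP table verbatim,
including unicode minus signs and mixed p-value notation (normalized on
read) and the printed F statistics (stored for display only — for selenium
and iron they are inconsistent with (β/σ)² of the printed values; the
source GWASs evidently supplied unrounded effects).

Three published figures are *not* reproducible from the printed table and
are deliberately excluded from the reproduction surface:

- **Selenium OR 1.25 / Q 4.78**: the printed rs6586282 outcome beta of
  −0.046 yields OR ≈ 1.20 and Q ≈ 8.4; both published values are recovered
  exactly if that beta is +0.046 — an apparent sign inconsistency between
  the printed table and the analysis dataset. The printed data are treated
  as canonical; the opt-in `selenium_patched` fixture carries the flipped
  sign and is clearly labelled.
- **Magnesium OR 1.41 (IVW) / 1.34 (MR-PRESSO)**: the printed mg/dL-scale
  instrument effects give OR ≈ 17.7, implying an undocumented per-SD
  rescaling (factor ≈ 0.12) that is nowhere stated; magnesium odds ratios
  are therefore not reproduced (its Q and Egger intercept, which are
  scale-sensitive in the right way, are).
- **Copper p = 3.75×10⁻⁴⁹**: hyper-sensitive to input rounding under the
  df = 1 dispersion (σ ≈ 0.02 from two nearly identical ratios); the OR
  itself (1.02) reproduces.

The published Egger intercept p-values (e.g. iron 0.761) also do not match
t(k−2) inference on the printed inputs (0.597); only the intercept point
values are treated as reproducible.

## Degenerate inputs and numerical choices

- Exactly proportional data give zero residual dispersion; the resulting
  zero SE is handled (p = 0, CI collapses to the point) rather than
  dividing by zero.
- Empirical p-values never reach 0 by construction.
- p-values computed for simulated records are clipped at 10⁻³⁰⁰ to respect
  the 0 < p ≤ 1 record invariant under extreme instrument strength.
- Cochran's Q is computed for k ≥ 2 even though df = 1 is fragile, because
  the reproduced heterogeneity table prints Q for the two-SNP exposures.
- The per-exposure sub-seed is derived from (seed, CRC32 of the exposure
  label), so multi-exposure results do not depend on listing order.

## Limitations

Beyond the synthetic-data caveats above: no proxy-SNP search, no strand
inference from genome builds, no indels or multi-allelic variants, no
I²GX weak-instrument correction for MR-Egger, no MR-RAPS/mode-based/
multivariable estimators, and clumping requires a user-supplied LD matrix.
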