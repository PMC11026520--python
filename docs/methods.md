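# Methods

## Change matrices and deconfounding

The analysis operates on within-subject change scores Δ = v(t₂) − v(t₁)
per region, not on cross-sectional volumes. Nuisance variation is removed
from the *change* columns by ordinary least squares against a design of
intercept, BMI, head size, two motion summaries, optional head-position
(x/y/z) and table-position columns, acquisition-site indicators (one-hot,
reference level dropped), and the age/sex basis age, age², sex, sex×age,
sex×age². Continuous columns are mean-centered; zero-variance columns are
dropped with a warning; a rank-deficient design is a hard error naming the
collinear columns. Residualization is followed by column z-scoring with the
sample (n−1) variance divisor. The order raw → residualized → standardized
is enforced through a state flag: z-scored matrices cannot be residualized,
and the co-decomposition refuses non-standardized inputs. Subjects with any
missing region volume are excluded listwise (the decomposition needs
complete matrices; no imputation is attempted).

## PLSC co-decomposition

PLSC is computed as one SVD of the cross-covariance C = XᵀY/(n−1) (the
PLS-SVD variant), not by iterative deflation: the symmetric
covariance-maximization objective with mutually uncorrelated, ordered
modes is exactly the SVD solution. Canonical vectors have unit norm and are
orthonormal within each side; cov(l_X, l_Y) for a mode equals its singular
value; squared singular values over all min(p, q) modes sum to ‖C‖²_F.
Sign non-identifiability is fixed at fit time by making the
largest-magnitude entry of each amygdala-side vector positive. Under tied
singular values individual vectors are not identified and only subspace
statements are meaningful; tests therefore skip per-vector comparisons
when neighboring singular values differ by less than 1e-6.

Both per-mode diagnostics are reported separately: the Pearson correlation
of the paired score columns and the explained-covariance fraction
s_l²/Σs². They are different quantities and are never conflated.

### Permutation significance

Mode significance uses a row-permutation test: rows of Y are permuted,
the decomposition refitted, and mode l's observed singular value compared
with the permuted singular value at the same rank. The p-value
(1 + #{s_perm ≥ s_obs})/(1 + n_perm) is bounded below by 1/(n_perm+1), so
clearing a strict p < 0.005 gate requires at least 200 permutations; the
pipeline default is 100 (configurable) and retention-oriented runs use 399.

A calibration caveat: permuting *residualized* data is only approximately
exchangeable — OLS residuals are coupled across rows through the fitted
design, a Freedman–Lane-type effect of order d/n for d design columns.
At d ≈ 15 and n = 300 this measurably depresses the uniformity of null
p-values; at the study scale (n ≈ 1400) the distortion is ~1%. The
calibration checks therefore feed the permutation test exchangeable inputs
(z-scored null changes without residualization, which is exact); real
analyses at n ≈ 1400 are effectively unaffected.

## Bootstrap hemisphere contrast

Per bootstrap iteration (default 100), subjects are resampled with
replacement once and the same resample feeds two fits — left subnuclei vs
brain and right subnuclei vs brain — so that the left-minus-right
difference isolates hemisphere effects from sampling noise. The two fits
carry two non-identifiabilities, mode order and sign. Alignment matches
modes on the **brain-side** canonical vectors, the only variable space the
two fits share (the amygdala-side vectors live in different left/right
spaces). Matching is greedy on descending |Pearson r| with each reference
mode matched exactly once; an exhaustive assignment search over all
L!·2^L relabelings is available and verified to agree for L ≤ 4. Flipped
modes have V, U and both score columns negated together.

By default every per-iteration fit is aligned to a fixed reference — the
full-sample left-hemisphere solution — which stabilizes aggregation across
iterations; aligning the right fit of each iteration to its own left fit
(`pairing="iteration"`) is also implemented. Percentile bounds (default
10th/90th, i.e. an 80% interval, width configurable) use linear
interpolation between order statistics; a coefficient is selected when its
interval *strictly* excludes zero, with direction labels following the
left-minus-right convention. Resamples producing a zero-variance column
are redrawn (logged, max 10 retries). No multiplicity correction is
applied across coefficients.

Because a mode's global sign is arbitrary, "left-dominant" for a planted
offset is only defined relative to the fitted mode's sign: recovery checks
resolve it as sign(⟨V_ref, a_left⟩) against the planted loading before
asserting the direction.

### Saturation of standardized loadings

After column z-scoring, a planted loading a_j with mode strength s appears
in the canonical vector through ρ_j = s·a_j/√(s²a_j² + 1), which saturates
for s|a_j| ≳ 2.5. Saturation compresses — and through the unit-norm
constraint can even invert — the left-right contrast of a planted offset.
The synthetic contrast condition therefore uses mode strength 2 at unit
noise (s·max|a_eff| ≈ 1.8, quasi-linear regime). This is a genuine
property of analyzing standardized change scores, worth keeping in mind
when interpreting coefficient differences on real data.

## Phenome-wide screen

Harmonization applies, in order: (1) one-hot expansion of unordered
categoricals into one binary column per level (missingness propagated);
(2) removal of columns with fewer than 500 complete values (strictly fewer
— 500 is kept); (3) deduplication of pairs with pairwise-complete
|r| > 0.99, keeping the first column in input order. The operation is
idempotent and emits a drop log. Complementary one-hot levels of a
two-level expansion correlate −1 and are deduplicated by the absolute-value
rule; they are genuinely redundant.

Screening correlates one latent score column (brain-side L_Y by default,
configurable to L_X or their mean) with every phenotype on
pairwise-complete observations; p-values use the exact t-transform with
n−2 degrees of freedom. Bonferroni uses α/m with m the retained phenotype
count (at the study's m = 977 and α = 0.05 this is the 5.11e-5 threshold);
FDR uses Benjamini–Hochberg step-up at q = 0.05. Phenotypes with fewer
than 3 complete pairs or zero variance are skipped with a warning and do
not count toward m. Manhattan tables emit both FDR lines — the
data-dependent largest rejected p and the nominal q — since either
convention appears in practice. Phenotype values are screened raw; no
covariate adjustment and no rank transform are applied by default.

Mode retention implements the two-gate rule: permutation p below the
configured level (default 0.005) AND at least one FDR-significant
phenotype. An empty retention is legal and logged.

## Age-binned ranking and expression trends

Subnucleus ranking uses the **raw** mm³ change (standardization would
destroy the atrophy/growth sign): per age bin (default six equal-width
bins over the observed first-visit age range, edges configurable), the
median change per subnucleus, ranked ascending from most negative. Ties
break deterministically by label order; empty bins are reported with zero
counts and no ranks. Expression trends compute per-(age, sex) cell medians
with within-cell bootstrap 5th/95th percentile bands (cells under 5
subjects report the median without bands) and one least-squares line per
sex through the (age, cell median) pairs, weighted by cell counts.

## Synthetic cohorts

The generator emulates the study regime: n = 1414 subjects by default,
first-visit ages 48–81, inter-visit interval ~2.3 ± 0.42 years (the
interval column is exposed but, matching the analysis, not used to
time-normalize Δ), 18 + 109 regions, log-normal baseline volumes with
region-specific means (positivity without affecting Δ-based analyses),
and v(t₂) = v(t₁) + Δ with

    Δ_X = Σ_k s_k z_k a_kᵀ + σ ε + confounds,   Δ_Y analogous with b_k.

Latent scores z_k are standard normal and independent across modes
(matching PLSC's uncorrelated-mode construction); loadings are unit-norm
with strictly decreasing strengths s_k for identifiable order. Amygdala
loadings are mirrored across hemispheres by default so the no-asymmetry
configuration is a true hemispheric null; asymmetry is planted as additive
offsets on the left-half loadings only (the effective left loading is then
deliberately not unit-norm — it is the known target). Confounds contaminate
both Δ matrices linearly with coefficient vectors drawn from the config
seed, so removal is verifiable against the retained clean Δ. Phenotypes
couple linearly to chosen latent columns (effect e on unit-variance noise
gives population r = e/√(e²+1)) with independent per-entry missingness.

What the generator does **not** emulate: scanner/site batch structure
beyond a categorical site column, segmentation error, heavy-tailed or
skewed phenotype distributions, informative missingness, attrition, or
spatial correlation among regions beyond the planted low-rank structure.
Passing tests show the estimators recover planted truth under the stated
conditions; they do not certify behavior under real-data pathologies.

## Problem sizes used in checks

End-to-end checks run at the study scale where it matters: loading
recovery at n = 1400, s/σ = 5, 20 seeds; hemisphere-contrast recovery at
n = 1400, strength 2, offsets 0.5, 100 bootstrap iterations, 20 seeds,
with the null variant over 10 seeds; permutation calibration over 200
null replicates (n = 300, 6×10 regions, 99 permutations) plus a planted
check at n = 1400; mode retention over 10 seeds with six fitted modes and
399 permutations; pipeline determinism at n = 400. The demo config uses
n = 400 with 399 permutations and 100 bootstrap iterations.

## Known limitations

* Confound removal is linear OLS on change scores; nonlinear confound
  effects and cross-sectional-volume confounding are out of scope.
* The hemisphere contrast reports no multiplicity control across
  coefficients, mirroring the analysis it implements; at 80% nominal
  coverage a fifth of null coefficients are expected to be selected.
* Greedy mode matching can in principle differ from the optimal assignment
  for large L with highly correlated modes; it is verified against
  exhaustive search for L ≤ 4, the regime used here.
* The phenotype harmonizer implements generic rules (count filter,
  dedup, one-hot); cohort-specific recodings (e.g. gated-question fills)
  are left to a pre-processing hook.
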