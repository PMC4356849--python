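# Methods

## The model

`ptstraj` analyses three-wave posttraumatic-stress (PTS) severity scores with
a latent class growth analysis (LCGA): a K-component finite mixture in which
each class k has a deterministic quadratic mean trajectory

    E[y_it | C_i = k] = b0_k + b1_k t + b2_k t^2,      t = 0, 1, 2,

and the observed score is that curve plus wave-specific Gaussian residual
noise, y_it ~ N(mean, sigma_t^2), independent across waves given class.  The
defining LCGA restriction is that within-class growth-factor variances are
zero — all heterogeneity between subjects is between classes.  With three
waves the quadratic is saturated (three coefficients, three wave means), so
each class is effectively a free mean profile; the polynomial
parameterisation matters for reporting (intercept / linear / quadratic
growth), not for fit.

Subjects may miss waves 2 and/or 3; wave 1 is required.  Missing waves drop
out of the observed-data likelihood (MAR).  Residual variances are
wave-specific and shared across classes by default (`residual_structure=
"wave"`, 3 free variances); a per-class option (`"wave_by_class"`, 3K) is
available.  The shared default is the parsimonious convention for this model
family and is what every experiment reported here uses.

### Estimation

Maximum likelihood by EM.  The E-step computes posterior class
probabilities tau_ik in log space; the M-step updates mixing proportions
(mean responsibility), growth coefficients (responsibility-weighted least
squares with waves weighted by 1/sigma_t^2), and residual variances
(responsibility-weighted mean squared residuals) — a conditional-maximisation
sweep whose log-likelihood monotonicity is asserted on every fit.  Mixtures
of curves are multimodal, so fits use many starts: half k-means partitions of
the wave scores (mean-imputed for clustering only), half random perturbations
of the pooled single-class quadratic fit.  Each start runs a 40-iteration
burn-in; the three best likelihoods are iterated to convergence (relative
log-likelihood change < 1e-6, max 2000 iterations) — the usual
short-run/long-run multistart scheme.  A start is abandoned when a class's
total responsibility collapses (< 1e-6 per subject) or a residual variance
falls below 1e-4 (both thresholds configurable).

Classes are reported in a canonical order — descending fitted trajectory
mean averaged over waves, ties broken by descending intercept — so output is
deterministic given the seed.  Posterior ties in modal assignment go to the
lower canonical index.

### Class enumeration

For each K the comparison table reports BIC = −2LL + p·ln(n), adjusted
BIC = −2LL + p·ln((n+2)/24) (the standard sample-size adjustment; stated
explicitly because "adjusted BIC" is ambiguous in print), normalised
entropy 1 − Σ(−tau·ln tau)/(n·ln K), per-class average posterior
probabilities among modally assigned subjects, and a k-vs-(k−1) test.  The
test implemented is the parametric-bootstrap likelihood-ratio test: simulate
from the fitted (K−1)-class model reusing the observed missingness pattern,
refit both models per replicate (reduced starts), p = (1 + #{boot ≥
observed})/(n_boot + 1), default n_boot = 199.  Much of the applied
trajectory literature reports the Lo–Mendell–Rubin adjusted test in this
role; the bootstrap version is used here because its reference distribution
is simulated rather than approximated, so it is fully specified.  Its
p-values are comparable in role, not numerically, to LMR p-values, and the
output says so.  The enumeration table flags the smallest K whose successor's
test is non-significant, but always emits the full table: class enumeration
in practice also weighs substantive interpretability, which no statistic
automates.

### Three-step covariate regression

Covariate effects on class membership are estimated by the bias-adjusted
three-step method: (1) fit the LCGA without covariates; (2) summarise its
classification quality as the K×K matrix D, D[k,s] = P(modal class s | true
class k) = Σ_i tau_ik·1(modal_i = s)/Σ_i tau_ik; (3) maximise

    Σ_i log Σ_k P(C_i = k | x_i; gamma) · D[k, s_i],

a multinomial logit in the covariates with the modal assignment s_i treated
as an error-prone indicator with known error rates.  Regressing on the modal
class directly attenuates effects whenever classification is imperfect;
fixing D inside the likelihood removes that attenuation (verified by
simulation: at entropy ≈ 0.8 the corrected estimator's bias is a fraction of
the naive estimator's), and the two coincide exactly when D = I.  Standard
errors come from the observed information (numerical Hessian) and ignore the
step-1 sampling variability of D, as the standard procedure does — a known
limitation that slightly understates uncertainty.

Optimisation is BFGS with an analytic gradient on an internally standardised
design (covariates here differ in scale by three orders of magnitude —
ancestry PCs ~0.01 vs age ~15 — and the raw-scale observed information is
numerically singular); estimates and covariance are mapped back to the
original scale exactly.  Results are expanded to every pairwise class
contrast; because contrasts are coefficient differences under one fit, odds
ratios are transitive across referent rotations by construction.

The study-shaped runners use: main-effects model — additive SNP dosage
(0/1/2 copies of the minor allele) + age + gender + two ancestry PCs;
interaction model — adds the abuse score (raw 0–24 scale, uncentered by
default) and dosage×abuse.  Complete-case handling with a logged drop count.
Both nominal (p < 0.05) and Bonferroni flags (p < 0.05/n_SNPs) are retained.

### Descriptives and QC

PCL-C totals are sums of 17 items scored 1–5 (range 17–85); the
probable-PTSD flag defaults to total ≥ 44, with a strict-exceed (> 44)
variant behind a flag — the literature's phrasing ("exceeding") implies
strict, common practice uses ≥; the choice only affects descriptive tables.
Abuse totals are sums of six items scored 0–4.  Cronbach's alpha, Spearman
rank correlation (midranks; dosages are heavily tied) for gene–environment
correlation, Welch t / chi-square comparisons of included vs dropped
subjects with Bonferroni over the variables tested.  Genotype QC applies
call rate > 0.95, MAF > 0.01, and an exact Hardy–Weinberg test (full
enumeration over heterozygote counts given allele counts; a chi-square
variant is provided for cross-checking).  Cross-tabulations report dosage
percentages within each class with counts alongside every percentage;
the abuse stratifier is a median split with exact-median values assigned to
the low stratum (a documented, arbitrary convention).

## The synthetic cohort generator

The generator (`dnhs_like_spec`) emulates a three-wave urban cohort of
trauma-exposed adults.  Defaults:

| quantity | default | note |
|---|---|---|
| n subjects | 473 | analytic-sample scale |
| class proportions | .681/.173/.080/.066 | low/decreasing/increasing/high |
| growth coefficients | (26.60,−0.87,−0.04), (53.53,−33.76,11.73), (37.85,19.24,−5.56), (70.06,−30.69,12.77) | PCL-C units, t = 0,1,2 |
| wave residual SDs | per class per wave, 7.0–13.8 | observed within-class SDs |
| SNP MAFs | 0.12, 0.11 | HWE binomial(2, MAF) |
| abuse score | NB(mean 3.59, SD 3.81) truncated to 0–24 | right-skewed; analytic-sample moments |
| gender/age/PCs | 57.5% female; N(53.35, 15.58²) floored at 18; PCs N(0, 0.05²/0.01²) | |
| retention | 1, 276/473, 217/473 | MCAR, independent per wave; monotone option |

Class membership follows a multinomial logit whose intercepts are solved so
the class probabilities equal the target proportions at covariate means
(exact control at the mean profile; the marginal shares then match the
targets to within Jensen-gap error).  Configurable per-contrast log-odds for
genotype (per minor-allele copy), abuse (per unit), and genotype×abuse enter
this logit.  PTS scores are generated as unclipped Gaussians around the
class curves — the fitted likelihood is Gaussian, and clipping to the 17–85
scale range would bias recovery experiments; a clip flag exists for realism
studies.  CTS item vectors are drawn uniformly among compositions of the
total (exact dynamic-programming sampling), as are PCL item vectors.

What the generator does *not* emulate: informative dropout (the cohort's
real attrition is unlikely to be MCAR), item-level measurement error in the
PCL, linkage disequilibrium between SNPs, and any real population structure
behind the two Gaussian PC covariates.  Recovery results therefore validate
the estimators under the stated model, not robustness to these violations.

## Recovery experiments and what they show

`ptstraj.recovery` regenerates cohorts from the calibrated truth and refits:

- **Trajectory recovery** (25 replicates, n = 473, K = 4, 50 starts):
  modal-class shares, growth coefficients, entropy, mean AvePP.  The
  steeply declining class is identified by its fitted cut-off-crossing
  pattern (elevated at wave 1 only) rather than by the most negative linear
  coefficient — the chronically elevated class is small (~30 subjects) and
  its slope estimate noisy enough to be picked by a min-slope rule in a
  sizeable fraction of replicates.
- **Odds-ratio recovery** (n = 5,000 per replicate, 5 replicates averaged on
  the log scale): a per-copy high-vs-low membership effect and, separately,
  a dosage×abuse interaction are generated, the full pipeline is rerun
  (LCGA → D → corrected regression), and the high-vs-low coefficient is
  recovered.  Five replicates because a single replicate's sampling SE of
  the dosage log-OR (≈0.13; the high class is ~7% of subjects) is of the
  same order as the ±10%-log-scale check applied to it.

A known, deliberate caveat: the generator uses printed *modal* class shares
as mixing proportions and observed within-modal-class SDs as residual SDs.
Under ~42%/54% missingness at waves 2/3, modal assignment under-counts the
small increasing class (subjects observed only at wave 1 cannot be
distinguished from the low class and are absorbed by it), so refitted modal
shares concentrate: the largest class recovers ~70–72% (generated 68.1%) and
the smallest ~4.5% (generated 6.6%).  This happens even when classifying
with the true generating parameters (largest 70.2%, smallest 5.1% over 200
oracle replicates) — it is a property of modal assignment under these
conditions, not an estimator defect; the correctly specified fit at
n = 20,000 recovers every mixing proportion and growth coefficient to well
under one unit.  The recovery experiments report the measured values
unadjusted.

## Numerical and design choices

- EM tolerance 1e-6 relative LL change; burn-in 40 iterations, 3 finalists;
  degenerate-start thresholds as above.  All randomness flows from a single
  integer seed; the pipeline fans the master seed out per stage by hashing
  the stage name, so adding a stage never perturbs earlier streams.
- Bootstrap LRT: n_boot = 199 and 5-start refits by default; the
  implementation accepts n_boot ≥ 19 so that calibration simulations that
  replicate the whole test many times stay affordable.
- Corrected regression: BFGS gtol scaled with n; convergence additionally
  accepted when the max gradient component is ≤ 1e-3·n; separation and rank
  deficiency raise diagnostic errors naming the offending columns.
- Problem sizes in the shipped experiments (25 replicates at n = 473; 5 at
  n = 5,000; 200-replicate calibration designs at n = 120–600) were chosen
  to keep the full validation suite in the tens of minutes on one core
  while leaving Monte-Carlo error well inside each check's tolerance.

## Limitations

Single-SNP models only (no LD, no haplotypes); no survey weights; no
one-step joint mixture-with-covariates estimation (the three-step layout is
the point); step-1 uncertainty in D ignored in SEs; MCAR dropout only in the
generator; the LMR test is represented functionally, not numerically, by the
bootstrap LRT.
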