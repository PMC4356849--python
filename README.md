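# ptstraj

Trajectory-based gene-by-environment analysis of posttraumatic stress (PTS).

Longitudinal cohorts show heterogeneous symptom courses after trauma: most
people stay low, some recover, some worsen, a few stay chronically elevated.
`ptstraj` implements the standard analysis pipeline for asking whether a
candidate SNP, an early-life stressor, and their interaction predict which
course a person follows:

1. **Latent class growth analysis (LCGA).** Three-wave PTS severity scores
   (PCL-C scale, 17–85) are modelled as a K-component mixture of quadratic
   mean trajectories, y_it ~ N(b0_k + b1_k·t + b2_k·t², σ_t²), with
   within-class growth variances fixed at zero. Fitting is multi-start EM
   with per-subject handling of missing waves (MAR).
2. **Class enumeration.** BIC, sample-size-adjusted BIC, classification
   entropy, per-class average posterior probabilities, and a parametric
   bootstrap likelihood-ratio test of k vs k−1 classes.
3. **Bias-adjusted three-step regression.** Class membership is regressed on
   SNP dosage (0/1/2 minor-allele copies), childhood physical abuse (0–24
   sum score), dosage×abuse, and covariates (age, gender, two ancestry PCs)
   by maximising Σ_i log Σ_k P(C=k|x_i; γ)·D[k, s_i], where s_i is the modal
   class and D[k,s] = P(modal s | true k) is estimated from the posteriors.
   This corrects the attenuation that plain regression on modal classes
   suffers when classification is imperfect, and reduces to ordinary
   multinomial logistic regression when classification is exact. All
   referent rotations, Wald CIs, and nominal/Bonferroni flags are reported.
4. **Descriptives.** Scale scoring with the probable-PTSD cut-off (44),
   Cronbach's alpha, Spearman gene–environment correlation, genotype QC
   (call rate, MAF, exact Hardy–Weinberg test), and class-by-genotype
   cross-tabulations with a median-split abuse stratifier.

The raw cohort this design comes from is not publicly deposited, so the
package ships a calibrated synthetic-cohort generator reproducing its
statistical structure (four trajectory classes, realistic wave attrition,
HWE genotypes at MAF ≈ 0.11, right-skewed abuse scores, configurable
genotype/abuse/interaction effects on class membership). Every stage is
validated by parameter recovery against the generator's known truth; see
`docs/methods.md` for the model details and the generator's defaults.

## Worked example

```python
import numpy as np
import ptstraj as pt

# a 473-subject cohort with a per-copy OR of 3.64 for membership in the
# chronically elevated ("high") class relative to the low class
spec = pt.dnhs_like_spec(
    seed=7,
    effect_spec=pt.EffectSpec(genotype=(0.0, 0.0, 0.0, np.log(3.64)),
                              snp_index=1),
)
ds = pt.simulate_cohort(spec)

fit = pt.fit_lcga(ds, K=4, n_starts=50, seed=8)
print(pt.label_trajectories(fit))   # ['high', 'increasing', 'decreasing', 'low']
print(fit.params.pi.round(3))       # [0.089 0.063 0.175 0.673]
print(round(pt.entropy_stat(fit.posteriors), 3))  # 0.887

res = pt.run_main_effects_model(ds, fit, "snp2",
                                class_names=pt.label_trajectories(fit))
tab = res.table()
print(tab[(tab.contrast == "high_vs_low") & (tab.predictor == "dosage")]
      [["or", "or_ci_low", "or_ci_high", "p"]])
#          or  or_ci_low  or_ci_high         p
#    4.402707   2.257769    8.585389  0.000014
```

Reading this: the fitted mixture finds the four planted trajectory shapes
(classes are reported in descending order of their average fitted curve and
named by their position relative to the probable-PTSD cut-off); entropy 0.89
says posteriors are sharp; the corrected regression recovers the planted
per-copy odds ratio (4.4, CI 2.3–8.6, against a generating value of 3.64 at
this sample size) for being in the chronically elevated rather than the
consistently low trajectory.

The same workflow is available from the shell:

```sh
ptstraj run-all --seed 1 --out out/            # simulate + full pipeline
ptstraj select --k-min 2 --k-max 6 --out out/  # class enumeration only
```

`run-all` writes the class-enumeration table, trajectory summary, per-subject
posterior export, regression tables (all contrasts, both models), QC and
descriptive reports, cross-tabulations, a trajectory figure, and a manifest
with per-stage seeds and a config hash; rerunning with the same seed
reproduces every table bit for bit.

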