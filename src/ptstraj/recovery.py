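"""Parameter-recovery experiments against the calibrated generating truth.

Because the original cohort is not deposited, the pipeline is validated by
simulation: cohorts are generated from the calibrated four-class model
(:func:`ptstraj.simulate.dnhs_like_spec`) and refit, and the recovered
quantities — modal class shares, growth coefficients, classification
entropy and average posterior probabilities, and regression odds ratios —
are compared with the values that generated them.  These experiments are
what the test suite and the reproduction script drive.
"""

from __future__ import annotations

import numpy as np

from .lcga import fit_lcga, label_trajectories
from .selection import average_posterior_probabilities, entropy_stat
from .simulate import EffectSpec, dnhs_like_spec, simulate_cohort
from .three_step import run_interaction_model, run_main_effects_model

__all__ = [
    "trajectory_recovery",
    "main_effect_recovery",
    "interaction_recovery",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def trajectory_recovery(
    n_reps: int = 25,
    n_subjects: int = 473,
    n_starts: int = 50,
    seed: int = 0,
    residual_structure: str = "wave",
) -> dict:
    """Simulate study-scale cohorts from the four-class truth and refit.

    For each replicate the 4-class LCGA is fit with ``n_starts`` starts and
    the replicate contributes: the modal share of its largest and smallest
    fitted classes, the linear coefficient of the steeply declining class,
    the quadratic coefficient of the chronically elevated class (highest
    average fitted trajectory, canonical class 1), the entropy, and the
    across-class mean AvePP.  The declining class is identified by its
    fitted pattern relative to the probable-PTSD cut-off (elevated at wave
    1, below afterwards) rather than by the most negative linear term: the
    chronically elevated class is small, so its coefficient estimates are
    noisy and would otherwise be picked in a fraction of replicates.
    Returns per-replicate arrays plus their means.
    """
    seeds = _child_seeds(seed, 2 * n_reps)
    largest, smallest, slopes, quads, entropies, avepps = ([] for _ in range(6))
    for r in range(n_reps):
        spec = dnhs_like_spec(n_subjects=n_subjects, seed=int(seeds[2 * r]))
        ds = simulate_cohort(spec)
        fit = fit_lcga(ds, K=4, n_starts=n_starts, seed=int(seeds[2 * r + 1]),
                       residual_structure=residual_structure)
        shares = 100.0 * np.bincount(fit.modal_class, minlength=4) / fit.n
        largest.append(shares.max())
        smallest.append(shares.min())
        labels = label_trajectories(fit)
        k_dec = (labels.index("decreasing") if "decreasing" in labels
                 else int(np.argmin(fit.params.beta[:, 1])))
        slopes.append(fit.params.beta[k_dec, 1])
        quads.append(fit.params.beta[0, 2])  # canonical class 1 = highest mean
        entropies.append(entropy_stat(fit.posteriors))
        _, summ = average_posterior_probabilities(fit.posteriors, fit.modal_class)
        avepps.append(summ["mean"])
    out = {
        "largest_share": np.asarray(largest),
        "smallest_share": np.asarray(smallest),
        "steepest_decline_slope": np.asarray(slopes),
        "elevated_class_quadratic": np.asarray(quads),
        "entropy": np.asarray(entropies),
        "avepp": np.asarray(avepps),
    }
    out.update({f"mean_{k}": float(v.mean()) for k, v in list(out.items())})
    out["n_reps"] = n_reps
    out["n_subjects"] = n_subjects
    return out


def _gxe_spec(n_subjects, seed, genotype_or=1.0, interaction_or=1.0):
    K = 4
    g = [0.0] * K
    i = [0.0] * K
    g[3] = float(np.log(genotype_or))  # high class (last in generator order)
    i[3] = float(np.log(interaction_or))
    return dnhs_like_spec(
        n_subjects=n_subjects,
        seed=seed,
        snp_mafs=(0.11,),
        effect_spec=EffectSpec(genotype=tuple(g), interaction=tuple(i), snp_index=0),
    )


def main_effect_recovery(
    seed: int = 0,
    n_subjects: int = 5000,
    genotype_or: float = 3.64,
    n_reps: int = 5,
    n_starts: int = 20,
) -> dict:
    """Generate cohorts with a per-copy genotype effect on the high-vs-low
    contrast, run the full three-step pipeline, and recover the odds ratio.

    The recovered value is the mean of the estimated high-vs-low dosage
    log-odds over ``n_reps`` replicates, exponentiated (averaging on the log
    scale because the estimator is approximately normal there).
    """
    seeds = _child_seeds(seed, 2 * n_reps)
    log_ors = []
    for r in range(n_reps):
        spec = _gxe_spec(n_subjects, int(seeds[2 * r]), genotype_or=genotype_or)
        ds = simulate_cohort(spec)
        fit = fit_lcga(ds, K=4, n_starts=n_starts, seed=int(seeds[2 * r + 1]))
        res = run_main_effects_model(ds, fit, 0)
        # canonical order: class 1 = highest trajectory, class K = lowest
        row = res.contrast(0, fit.K - 1)
        coef = float(row.loc[row.predictor == "dosage", "coef"].iloc[0])
        log_ors.append(coef)
    log_ors = np.asarray(log_ors)
    return {
        "log_or": log_ors,
        "recovered_or": float(np.exp(log_ors.mean())),
        "generating_or": genotype_or,
        "n_reps": n_reps,
        "n_subjects": n_subjects,
    }


def interaction_recovery(
    seed: int = 0,
    n_subjects: int = 5000,
    genotype_or: float = 3.64,
    interaction_or: float = 1.32,
    n_reps: int = 5,
    n_starts: int = 20,
) -> dict:
    """As :func:`main_effect_recovery`, but the generating model adds a
    dosage-by-abuse interaction on the high-vs-low contrast and the fitted
    model is the hierarchical interaction model; recovers the interaction
    odds ratio (per abuse-unit per allele copy)."""
    seeds = _child_seeds(seed, 2 * n_reps)
    log_ors = []
    for r in range(n_reps):
        spec = _gxe_spec(n_subjects, int(seeds[2 * r]),
                         genotype_or=genotype_or, interaction_or=interaction_or)
        ds = simulate_cohort(spec)
        fit = fit_lcga(ds, K=4, n_starts=n_starts, seed=int(seeds[2 * r + 1]))
        res = run_interaction_model(ds, fit, 0)
        row = res.contrast(0, fit.K - 1)
        coef = float(row.loc[row.predictor == "dosage_x_abuse", "coef"].iloc[0])
        log_ors.append(coef)
    log_ors = np.asarray(log_ors)
    return {
        "log_or": log_ors,
        "recovered_or": float(np.exp(log_ors.mean())),
        "generating_or": interaction_or,
        "n_reps": n_reps,
        "n_subjects": n_subjects,
    }
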