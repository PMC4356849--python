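"""Synthetic longitudinal PTS cohorts.

Generates complete cohorts with the statistical structure the trajectory
analysis assumes: a small number of latent trajectory classes with quadratic
mean curves over three survey waves, biallelic SNP genotypes in
Hardy-Weinberg equilibrium, a right-skewed childhood physical-abuse score,
demographic covariates, and class membership driven by a multinomial logit
in genotype, abuse, and their interaction.  Every stage of the downstream
pipeline (mixture fitting, class enumeration, bias-adjusted covariate
regression) can therefore be exercised by parameter recovery without any
external data.

The calibrated default (:func:`dnhs_like_spec`) mimics a three-wave urban
cohort of trauma-exposed adults: four trajectory classes (low / decreasing /
increasing / high relative to the probable-PTSD cut-off), PCL-C-scale scores,
a 0-24 abuse score with mean ~3.6 and SD ~3.8, SNPs at minor allele
frequencies ~0.11-0.12, and monotone-ish attrition from 473 to 276 to 217
observed scores per wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dataset import LongitudinalDataset, N_WAVES, WAVE_TIMES
from .errors import SpecValidationError

__all__ = [
    "AbuseDistribution",
    "CovariateParams",
    "EffectSpec",
    "DropoutSpec",
    "SimulationSpec",
    "dnhs_like_spec",
    "simulate_cohort",
    "simulate_pcl_items",
    "simulate_cts_items",
]

PCL_N_ITEMS = 17
CTS_N_ITEMS = 6


# ---------------------------------------------------------------------------
# spec dataclasses


@dataclass(frozen=True)
class AbuseDistribution:
    """Discrete right-skewed childhood physical-abuse score on 0..max_score.

    Modelled as a negative binomial with the given mean and SD, truncated to
    the scale range and renormalised.  A sum of six rare-event items is
    overdispersed relative to Poisson, which the NB captures; requires
    sd**2 > mean.
    """

    mean: float = 3.59
    sd: float = 3.81
    max_score: int = 24

    def pmf(self) -> np.ndarray:
        var = self.sd**2
        if var <= self.mean:
            raise SpecValidationError(
                "abuse_distribution", "sd^2 must exceed mean for a negative binomial"
            )
        r = self.mean**2 / (var - self.mean)
        p = r / (r + self.mean)
        support = np.arange(self.max_score + 1)
        pmf = stats.nbinom.pmf(support, r, p)
        return pmf / pmf.sum()

    def truncated_mean(self) -> float:
        pmf = self.pmf()
        return float(pmf @ np.arange(self.max_score + 1))


@dataclass(frozen=True)
class CovariateParams:
    """Demographic covariates: gender, age, and two ancestry PCs."""

    female_prop: float = 0.575
    age_mean: float = 53.35
    age_sd: float = 15.58
    age_floor: float = 18.0
    pc_sds: tuple[float, float] = (0.05, 0.01)


@dataclass(frozen=True)
class EffectSpec:
    """Per-class log-odds of membership relative to the first listed class.

    ``genotype`` is the additive per-minor-allele-copy effect of the SNP at
    ``snp_index``; ``abuse`` the per-unit abuse effect; ``interaction`` the
    per-copy-per-unit genotype-by-abuse effect.  Entry 0 (the referent class)
    must be zero in each vector.
    """

    genotype: tuple[float, ...] = ()
    abuse: tuple[float, ...] = ()
    interaction: tuple[float, ...] = ()
    snp_index: int = 0

    def resolved(self, n_classes: int) -> "EffectSpec":
        def fill(v, name):
            if len(v) == 0:
                return tuple([0.0] * n_classes)
            if len(v) != n_classes:
                raise SpecValidationError(
                    f"effect_spec.{name}", f"expected {n_classes} entries, got {len(v)}"
                )
            if v[0] != 0.0:
                raise SpecValidationError(
                    f"effect_spec.{name}", "referent-class entry (index 0) must be 0"
                )
            return tuple(float(x) for x in v)

        return EffectSpec(
            genotype=fill(self.genotype, "genotype"),
            abuse=fill(self.abuse, "abuse"),
            interaction=fill(self.interaction, "interaction"),
            snp_index=self.snp_index,
        )


@dataclass(frozen=True)
class DropoutSpec:
    """Per-wave retention probabilities.  Wave 1 is always observed.

    Default: missingness independent across waves 2 and 3 (MCAR) with
    retention matching 276/473 and 217/473.  With ``monotone=True`` wave-3
    observation is nested inside wave-2 observation while preserving the
    same marginal retention rates.
    """

    retention: tuple[float, float, float] = (1.0, 276 / 473, 217 / 473)
    monotone: bool = False


@dataclass(frozen=True)
class SimulationSpec:
    """Full generating model for a synthetic cohort."""

    n_subjects: int = 473
    class_proportions: tuple[float, ...] = (0.681, 0.173, 0.080, 0.066)
    #: per class (intercept, linear, quadratic) on the PCL-C score scale,
    #: wave time coded t = 0, 1, 2
    growth_coefficients: tuple[tuple[float, float, float], ...] = (
        (26.60, -0.87, -0.04),
        (53.53, -33.76, 11.73),
        (37.85, 19.24, -5.56),
        (70.06, -30.69, 12.77),
    )
    #: per class per wave residual SD, PCL-C units
    wave_residual_sds: tuple[tuple[float, float, float], ...] = (
        (7.01, 8.54, 7.49),
        (7.81, 8.14, 9.06),
        (8.68, 13.29, 12.28),
        (10.36, 13.79, 8.60),
    )
    class_labels: Optional[tuple[str, ...]] = ("low", "decreasing", "increasing", "high")
    snp_mafs: tuple[float, ...] = (0.12, 0.11)
    snp_names: Optional[tuple[str, ...]] = None
    abuse_distribution: AbuseDistribution = field(default_factory=AbuseDistribution)
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    dropout: DropoutSpec = field(default_factory=DropoutSpec)
    #: clip generated scores to the 17-85 PCL-C range (off by default: the
    #: mixture likelihood is Gaussian and clipping would bias recovery)
    clip_pts: bool = False
    generate_cts_items: bool = True
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    def validate(self) -> None:
        pi = np.asarray(self.class_proportions, dtype=float)
        if self.n_subjects < 1:
            raise SpecValidationError("n_subjects", "must be a positive integer")
        if not np.all(np.isfinite(pi)) or np.any(pi <= 0):
            raise SpecValidationError("class_proportions", "entries must be finite and > 0")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise SpecValidationError("class_proportions", "must sum to 1 within 1e-12")
        K = self.n_classes
        beta = np.asarray(self.growth_coefficients, dtype=float)
        if beta.shape != (K, 3) or not np.all(np.isfinite(beta)):
            raise SpecValidationError(
                "growth_coefficients", f"expected finite array of shape ({K}, 3)"
            )
        sds = np.asarray(self.wave_residual_sds, dtype=float)
        if sds.shape != (K, N_WAVES) or not np.all(np.isfinite(sds)):
            raise SpecValidationError(
                "wave_residual_sds", f"expected finite array of shape ({K}, {N_WAVES})"
            )
        if np.any(sds <= 0):
            raise SpecValidationError("wave_residual_sds", "every residual SD must be > 0")
        if self.class_labels is not None and len(self.class_labels) != K:
            raise SpecValidationError("class_labels", f"expected {K} labels")
        mafs = np.asarray(self.snp_mafs, dtype=float)
        if mafs.size == 0 or not np.all(np.isfinite(mafs)):
            raise SpecValidationError("snp_mafs", "must be a non-empty finite vector")
        if np.any(mafs <= 0.01) or np.any(mafs > 0.5):
            raise SpecValidationError("snp_mafs", "every MAF must lie in (0.01, 0.5]")
        if self.snp_names is not None and len(self.snp_names) != mafs.size:
            raise SpecValidationError("snp_names", "length must match snp_mafs")
        eff = self.effect_spec.resolved(K)
        if not (0 <= eff.snp_index < mafs.size):
            raise SpecValidationError("effect_spec.snp_index", "out of range for snp_mafs")
        ret = np.asarray(self.dropout.retention, dtype=float)
        if ret.shape != (N_WAVES,) or np.any(ret < 0) or np.any(ret > 1):
            raise SpecValidationError(
                "dropout.retention", f"expected {N_WAVES} probabilities in [0, 1]"
            )
        if ret[0] != 1.0:
            raise SpecValidationError("dropout.retention", "wave 1 must always be observed")
        if self.dropout.monotone and ret[2] > ret[1]:
            raise SpecValidationError(
                "dropout.retention", "monotone dropout needs retention[2] <= retention[1]"
            )
        cov = self.covariate_params
        if not 0 <= cov.female_prop <= 1:
            raise SpecValidationError("covariate_params.female_prop", "must be in [0, 1]")
        if cov.age_sd <= 0 or not np.isfinite(cov.age_mean):
            raise SpecValidationError("covariate_params.age", "mean must be finite, sd > 0")
        if any(sd <= 0 for sd in cov.pc_sds):
            raise SpecValidationError("covariate_params.pc_sds", "must be > 0")
        self.abuse_distribution.pmf()  # raises if inconsistent


def dnhs_like_spec(**overrides) -> SimulationSpec:
    """The calibrated default cohort: four trajectory classes on a PCL-C
    scale with urban-cohort demographics and two SNPs at MAF 0.12 / 0.11."""
    spec = SimulationSpec(**overrides)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# item-level scores


def _composition_table(n_items: int, low: int, high: int, total: int) -> np.ndarray:
    """counts[j, s] = number of ways j items in [low, high] sum to s (shifted)."""
    span = high - low
    max_sum = n_items * span
    counts = np.zeros((n_items + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for j in range(1, n_items + 1):
        # convolve previous row with a length-(span+1) boxcar
        prev = counts[j - 1]
        row = np.convolve(prev, np.ones(span + 1))[: max_sum + 1]
        counts[j] = row
    return counts


def _uniform_composition(total: int, n_items: int, low: int, high: int, rng) -> np.ndarray:
    """Draw item scores in [low, high] summing to ``total``, uniformly among
    all valid compositions (sequential sampling from exact DP counts)."""
    if not (n_items * low <= total <= n_items * high):
        raise SpecValidationError(
            "total", f"{total} unreachable with {n_items} items in [{low}, {high}]"
        )
    shifted = total - n_items * low
    counts = _composition_table(n_items, low, high, shifted)
    items = np.empty(n_items, dtype=int)
    remaining = shifted
    span = high - low
    for j in range(n_items, 0, -1):
        vals = np.arange(min(span, remaining) + 1)
        weights = counts[j - 1, remaining - vals]
        weights = weights / weights.sum()
        v = int(rng.choice(vals, p=weights))
        items[n_items - j] = v + low
        remaining -= v
    return items


def simulate_pcl_items(total_target: float, n_items: int = PCL_N_ITEMS, rng=None) -> np.ndarray:
    """Item responses (1-5) for a 17-item PTSD checklist summing to the
    rounded target total, drawn uniformly among valid compositions."""
    if n_items != PCL_N_ITEMS:
        raise SpecValidationError("n_items", f"the checklist has {PCL_N_ITEMS} items")
    total = int(round(total_target))
    if not PCL_N_ITEMS <= total <= 5 * PCL_N_ITEMS:
        raise SpecValidationError("total_target", f"{total} outside [17, 85]")
    rng = np.random.default_rng() if rng is None else rng
    return _uniform_composition(total, n_items, 1, 5, rng)


def simulate_cts_items(total: int, rng=None) -> np.ndarray:
    """Six conflict-tactics items (0-4) summing to ``total`` in [0, 24]."""
    rng = np.random.default_rng() if rng is None else rng
    return _uniform_composition(int(total), CTS_N_ITEMS, 0, 4, rng)


# ---------------------------------------------------------------------------
# cohort generation


def _calibrated_intercepts(spec: SimulationSpec, eff: EffectSpec) -> np.ndarray:
    """Multinomial-logit intercepts solved so that class probabilities equal
    the spec proportions at covariate means (exact marginal control at the
    mean covariate profile, no rejection sampling)."""
    pi = np.asarray(spec.class_proportions, dtype=float)
    d_mean = 2.0 * spec.snp_mafs[eff.snp_index]
    a_mean = spec.abuse_distribution.truncated_mean()
    g = np.asarray(eff.genotype)
    a = np.asarray(eff.abuse)
    ia = np.asarray(eff.interaction)
    shift = g * d_mean + a * a_mean + ia * d_mean * a_mean
    alpha = np.log(pi / pi[0]) - (shift - shift[0])
    return alpha


def simulate_cohort(spec: SimulationSpec) -> LongitudinalDataset:
    """Generate a cohort under ``spec``.

    Sampling order is fixed so a given seed reproduces the dataset exactly:
    covariates, genotypes, abuse, latent class, wave scores, then dropout.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    K = spec.n_classes
    eff = spec.effect_spec.resolved(K)

    cov = spec.covariate_params
    gender = (rng.random(n) < cov.female_prop).astype(float)
    age = np.maximum(rng.normal(cov.age_mean, cov.age_sd, size=n), cov.age_floor)
    pcs = np.column_stack(
        [rng.normal(0.0, sd, size=n) for sd in cov.pc_sds]
    )

    mafs = np.asarray(spec.snp_mafs, dtype=float)
    dosages = rng.binomial(2, mafs[None, :], size=(n, mafs.size)).astype(float)

    pmf = spec.abuse_distribution.pmf()
    support = np.arange(spec.abuse_distribution.max_score + 1)
    cts_total = rng.choice(support, size=n, p=pmf).astype(float)
    if spec.generate_cts_items:
        cts_items = np.vstack(
            [simulate_cts_items(int(t), rng=rng) for t in cts_total]
        ).astype(float)
    else:
        cts_items = None

    alpha = _calibrated_intercepts(spec, eff)
    d = dosages[:, eff.snp_index]
    eta = (
        alpha[None, :]
        + np.outer(d, eff.genotype)
        + np.outer(cts_total, eff.abuse)
        + np.outer(d * cts_total, eff.interaction)
    )
    eta -= eta.max(axis=1, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    true_class = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    beta = np.asarray(spec.growth_coefficients, dtype=float)
    sds = np.asarray(spec.wave_residual_sds, dtype=float)
    t = np.asarray(WAVE_TIMES, dtype=float)
    design = np.column_stack([np.ones_like(t), t, t**2])  # (3 waves, 3 terms)
    means = beta @ design.T  # (K, waves)
    noise = rng.normal(size=(n, N_WAVES))
    pts = means[true_class] + noise * sds[true_class]
    if spec.clip_pts:
        pts = np.clip(pts, 17.0, 85.0)

    ret = np.asarray(spec.dropout.retention, dtype=float)
    if spec.dropout.monotone:
        keep2 = rng.random(n) < ret[1]
        cond3 = ret[2] / ret[1] if ret[1] > 0 else 0.0
        keep3 = keep2 & (rng.random(n) < cond3)
    else:
        keep2 = rng.random(n) < ret[1]
        keep3 = rng.random(n) < ret[2]
    pts[~keep2, 1] = np.nan
    pts[~keep3, 2] = np.nan

    snp_names = spec.snp_names or tuple(f"snp{i + 1}" for i in range(mafs.size))
    return LongitudinalDataset(
        subject_id=np.array([f"S{i + 1:05d}" for i in range(n)]),
        pts=pts,
        cts_items=cts_items,
        cts_total=cts_total,
        dosages=dosages,
        snp_names=tuple(snp_names),
        age=age,
        gender=gender,
        ancestry_pcs=pcs,
        true_class=true_class,
        class_labels=spec.class_labels,
    )
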