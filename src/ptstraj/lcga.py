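"""Latent class growth analysis (LCGA) by multi-start EM.

The model is a K-component finite mixture of quadratic mean trajectories:
conditional on class k, the wave-t score is

    y_it ~ Normal(beta0_k + beta1_k * t + beta2_k * t^2,  sigma_t^2)

independently across observed waves, with wave times t = 0, 1, 2.  The
defining LCGA restriction is that within-class growth-factor variances are
fixed at zero — each class has one deterministic mean curve; all
within-class spread is residual.  Residual variances are wave-specific and
shared across classes by default (``residual_structure="wave"``); a
per-class option exists (``"wave_by_class"``).  Missing waves drop out of
the observed-data likelihood (MAR); wave 1 must be observed for every
subject.

With three waves the quadratic mean curve is saturated: each class's three
wave means are free.  Class separation therefore comes entirely from the
mixture structure, not from smoothness of the curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .dataset import N_WAVES, WAVE_TIMES, LongitudinalDataset
from .errors import ConvergenceError, DegenerateClassError

__all__ = [
    "LCGAParameters",
    "LCGAFit",
    "class_density",
    "e_step",
    "m_step",
    "fit_lcga",
    "assign_modal_class",
    "label_trajectories",
]

_T = np.asarray(WAVE_TIMES)
#: (waves, 3) polynomial design [1, t, t^2]
DESIGN = np.column_stack([np.ones_like(_T), _T, _T**2])

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LCGAParameters:
    """Mixture parameters: weights pi (K,), growth coefficients beta (K, 3)
    as (intercept, linear, quadratic), and residual variances sigma2 —
    shape (waves,) when shared across classes, (K, waves) otherwise."""

    pi: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-10 or np.any(self.pi <= 0):
            raise ValueError("class proportions must be positive and sum to 1")
        if np.any(self.sigma2 <= 0):
            raise ValueError("residual variances must be positive")
        if self.beta.shape != (self.K, 3):
            raise ValueError("beta must have shape (K, 3)")

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def per_class_sigma(self) -> bool:
        return self.sigma2.ndim == 2

    @property
    def param_count(self) -> int:
        """Free parameters: (K-1) weights + 3K growth terms + free variances."""
        n_sigma = self.sigma2.size
        return (self.K - 1) + 3 * self.K + n_sigma

    def class_sigma2(self) -> np.ndarray:
        """Residual variances broadcast to shape (K, waves)."""
        if self.per_class_sigma:
            return self.sigma2
        return np.broadcast_to(self.sigma2, (self.K, N_WAVES))

    def fitted_means(self) -> np.ndarray:
        """(K, waves) model-implied wave means."""
        return self.beta @ DESIGN.T


@dataclass
class LCGAFit:
    """A fitted LCGA model: parameters, maximised log-likelihood, the n-by-K
    posterior matrix, and modal class assignments (canonical class order:
    descending trajectory mean averaged over waves)."""

    params: LCGAParameters
    loglik: float
    posteriors: np.ndarray
    modal_class: np.ndarray
    converged: bool
    n_iter: int
    n_starts_used: int
    best_start_seed: Optional[int] = None

    @property
    def K(self) -> int:
        return self.params.K

    @property
    def n(self) -> int:
        return self.posteriors.shape[0]


# ---------------------------------------------------------------------------
# likelihood pieces


def _log_density_matrix(pts, mask, params: LCGAParameters) -> np.ndarray:
    """(n, K) log of the class-conditional density of each subject's
    observed waves."""
    means = params.fitted_means()  # (K, W)
    sig2 = params.class_sigma2()  # (K, W)
    resid = pts[:, None, :] - means[None, :, :]  # (n, K, W)
    with np.errstate(invalid="ignore"):
        ll_terms = -0.5 * (LOG2PI + np.log(sig2)[None] + resid**2 / sig2[None])
    ll_terms = np.where(mask[:, None, :], ll_terms, 0.0)
    return ll_terms.sum(axis=2)


def class_density(pts_scores, wave_mask, beta_k, sigma2_t) -> float:
    """Likelihood contribution of one subject under one class: the product
    over observed waves of the Normal density at the class mean curve."""
    y = np.asarray(pts_scores, dtype=float)
    m = np.asarray(wave_mask, dtype=bool)
    if not m.any():
        raise ValueError("subject has no observed waves")
    mu = DESIGN @ np.asarray(beta_k, dtype=float)
    s2 = np.broadcast_to(np.asarray(sigma2_t, dtype=float), (N_WAVES,))
    ll = -0.5 * (LOG2PI + np.log(s2[m]) + (y[m] - mu[m]) ** 2 / s2[m])
    return float(np.exp(ll.sum()))


def e_step(pts, mask, params: LCGAParameters):
    """Posterior class probabilities and the observed-data log-likelihood.

    tau_ik is proportional to pi_k times the class density, computed in log
    space to avoid underflow.
    """
    logw = _log_density_matrix(pts, mask, params) + np.log(params.pi)[None, :]
    norm = logsumexp(logw, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = int(np.flatnonzero(~np.isfinite(norm))[0])
        raise FloatingPointError(
            f"zero total likelihood for subject index {bad}; model degenerate"
        )
    tau = np.exp(logw - norm[:, None])
    return tau, float(norm.sum())


def m_step(pts, mask, tau, per_class_sigma: bool = False,
           sigma2: Optional[np.ndarray] = None,
           min_weight: float = 1e-6) -> LCGAParameters:
    """Closed-form maximisation given responsibilities.

    pi is the mean responsibility; beta solves a responsibility-weighted
    least-squares fit of the observed scores on (1, t, t^2) with waves
    weighted inversely to the current residual variances; sigma2 is the
    responsibility-weighted mean squared residual per wave (pooled over
    classes, or per class when configured).
    """
    n, K = tau.shape
    weights = tau.sum(axis=0)
    if np.any(weights < min_weight * n):
        raise DegenerateClassError(
            f"class weight collapsed (min total responsibility {weights.min():.3g})"
        )
    pi = weights / n

    if sigma2 is None:
        inv_s2 = np.ones((K, N_WAVES))
    else:
        s2 = np.asarray(sigma2, dtype=float)
        inv_s2 = 1.0 / (s2 if s2.ndim == 2 else np.broadcast_to(s2, (K, N_WAVES)))

    y0 = np.where(mask, pts, 0.0)
    # per class/wave weighted counts and sums of y
    s0 = tau.T @ mask  # (K, W) total responsibility at each wave
    s1 = tau.T @ y0  # (K, W) responsibility-weighted wave sums
    beta = np.empty((K, 3))
    for k in range(K):
        w = s0[k] * inv_s2[k]
        A = (DESIGN * w[:, None]).T @ DESIGN
        b = DESIGN.T @ (inv_s2[k] * s1[k])
        beta[k] = np.linalg.solve(A, b)

    means = beta @ DESIGN.T  # (K, W)
    # responsibility-weighted squared residuals per wave
    sq = np.empty((K, N_WAVES))
    for k in range(K):
        r2 = np.where(mask, (pts - means[k][None, :]) ** 2, 0.0)
        sq[k] = tau[:, k] @ r2
    if per_class_sigma:
        new_sigma2 = sq / np.maximum(s0, 1e-300)
    else:
        new_sigma2 = sq.sum(axis=0) / mask.sum(axis=0)
    # keep construction valid; a collapsed variance is caught by the EM
    # driver's floor check, which abandons the start
    new_sigma2 = np.maximum(new_sigma2, 1e-300)
    return LCGAParameters(pi=pi, beta=beta, sigma2=new_sigma2)


# ---------------------------------------------------------------------------
# EM driver


def _em(pts, mask, params, tol, max_iter, sigma2_floor, min_weight):
    ll_prev = -np.inf
    ll = -np.inf
    for it in range(1, max_iter + 1):
        tau, ll = e_step(pts, mask, params)
        if ll < ll_prev - 1e-8 * (abs(ll_prev) + 1.0):
            raise ConvergenceError(
                f"log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}"
            )
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            return params, tau, ll, it, True
        ll_prev = ll
        params = m_step(
            pts, mask, tau,
            per_class_sigma=params.per_class_sigma,
            sigma2=params.sigma2,
            min_weight=min_weight,
        )
        if np.any(params.sigma2 < sigma2_floor):
            raise DegenerateClassError(
                f"residual variance fell below floor {sigma2_floor:g}"
            )
    tau, ll = e_step(pts, mask, params)
    return params, tau, ll, max_iter, False


def _pooled_ols(pts, mask):
    """Single-class quadratic fit (weights 1) and per-wave residual variance."""
    s0 = mask.sum(axis=0).astype(float)
    s1 = np.where(mask, pts, 0.0).sum(axis=0)
    A = (DESIGN * s0[:, None]).T @ DESIGN
    beta = np.linalg.solve(A, DESIGN.T @ s1)
    mu = DESIGN @ beta
    resid2 = np.where(mask, (pts - mu[None, :]) ** 2, 0.0).sum(axis=0)
    sigma2 = resid2 / np.maximum(s0, 1.0)
    return beta, np.maximum(sigma2, 1e-8)


def _kmeans_params(pts, mask, K, seed, per_class_sigma):
    from sklearn.cluster import KMeans

    wave_means = np.nansum(np.where(mask, pts, 0.0), axis=0) / mask.sum(axis=0)
    filled = np.where(mask, pts, wave_means[None, :])
    km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(filled)
    tau = np.zeros((pts.shape[0], K))
    tau[np.arange(pts.shape[0]), km.labels_] = 1.0
    # guard: a cluster may be empty for tiny n
    tau = 0.999 * tau + 0.001 / K
    tau /= tau.sum(axis=1, keepdims=True)
    return m_step(pts, mask, tau, per_class_sigma=per_class_sigma)


def _random_params(pts, mask, K, rng, per_class_sigma):
    beta0, sigma2 = _pooled_ols(pts, mask)
    scale = np.sqrt(sigma2.mean())
    beta = beta0[None, :] + rng.normal(size=(K, 3)) * scale * np.array([1.5, 0.75, 0.35])
    pi = rng.dirichlet(np.full(K, 5.0))
    s2 = np.broadcast_to(sigma2, (K, N_WAVES)).copy() if per_class_sigma else sigma2
    return LCGAParameters(pi=pi, beta=beta, sigma2=s2)


def _canonicalize(params, tau):
    """Reorder classes by descending trajectory mean averaged over waves;
    ties broken by descending intercept."""
    means = params.fitted_means().mean(axis=1)
    order = np.lexsort((-params.beta[:, 0], -means))
    sigma2 = params.sigma2[order] if params.per_class_sigma else params.sigma2
    new = LCGAParameters(pi=params.pi[order], beta=params.beta[order], sigma2=sigma2)
    return new, tau[:, order]


def fit_lcga(
    dataset,
    K: int,
    n_starts: int = 50,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    residual_structure: str = "wave",
    sigma2_floor: float = 1e-4,
    burn_in_iter: int = 40,
    n_finalists: int = 3,
) -> LCGAFit:
    """Best-of-``n_starts`` EM fit of the K-class LCGA.

    Half the starts come from k-means on the wave scores (mean-imputed for
    clustering only), half from random perturbations of the pooled
    single-class quadratic fit.  To keep many starts affordable, every start
    runs ``burn_in_iter`` EM iterations, then the ``n_finalists`` best
    log-likelihoods are iterated to convergence (relative LL change below
    ``tol``); this emulates the usual short-run/long-run multistart scheme.
    A start is abandoned if a class's total responsibility collapses or a
    residual variance falls below ``sigma2_floor``.
    """
    if residual_structure not in ("wave", "wave_by_class"):
        raise ValueError("residual_structure must be 'wave' or 'wave_by_class'")
    per_class = residual_structure == "wave_by_class"
    if isinstance(dataset, LongitudinalDataset):
        pts, mask = dataset.pts, dataset.wave_mask
    else:  # (pts, mask) tuple, used internally (e.g. bootstrap refits)
        pts, mask = dataset
        pts = np.asarray(pts, dtype=float)
        mask = np.asarray(mask, dtype=bool)
    if K < 1:
        raise ValueError("K must be >= 1")
    if mask[:, 0].sum() < K:
        raise ValueError("need at least K subjects with wave-1 scores")
    pts = np.where(mask, pts, 0.0)

    rng = np.random.default_rng(seed)
    if K == 1:
        beta, sigma2 = _pooled_ols(pts, mask)
        s2 = sigma2[None, :] if per_class else sigma2
        params = LCGAParameters(pi=np.ones(1), beta=beta[None, :], sigma2=s2)
        params, tau, ll, n_iter, conv = _em(
            pts, mask, params, tol, max_iter, sigma2_floor, min_weight=1e-6
        )
        params, tau = _canonicalize(params, tau)
        return LCGAFit(params, ll, tau, tau.argmax(axis=1), conv, n_iter, 1, seed)

    candidates = []
    failures = []
    start_seeds = rng.integers(0, 2**31 - 1, size=n_starts)
    for s, sseed in enumerate(start_seeds):
        srng = np.random.default_rng(sseed)
        try:
            if s < (n_starts + 1) // 2:
                params = _kmeans_params(pts, mask, K, int(sseed) % (2**31), per_class)
            else:
                params = _random_params(pts, mask, K, srng, per_class)
            params, tau, ll, n_iter, conv = _em(
                pts, mask, params, tol, min(burn_in_iter, max_iter),
                sigma2_floor, min_weight=1e-6,
            )
            candidates.append([ll, params, conv, n_iter, int(sseed)])
        except (DegenerateClassError, ConvergenceError, FloatingPointError,
                np.linalg.LinAlgError) as exc:
            failures.append(str(exc))
    if not candidates:
        raise ConvergenceError(
            f"no EM start survived out of {n_starts}", diagnostics=failures
        )

    candidates.sort(key=lambda c: -c[0])
    best = None
    for ll0, params, conv, n_iter0, sseed in candidates[: max(1, n_finalists)]:
        if conv:
            item = (ll0, params, True, n_iter0, sseed)
        else:
            try:
                params, tau, ll, n_iter, conv = _em(
                    pts, mask, params, tol, max_iter, sigma2_floor, min_weight=1e-6
                )
                item = (ll, params, conv, n_iter0 + n_iter, sseed)
            except (DegenerateClassError, ConvergenceError, FloatingPointError,
                    np.linalg.LinAlgError):
                continue
        if best is None or item[0] > best[0]:
            best = item
    if best is None:
        raise ConvergenceError(
            "no finalist start converged", diagnostics=[c[0] for c in candidates]
        )

    ll, params, conv, n_iter, sseed = best
    tau, ll = e_step(pts, mask, params)
    params, tau = _canonicalize(params, tau)
    return LCGAFit(
        params=params,
        loglik=ll,
        posteriors=tau,
        modal_class=tau.argmax(axis=1),
        converged=conv,
        n_iter=n_iter,
        n_starts_used=len(candidates),
        best_start_seed=sseed,
    )


# ---------------------------------------------------------------------------
# post-fit utilities


def assign_modal_class(fit: LCGAFit, subject_id=None):
    """Per-subject most likely class plus all K membership probabilities.

    Ties in the posterior go to the lower canonical class index (argmax's
    first-maximum rule), which is deterministic and logged in the column
    order itself.
    """
    import pandas as pd

    n, K = fit.posteriors.shape
    if subject_id is None:
        subject_id = np.arange(1, n + 1)
    out = {"subject_id": np.asarray(subject_id), "modal_class": fit.modal_class + 1}
    for k in range(K):
        out[f"prob_class{k + 1}"] = fit.posteriors[:, k]
    return pd.DataFrame(out)


def label_trajectories(fit: LCGAFit, ptsd_cutoff: float = 44.0) -> list:
    """Semantic trajectory names from the fitted wave means relative to the
    probable-PTSD cut-off: low (all below), high (all at/above), decreasing
    (above at wave 1 only), increasing (below at wave 1, at/above later).
    Unmatched shapes keep their positional name ``class_k``."""
    means = fit.params.fitted_means()
    labels = []
    for k in range(fit.K):
        above = means[k] >= ptsd_cutoff
        if not above.any():
            labels.append("low")
        elif above.all():
            labels.append("high")
        elif above[0] and not above[1] and not above[2]:
            labels.append("decreasing")
        elif not above[0] and above[1] and above[2]:
            labels.append("increasing")
        else:
            labels.append(f"class_{k + 1}")
    seen: dict = {}
    for i, lab in enumerate(labels):
        seen.setdefault(lab, []).append(i)
    for lab, idx in seen.items():
        if len(idx) > 1:
            for j, i in enumerate(idx):
                labels[i] = f"{lab}_{j + 1}"
    return labels
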