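"""Bias-adjusted three-step regression of latent class on covariates.

Step 1 fits the LCGA; step 2 summarises its classification quality as the
K-by-K error matrix D with D[k, s] = P(modal class s | true class k),
estimated from the posteriors; step 3 regresses the latent class on
covariates by maximum likelihood, treating the modal assignment as an
imperfect indicator of the latent class with known error rates D:

    log L(gamma) = sum_i log sum_k P(C_i = k | x_i; gamma) * D[k, s_i]

where P(C = k | x; gamma) is a multinomial logit and s_i is subject i's
modal class.  Regressing on the modal class directly attenuates covariate
effects whenever classification is imperfect; fixing D inside the
likelihood removes that attenuation while keeping the mixture model itself
untouched, and reduces to ordinary multinomial logistic regression when D
is the identity.  Standard errors come from the observed information
(numerical Hessian) and ignore the step-1 sampling variability of D, as the
standard three-step procedure does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import LongitudinalDataset
from .errors import ConvergenceError, RankDeficiencyError
from .lcga import LCGAFit

__all__ = [
    "ClassificationErrorMatrix",
    "CovariateModelResult",
    "classification_error_matrix",
    "fit_corrected_multinomial",
    "run_main_effects_model",
    "run_interaction_model",
    "apply_bonferroni",
]


@dataclass
class ClassificationErrorMatrix:
    """Row-stochastic D with D[k, s] = P(modal class s | true class k), and
    the expected class sizes sum_i tau_ik."""

    D: np.ndarray
    class_sizes: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        self.class_sizes = np.asarray(self.class_sizes, dtype=float)
        rows = self.D.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-10) or np.any(self.D < 0):
            raise ValueError("D must be row-stochastic")

    @property
    def K(self) -> int:
        return self.D.shape[0]


def classification_error_matrix(tau, modal) -> ClassificationErrorMatrix:
    """D[k, s] = sum_i tau_ik 1(modal_i = s) / sum_i tau_ik."""
    tau = np.asarray(tau, dtype=float)
    modal = np.asarray(modal)
    n, K = tau.shape
    sizes = tau.sum(axis=0)
    if np.any(sizes <= 0):
        empty = int(np.flatnonzero(sizes <= 0)[0])
        raise ValueError(f"expected size of class {empty + 1} is zero")
    D = np.zeros((K, K))
    for s in range(K):
        D[:, s] = tau[modal == s].sum(axis=0)
    D /= sizes[:, None]
    return ClassificationErrorMatrix(D=D, class_sizes=sizes)


# ---------------------------------------------------------------------------
# corrected multinomial likelihood


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[j] for j in np.flatnonzero(diag <= tol)]
    if bad:
        raise RankDeficiencyError(bad)


def _neg_loglik_and_grad(g_flat, X, D, modal_onehot, K, P):
    gamma = np.zeros((K, P))
    gamma[1:] = g_flat.reshape(K - 1, P)
    eta = X @ gamma.T
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)  # (n, K)
    d = modal_onehot @ D.T  # (n, K): d_ik = D[k, s_i]
    q = np.einsum("ik,ik->i", p, d)
    q = np.maximum(q, 1e-300)
    nll = -np.log(q).sum()
    # d nll / d gamma_kj = -sum_i x_ij p_ik (d_ik - q_i) / q_i   (k >= 1)
    w = p * (d - q[:, None]) / q[:, None]
    grad = -(w[:, 1:].T @ X)
    return nll, grad.ravel()


@dataclass
class CovariateModelResult:
    """Fitted corrected (or naive, D = I) multinomial model.

    ``gamma`` holds log-odds per class relative to class index
    ``referent`` (canonical order); ``cov`` is the joint covariance of the
    non-referent coefficient blocks.  ``table()`` expands to every pairwise
    contrast with ORs, Wald 95% CIs, and p-values; odds ratios are
    transitive across referent rotations by construction.
    """

    model_tag: str
    referent: int
    class_names: tuple
    predictor_names: tuple
    gamma: np.ndarray  # (K, P), referent row = 0
    cov: np.ndarray  # ((K-1)P, (K-1)P) for non-referent rows
    loglik: float
    converged: bool
    grad_norm: float
    n_used: int
    n_dropped: int = 0
    bonferroni_alpha: Optional[float] = None

    @property
    def K(self) -> int:
        return self.gamma.shape[0]

    def _block_index(self, k: int) -> int:
        """Index of class k within the stacked non-referent blocks."""
        nonref = [j for j in range(self.K) if j != self.referent]
        return nonref.index(k)

    def contrast(self, a: int, b: int) -> pd.DataFrame:
        """Log-odds of class a vs class b per predictor, with Wald SE/CI/p."""
        P = self.gamma.shape[1]
        coef = self.gamma[a] - self.gamma[b]
        L = np.zeros((P, self.cov.shape[0]))
        if a != self.referent:
            ia = self._block_index(a)
            L[:, ia * P:(ia + 1) * P] = np.eye(P)
        if b != self.referent:
            ib = self._block_index(b)
            L[:, ib * P:(ib + 1) * P] -= np.eye(P)
        var = np.einsum("ij,jk,ik->i", L, self.cov, L)
        se = np.sqrt(np.maximum(var, 0.0))
        z = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.nan)
        pval = 2.0 * stats.norm.sf(np.abs(z))
        lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
        with np.errstate(over="ignore"):  # near-separated contrasts -> inf CI
            return pd.DataFrame({
            "contrast": f"{self.class_names[a]}_vs_{self.class_names[b]}",
            "predictor": list(self.predictor_names),
            "coef": coef, "se": se, "or": np.exp(coef),
            "or_ci_low": np.exp(lo), "or_ci_high": np.exp(hi),
            "z": z, "p": pval,
        })

    def table(self, pairs: Optional[Sequence[tuple]] = None) -> pd.DataFrame:
        """All pairwise contrasts (or the requested ones), one row per
        contrast-predictor pair."""
        if pairs is None:
            K = self.K
            pairs = [(a, b) for a in range(K) for b in range(K) if a < b]
        frames = [self.contrast(a, b) for a, b in pairs]
        out = pd.concat(frames, ignore_index=True)
        out.insert(0, "model", self.model_tag)
        return out


def fit_corrected_multinomial(
    modal,
    D,
    X,
    predictor_names: Optional[Sequence[str]] = None,
    class_names: Optional[Sequence[str]] = None,
    referent: int = 0,
    model_tag: str = "corrected",
    gtol: float = 1e-6,
) -> CovariateModelResult:
    """Maximise the misclassification-corrected multinomial likelihood.

    ``modal`` holds modal class indices (0-based), ``D`` the classification
    error matrix (row-stochastic; pass the identity for a naive modal-class
    regression), ``X`` the design matrix including its intercept column.
    """
    modal = np.asarray(modal)
    X = np.asarray(X, dtype=float)
    D = D.D if isinstance(D, ClassificationErrorMatrix) else np.asarray(D, dtype=float)
    K = D.shape[0]
    n, P = X.shape
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(P)]
    if class_names is None:
        class_names = [f"class_{k + 1}" for k in range(K)]
    if not 0 <= referent < K:
        raise ValueError("referent out of range")
    _check_design(X, predictor_names)

    onehot = np.zeros((n, K))
    onehot[np.arange(n), modal] = 1.0

    # standardise non-constant columns for optimisation and the numerical
    # Hessian (covariates can differ in scale by orders of magnitude);
    # coefficients and covariance are mapped back afterwards
    col_sd = X.std(axis=0)
    const = col_sd < 1e-12
    m = np.where(const, 0.0, X.mean(axis=0))
    s = np.where(const, 1.0, col_sd)
    Xs = (X - m) / s

    x0 = np.zeros((K - 1) * P)
    res = optimize.minimize(
        _neg_loglik_and_grad, x0, args=(Xs, D, onehot, K, P),
        jac=True, method="BFGS",
        options={"gtol": gtol * max(1.0, n / 100.0), "maxiter": 2000},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if not res.success and grad_norm > 1e-3 * n:
        raise ConvergenceError(
            f"corrected multinomial fit did not converge "
            f"(max |gradient| = {grad_norm:.3g}); possible separation",
            diagnostics=res,
        )

    from statsmodels.tools.numdiff import approx_hess1

    hess = approx_hess1(
        res.x, lambda g: _neg_loglik_and_grad(g, Xs, D, onehot, K, P)[0]
    )
    try:
        cov_std = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            "observed information is singular; possible separation",
            diagnostics=res,
        ) from exc

    # back-transform: eta = gamma_std . (x - m)/s  =>  per class block,
    # gamma = A gamma_std with A[j,j] = 1/s_j and the intercept absorbing
    # the centring shifts
    A = np.diag(1.0 / s)
    icept = int(np.flatnonzero(const)[0]) if const.any() else None
    if icept is not None:
        A[icept, :] = -m / s
        A[icept, icept] = 1.0
    T = np.kron(np.eye(K - 1), A)  # stacked-block map (row-major blocks)
    cov = T @ cov_std @ T.T
    gamma_free = (res.x.reshape(K - 1, P) @ A.T)
    gamma = np.zeros((K, P))
    rows = [k for k in range(K) if k != 0]
    gamma[rows] = gamma_free  # optimiser referent is class 0
    # re-express relative to the requested referent
    gamma = gamma - gamma[referent][None, :]
    if referent != 0:
        # covariance of (gamma_k - gamma_ref) blocks for k != referent
        blocks = []
        P_ = P
        full = np.zeros((K, P_, (K - 1) * P_))
        for i, k in enumerate(rows):
            full[k, :, i * P_:(i + 1) * P_] = np.eye(P_)
        L = np.vstack([full[k] - full[referent] for k in range(K) if k != referent])
        cov = L @ cov @ L.T

    return CovariateModelResult(
        model_tag=model_tag,
        referent=referent,
        class_names=tuple(class_names),
        predictor_names=tuple(predictor_names),
        gamma=gamma,
        cov=cov,
        loglik=-float(res.fun),
        converged=bool(res.success or grad_norm <= 1e-3 * n),
        grad_norm=grad_norm,
        n_used=n,
    )


# ---------------------------------------------------------------------------
# study-shaped model runners


def _complete_case(dataset: LongitudinalDataset, snp: int, with_abuse: bool):
    d = dataset.dosages[:, snp]
    cols = [d, dataset.age, dataset.gender,
            dataset.ancestry_pcs[:, 0], dataset.ancestry_pcs[:, 1]]
    if with_abuse:
        cols.insert(1, dataset.cts_total)
    M = np.column_stack(cols)
    keep = np.all(np.isfinite(M), axis=1)
    return M, keep


def _snp_index(dataset: LongitudinalDataset, snp) -> int:
    if isinstance(snp, str):
        return list(dataset.snp_names).index(snp)
    return int(snp)


def run_main_effects_model(
    dataset: LongitudinalDataset,
    fit: LCGAFit,
    snp,
    class_names: Optional[Sequence[str]] = None,
    referent: Optional[int] = None,
) -> CovariateModelResult:
    """Corrected multinomial model of class on SNP dosage (additive, per
    copy of the minor allele), controlling for age, gender, and the two
    ancestry principal components.  Subjects with any missing predictor are
    dropped (complete-case)."""
    j = _snp_index(dataset, snp)
    M, keep = _complete_case(dataset, j, with_abuse=False)
    n_dropped = int((~keep).sum())
    X = np.column_stack([np.ones(keep.sum()), M[keep]])
    names = ("const", "dosage", "age", "gender", "pc1", "pc2")
    dmat = classification_error_matrix(fit.posteriors, fit.modal_class)
    ref = fit.K - 1 if referent is None else referent  # lowest-trajectory class
    result = fit_corrected_multinomial(
        fit.modal_class[keep], dmat, X,
        predictor_names=names, class_names=class_names,
        referent=ref, model_tag="main_effects",
    )
    result.n_dropped = n_dropped
    return result


def run_interaction_model(
    dataset: LongitudinalDataset,
    fit: LCGAFit,
    snp,
    class_names: Optional[Sequence[str]] = None,
    referent: Optional[int] = None,
    center_abuse: bool = False,
) -> CovariateModelResult:
    """Adds the childhood-physical-abuse main effect and the dosage-by-abuse
    interaction to the main-effects model.  Abuse enters on its raw 0-24
    scale unless ``center_abuse``; the interaction OR is per abuse-unit per
    allele copy."""
    j = _snp_index(dataset, snp)
    M, keep = _complete_case(dataset, j, with_abuse=True)
    n_dropped = int((~keep).sum())
    Mk = M[keep].copy()
    abuse = Mk[:, 1] - (Mk[:, 1].mean() if center_abuse else 0.0)
    inter = Mk[:, 0] * abuse
    X = np.column_stack([np.ones(len(Mk)), Mk[:, 0], abuse, inter, Mk[:, 2:]])
    names = ("const", "dosage", "abuse", "dosage_x_abuse",
             "age", "gender", "pc1", "pc2")
    dmat = classification_error_matrix(fit.posteriors, fit.modal_class)
    ref = fit.K - 1 if referent is None else referent
    result = fit_corrected_multinomial(
        fit.modal_class[keep], dmat, X,
        predictor_names=names, class_names=class_names,
        referent=ref, model_tag="interaction",
    )
    result.n_dropped = n_dropped
    return result


def apply_bonferroni(table: pd.DataFrame, n_snps: int, alpha: float = 0.05) -> pd.DataFrame:
    """Flag each row at the nominal level and at the Bonferroni-corrected
    level alpha / n_snps; both flags are retained."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    out = table.copy()
    out["sig_nominal"] = out["p"] < alpha
    out["sig_bonferroni"] = out["p"] < alpha / n_snps
    out.attrs["bonferroni_alpha"] = alpha / n_snps
    return out
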