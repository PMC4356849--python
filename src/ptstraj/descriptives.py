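"""Scale scoring, psychometrics, genotype QC, and descriptive decompositions.

Covers the per-subject scale arithmetic (17-item PTSD checklist totals and
the probable-PTSD cut-off; 6-item conflict-tactics physical-abuse totals),
Cronbach's alpha, the Spearman gene-environment correlation, per-SNP
genotype quality control (call rate, minor allele frequency, exact
Hardy-Weinberg test), class-by-genotype cross-tabulations with an optional
median-split stratifier, and Bonferroni-corrected group comparisons between
an analytic subsample and the subjects excluded from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "score_pcl",
    "score_cts",
    "cronbach_alpha",
    "spearman_rge",
    "hwe_exact_test",
    "genotype_qc",
    "median_split",
    "crosstab_by_class",
    "compare_included_vs_dropped",
]

PCL_CUTOFF = 44.0


def score_pcl(items, cutoff: float = PCL_CUTOFF, strict_exceed: bool = False):
    """Total severity score of the 17-item PTSD checklist (items 1-5, total
    17-85) and the probable-PTSD flag.

    The cut-off convention is configurable: by default a total at or above
    the cut-off counts as probable PTSD (``total >= 44``, the common
    operational rule); ``strict_exceed=True`` flags only totals strictly
    above it.  Out-of-range items raise with the offending index.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape[-1] != 17:
        raise ValueError(f"expected 17 items, got {arr.shape[-1]}")
    bad = np.flatnonzero((arr < 1) | (arr > 5) | (arr != np.round(arr)))
    if bad.size:
        raise ValueError(f"item {int(bad[0]) % 17 + 1} outside 1-5")
    total = arr.sum(axis=-1)
    flag = total > cutoff if strict_exceed else total >= cutoff
    return total, flag


def score_cts(items):
    """Childhood physical abuse severity: sum of six conflict-tactics items
    rated 0-4, giving a 0-24 total."""
    arr = np.asarray(items, dtype=float)
    if arr.shape[-1] != 6:
        raise ValueError(f"expected 6 items, got {arr.shape[-1]}")
    bad = np.flatnonzero((arr < 0) | (arr > 4) | (arr != np.round(arr)))
    if bad.size:
        raise ValueError(f"item {int(bad[0]) % 6 + 1} outside 0-4")
    return arr.sum(axis=-1)


def cronbach_alpha(item_matrix) -> float:
    """Internal consistency: (k/(k-1)) (1 - sum of item variances / variance
    of the total), sample variances with ddof=1 on complete rows."""
    X = np.asarray(item_matrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if k < 2 or n < 3:
        raise ValueError("need at least 2 items and 3 complete subjects")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def spearman_rge(dosage, abuse):
    """Spearman rank correlation between SNP dosage and the abuse score
    (midranks for the heavily tied dosages), with the t-approximation
    p-value.  This is the gene-environment correlation check: a material
    correlation would complicate any interaction's interpretation."""
    d = np.asarray(dosage, dtype=float)
    a = np.asarray(abuse, dtype=float)
    keep = np.isfinite(d) & np.isfinite(a)
    d, a = d[keep], a[keep]
    if d.size < 5:
        raise ValueError("need at least 5 paired complete observations")
    if np.all(d == d[0]) or np.all(a == a[0]):
        raise ValueError("constant vector; correlation undefined")
    rho, p = stats.spearmanr(d, a)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test by full enumeration over heterozygote
    counts compatible with the observed allele counts.

    P(h heterozygotes | n genotypes, n_minor alleles) is proportional to
    2^h * n! / ((n_minor-h)/2)! h! ((2n - n_minor - h)/2)!, enumerated over
    all h with the parity of n_minor; the p-value sums the probabilities of
    configurations no more likely than the observed one.
    """
    for name, v in (("n_hom_minor", n_hom_minor), ("n_het", n_het),
                    ("n_hom_major", n_hom_major)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("no genotyped subjects")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # orient to the rarer allele
        n_minor = 2 * n - n_minor
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hs = hs[(n_minor - hs) // 2 + hs <= n]
    logp = np.array([
        h * math.log(2.0)
        - math.lgamma((n_minor - h) // 2 + 1)
        - math.lgamma(h + 1)
        - math.lgamma(n - (n_minor + h) // 2 + 1)
        for h in hs
    ])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hs == n_het)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_chi2_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """One-df chi-square Hardy-Weinberg test (cross-check for the exact test)."""
    n = n_hom_minor + n_het + n_hom_major
    p = (2 * n_hom_minor + n_het) / (2 * n)
    exp = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    obs = np.array([n_hom_minor, n_het, n_hom_major])
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = np.nansum((obs - exp) ** 2 / np.where(exp > 0, exp, np.nan))
    return float(stats.chi2.sf(x2, df=1))


def genotype_qc(
    dosages,
    snp_names: Optional[Sequence[str]] = None,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
):
    """Per-SNP QC: call rate, minor allele frequency, exact Hardy-Weinberg
    p-value; SNPs failing any threshold are dropped and listed with the
    reason.  Returns (filtered dosage matrix, kept names, report frame)."""
    D = np.asarray(dosages, dtype=float)
    n, S = D.shape
    if snp_names is None:
        snp_names = [f"snp{j + 1}" for j in range(S)]
    rows = []
    keep = []
    for j in range(S):
        d = D[:, j]
        called = d[np.isfinite(d)]
        call_rate = called.size / n
        if called.size == 0:
            rows.append({"snp": snp_names[j], "n_called": 0, "call_rate": 0.0,
                         "maf": np.nan, "hwe_p": np.nan, "kept": False,
                         "reason": "no calls"})
            continue
        counts = [int((called == g).sum()) for g in (2, 1, 0)]  # minor-hom, het, major-hom
        maf = (counts[1] + 2 * counts[0]) / (2 * called.size)
        maf = min(maf, 1 - maf)
        hwe_p = hwe_exact_test(*counts)
        reasons = []
        if call_rate <= call_rate_min:
            reasons.append(f"call rate {call_rate:.3f} <= {call_rate_min}")
        if maf <= maf_min:
            reasons.append(f"MAF {maf:.4f} <= {maf_min}")
        if hwe_p <= hwe_p_min:
            reasons.append(f"HWE p {hwe_p:.2e} <= {hwe_p_min}")
        kept = not reasons
        if kept:
            keep.append(j)
        rows.append({"snp": snp_names[j], "n_called": called.size,
                     "call_rate": call_rate, "maf": maf, "hwe_p": hwe_p,
                     "kept": kept, "reason": "; ".join(reasons)})
    report = pd.DataFrame(rows)
    return D[:, keep], [snp_names[j] for j in keep], report


# ---------------------------------------------------------------------------
# cross-tabulations


def median_split(values) -> np.ndarray:
    """High/low stratifier: 'high' means strictly above the sample median;
    values at the median fall in the low stratum."""
    v = np.asarray(values, dtype=float)
    med = np.nanmedian(v)
    return np.where(v > med, "high", "low")


def crosstab_by_class(
    class_labels,
    dosages,
    stratifier=None,
    class_order: Optional[Sequence] = None,
):
    """Row-percentage tables of dosage (0/1/2) within each trajectory class.

    Returns a DataFrame with counts and percentages per class; with a
    ``stratifier`` (labels, or a continuous score which is median-split),
    a dict of stratum -> DataFrame.  Percentages in each row sum to 100 up
    to rounding; counts are always carried alongside.
    """
    labels = np.asarray(class_labels)
    d = np.asarray(dosages, dtype=float)
    if labels.shape[0] != d.shape[0]:
        raise ValueError("labels and dosages must align")
    if stratifier is not None:
        strat = np.asarray(stratifier)
        if strat.dtype.kind in "fiu":
            strat = median_split(strat)
        return {
            s: crosstab_by_class(labels[strat == s], d[strat == s],
                                 class_order=class_order)
            for s in ("low", "high")
        }
    if class_order is None:
        class_order = sorted(pd.unique(labels).tolist(), key=str)
    rows = []
    for cls in class_order:
        sel = (labels == cls) & np.isfinite(d)
        nc = int(sel.sum())
        counts = [int((d[sel] == g).sum()) for g in (0, 1, 2)]
        pcts = [100.0 * c / nc if nc else np.nan for c in counts]
        rows.append({"class": cls, "n": nc,
                     "n_dose0": counts[0], "n_dose1": counts[1], "n_dose2": counts[2],
                     "pct_dose0": pcts[0], "pct_dose1": pcts[1], "pct_dose2": pcts[2]})
    return pd.DataFrame(rows)


def compare_included_vs_dropped(
    full: pd.DataFrame,
    included_mask,
    variables: dict,
    alpha: float = 0.05,
):
    """Bonferroni-corrected comparisons of included vs dropped subjects:
    Welch t-tests for continuous variables, chi-square tests for
    categorical ones.  ``variables`` maps column name to 'continuous' or
    'categorical'.  Degenerate variables are skipped with a note."""
    mask = np.asarray(included_mask, dtype=bool)
    rows = []
    n_tests = len(variables)
    for name, kind in variables.items():
        a = full.loc[mask, name].dropna()
        b = full.loc[~mask, name].dropna()
        note = ""
        if len(a) < 2 or len(b) < 2:
            rows.append({"variable": name, "test": None, "stat": np.nan,
                         "p": np.nan, "significant": False,
                         "note": "skipped: degenerate group"})
            continue
        if kind == "continuous":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            test = "welch_t"
        elif kind == "categorical":
            tab = pd.crosstab(full[name], mask)
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                rows.append({"variable": name, "test": "chi2", "stat": np.nan,
                             "p": np.nan, "significant": False,
                             "note": "skipped: constant variable"})
                continue
            stat, p, _, _ = stats.chi2_contingency(tab)
            test = "chi2"
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        rows.append({"variable": name, "test": test, "stat": float(stat),
                     "p": float(p), "significant": bool(p < alpha / n_tests),
                     "note": note})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_alpha"] = alpha / n_tests
    return out
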