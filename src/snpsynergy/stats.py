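"""Statistical primitives shared by all analysis stages.

Conventions follow common candidate-gene practice: Pearson chi-square
without continuity correction, Wald z inference on the log-odds scale
with 1.96-SE confidence limits, Woolf standard errors for 2x2 tables
with a Haldane-Anscombe +0.5 fallback when a cell is empty, and a
maximum-likelihood logistic fit that flags (rather than silently
reports) separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile
SEPARATION_COEF = 15.0  # |log-odds| beyond which a fit is treated as separated


class AnalysisError(ValueError):
    """Raised when a statistical primitive gets unusable input."""


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p_value: float
    expected: tuple[float, float, float]
    allele2_freq: float


def hwe_chi2(counts) -> HWEResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    ``counts`` is the genotype triple (n_hom_ref, n_het, n_hom_alt).
    Expected counts are (p^2, 2pq, q^2) * n with the allele frequency
    estimated from the same table; cells with zero expectation (a
    monomorphic locus) contribute nothing.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3:
        raise AnalysisError(
            "HWE is defined for three-genotype (SNP) tables only; "
            "presence/null loci are untestable"
        )
    if any(c < 0 for c in counts):
        raise AnalysisError("negative genotype count")
    n = sum(counts)
    if n == 0:
        raise AnalysisError("empty genotype table")
    n_rr, n_ra, n_aa = counts
    q = (2 * n_aa + n_ra) / (2 * n)  # effect-allele frequency
    p = 1.0 - q
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    chi2 = sum(
        (o - e) ** 2 / e for o, e in zip(counts, expected) if e > 0
    )
    p_value = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return HWEResult(chi2=float(chi2), df=1, p_value=p_value,
                     expected=expected, allele2_freq=q)


# ---------------------------------------------------------------------------
# 2x2 odds ratio


@dataclass(frozen=True)
class TwoByTwoResult:
    """Cross-product odds ratio with Woolf confidence limits.

    Cell layout: a = exposed cases, b = unexposed cases, c = exposed
    controls, d = unexposed controls, so OR = ad / bc.
    """

    odds_ratio: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    p_value: float
    haldane: bool
    cells: tuple[int, int, int, int]


def or_2x2(a: int, b: int, c: int, d: int) -> TwoByTwoResult:
    """Unadjusted odds ratio from a 2x2 case-control table.

    Zero cells trigger the Haldane-Anscombe correction (+0.5 to every
    cell), flagged in the result.  A zero margin (no exposed subject at
    all, or no case at all, etc.) leaves the OR undefined and raises.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise AnalysisError("negative cell count")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise AnalysisError(
            f"odds ratio undefined: zero margin in table {cells}"
        )
    haldane = any(x == 0 for x in cells)
    aa, bb, cc, dd = (x + 0.5 for x in cells) if haldane else cells
    log_or = float(np.log(aa * dd / (bb * cc)))
    se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    z = log_or / se
    p = float(2 * sps.norm.sf(abs(z)))
    return TwoByTwoResult(
        odds_ratio=float(np.exp(log_or)),
        log_or=log_or,
        se_log_or=se,
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=max(p, np.finfo(float).tiny),
        haldane=haldane,
        cells=tuple(int(x) for x in cells),
    )


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass
class RegressionFit:
    """A maximum-likelihood logistic fit with per-coefficient Wald tests."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float
    nobs: int
    converged: bool
    separated: bool

    def odds_ratio(self, term: str) -> float | None:
        if self.separated or not self.converged:
            return None
        return float(np.exp(self.params[term]))

    def conf_int(self, term: str) -> tuple[float, float] | None:
        if self.separated or not self.converged:
            return None
        lo = self.params[term] - Z95 * self.bse[term]
        hi = self.params[term] + Z95 * self.bse[term]
        return float(np.exp(lo)), float(np.exp(hi))

    def p_value(self, term: str) -> float | None:
        if self.separated or not self.converged:
            return None
        return float(self.pvalues[term])


def fit_logistic(response, design: pd.DataFrame) -> RegressionFit:
    """Fit ``P(response=1) = expit(design @ beta)`` by maximum likelihood.

    ``design`` must already contain the intercept column and no missing
    values.  Complete or quasi-complete separation (divergent
    coefficients, |coef| > 15 on the logit scale) is flagged; flagged
    fits report no odds ratio.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(design).astype(float)
    if y.ndim != 1 or len(y) != len(X):
        raise AnalysisError("response/design length mismatch")
    if not np.isin(y, (0.0, 1.0)).all():
        raise AnalysisError("response must be binary 0/1")
    if X.isna().any().any():
        raise AnalysisError("design matrix contains missing values")
    model = sm.Logit(y, X)
    separated = False
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-8)
        converged = bool(res.mle_retvals.get("converged", False))
        params = pd.Series(res.params, index=X.columns)
        bse = pd.Series(res.bse, index=X.columns)
        llf = float(res.llf)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separated = True
        params = pd.Series(np.nan, index=X.columns)
        bse = pd.Series(np.nan, index=X.columns)
        llf = float("nan")
    if converged and np.abs(params.to_numpy()).max() > SEPARATION_COEF:
        separated = True
    if not converged:
        separated = True
    with np.errstate(invalid="ignore", divide="ignore"):
        z = params / bse
        pvals = 2 * sps.norm.sf(np.abs(z))
    pvals = pd.Series(np.clip(pvals, np.finfo(float).tiny, 1.0), index=X.columns)
    return RegressionFit(
        params=params, bse=bse, zvalues=pd.Series(z, index=X.columns),
        pvalues=pvals, llf=llf, nobs=len(y),
        converged=converged and not separated, separated=separated,
    )


def likelihood_ratio_test(full: RegressionFit, reduced: RegressionFit,
                          df: int) -> float:
    """Two-sided P for nested logistic models via the LR chi-square."""
    if full.separated or reduced.separated:
        raise AnalysisError("likelihood-ratio test on a flagged fit")
    lr = 2.0 * (full.llf - reduced.llf)
    lr = max(lr, 0.0)
    return float(sps.chi2.sf(lr, df=df))


# ---------------------------------------------------------------------------
# Simple tests


def chi2_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x k count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise AnalysisError("need at least a 2x2 table")
    if (arr < 0).any():
        raise AnalysisError("negative count")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise AnalysisError("zero margin in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return float(chi2), int(dof), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with normal approximation and tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise AnalysisError("need at least two observations per group")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def ks_normality(x) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise AnalysisError("need at least two observations")
    mu, sigma = float(np.mean(x)), float(np.std(x, ddof=1))
    if sigma == 0:
        raise AnalysisError("degenerate sample (zero variance)")
    res = sps.kstest(x, "norm", args=(mu, sigma))
    return float(res.statistic), float(res.pvalue)


def bonferroni(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise AnalysisError("alpha must lie in (0, 1)")
    if m < 1:
        raise AnalysisError("number of tests must be >= 1")
    return alpha / m


def bonferroni_display(alpha: float, m: int) -> float:
    """The threshold rounded to the 4-decimal display convention."""
    return round(bonferroni(alpha, m), 4)
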