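"""Two-sample tests, effect sizes and multiplicity adjustment.

All comparisons are strictly upper-sided: with x the lower-dose (or first)
group and y the higher-dose group, the null is H0: mu_x = mu_y against
H1: mu_x > mu_y. Rejection uses ``p < alpha`` strictly.

Scalar entry points delegate to scipy / statsmodels; the private ``*_matrix``
helpers recompute the same quantities in closed form across a whole matrix of
bootstrap replicates and are cross-checked against the scalar routes in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .npi import Sample

__all__ = ["TestResult", "EffectStats", "t_test_upper", "wmt_upper", "effect_stats", "bh_adjust"]

#: largest combined sample size for which the WMT uses the exact null distribution
EXACT_WMT_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of one upper-sided two-sample test."""

    statistic: float
    p_value: float
    alpha: float
    test: str  # "t" or "wmt"

    @property
    def reject(self) -> bool:
        """Strict rejection rule: a p-value exactly at alpha does not reject."""
        return self.p_value < self.alpha

    @property
    def outcome(self) -> str:
        """'Y' for rejection, 'N' for non-rejection."""
        return "Y" if self.reject else "N"


@dataclass(frozen=True)
class EffectStats:
    """Raw and standardised effect size for a two-group comparison.

    ``pooled_sd`` is the averaged-variance form sqrt((s_x^2 + s_y^2)/2) with
    n-1 sample standard deviations — appropriate for (near-)equal group sizes
    — and ``cohens_d = effect_size / pooled_sd``.
    """

    effect_size: float
    cohens_d: float
    pooled_sd: float


def _as_array(x) -> np.ndarray:
    if isinstance(x, Sample):
        return x.values
    a = np.asarray(x, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("expected a non-empty 1-d array of measurements")
    return a


def t_test_upper(x, y, alpha: float = 0.05) -> TestResult:
    """Upper-sided equal-variance (pooled) two-sample t-test.

    The p-value is the upper tail of Student's t with n_x + n_y - 2 degrees
    of freedom. Identical constant samples have no defined statistic.
    """
    xv, yv = _as_array(x), _as_array(y)
    if xv.size < 2 or yv.size < 2:
        raise ValueError("the t-test requires at least two observations per group")
    res = sps.ttest_ind(xv, yv, equal_var=True, alternative="greater")
    if not np.isfinite(res.pvalue):
        raise ValueError("undefined t statistic: zero pooled variance")
    return TestResult(float(res.statistic), float(res.pvalue), alpha, "t")


def wmt_upper(x, y, alpha: float = 0.05) -> TestResult:
    """Upper-sided Wilcoxon–Mann–Whitney rank-sum test.

    Uses the exact null distribution of U when the combined sample is small
    (n_x + n_y <= 20) and tie-free, otherwise the normal approximation with
    continuity correction. The statistic reported is U for the first group.
    """
    xv, yv = _as_array(x), _as_array(y)
    combined = np.concatenate([xv, yv])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= EXACT_WMT_MAX_N and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(xv, yv, alternative="greater", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), alpha, "wmt")


def effect_stats(x, y) -> EffectStats:
    """Mean difference, averaged-variance pooled sd and Cohen's d."""
    xv, yv = _as_array(x), _as_array(y)
    if xv.size < 2 or yv.size < 2:
        raise ValueError("effect statistics require at least two observations per group")
    es = float(xv.mean() - yv.mean())
    s = float(np.sqrt((xv.var(ddof=1) + yv.var(ddof=1)) / 2.0))
    if s == 0.0:
        raise ValueError("both samples are constant: pooled sd is zero")
    return EffectStats(effect_size=es, cohens_d=es / s, pooled_sd=s)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR control).

    Order-preserving: the i-th output corresponds to the i-th input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-d array of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorised replicate paths (rows = bootstrap replicates)

def t_test_upper_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Upper-sided pooled-t p-values, one per row of (X, Y)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    nx, ny = X.shape[1], Y.shape[1]
    df = nx + ny - 2
    sp2 = ((nx - 1) * X.var(axis=1, ddof=1) + (ny - 1) * Y.var(axis=1, ddof=1)) / df
    t = (X.mean(axis=1) - Y.mean(axis=1)) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return sps.t.sf(t, df)


def wmt_upper_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Upper-sided WMT p-values, one per row of (X, Y).

    NPI-B replicates are almost surely tie-free, so the exact/asymptotic
    switch depends on the sample sizes only.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    method = "exact" if X.shape[1] + Y.shape[1] <= EXACT_WMT_MAX_N else "asymptotic"
    return sps.mannwhitneyu(X, Y, alternative="greater", method=method, axis=1).pvalue


def bh_adjust_matrix(P: np.ndarray) -> np.ndarray:
    """Row-wise BH step-up adjustment of a (replicates, tests) p-matrix."""
    P = np.asarray(P, dtype=float)
    r, k = P.shape
    order = np.argsort(P, axis=1)
    ps = np.take_along_axis(P, order, axis=1)
    scaled = ps * (k / np.arange(1, k + 1))
    adj = np.minimum.accumulate(scaled[:, ::-1], axis=1)[:, ::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=1)
    return out
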