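"""Supporting goodness-of-fit statistics.

These operationalize the auxiliary checks used alongside the curve-family
competition: a Pearson chi-squared comparison of an empirical curve against a
theoretical one (both treated as distributions over the time grid), a
Smirnov-Kolmogorov comparison of two curves in cumulative form, a Fisher
F-test for the parallelism of two decay curves on the log scale, and a
per-time-point normality check of replicate scatter.

Curves are not independent samples, so the chi-squared and KS p-values are
descriptive summaries rather than exact sampling probabilities; the
chi-squared calibration is exact only when the empirical noise variance
matches the expected magnitude (Poisson-like scaling), which is how the
calibration tests exercise it.

Note on the parallelism rejection rule: the conventional orientation is
implemented — parallelism (H0) is *rejected* when the slope-difference
statistic exceeds its critical value (Fd > Fst).  Result objects carry both
the statistic and the critical value so the decision is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GofResult",
    "ParallelismResult",
    "chisq_gof",
    "ks_compare",
    "parallelism_test",
    "gaussianity_check",
]


@dataclass
class GofResult:
    test: str
    statistic: float
    p_value: float
    df: int | None = None
    alpha: float = 0.05
    reject: bool = False
    detail: dict = field(default_factory=dict)

    @property
    def applicable(self) -> bool:
        return bool(self.detail.get("applicable", True))


@dataclass
class ParallelismResult:
    slope_a: float
    slope_b: float
    f_statistic: float       # Fd
    f_critical: float        # Fst at the chosen alpha
    p_value: float
    alpha: float
    parallel: bool           # Fd < Fst


def chisq_gof(empirical, theoretical, alpha=0.05) -> GofResult:
    """Pearson chi-squared fit of an empirical curve to a theoretical one.

    The theoretical curve is rescaled to the empirical curve's total mass so
    both are compared as distributions; the statistic is sum((o-e)^2/e) with
    n-1 degrees of freedom (one lost to the mass constraint).
    """
    o = np.asarray(empirical, dtype=float)
    e = np.asarray(theoretical, dtype=float)
    if o.shape != e.shape or o.ndim != 1:
        raise ValueError("curves must be equal-length 1-D arrays")
    if o.sum() <= 0:
        raise ValueError("empirical curve has non-positive mass")
    e = e * (o.sum() / e.sum())
    if np.any(e <= 0):
        raise ValueError("non-positive expected value after rescaling")
    stat = float(np.sum((o - e) ** 2 / e))
    df = len(o) - 1
    p = float(sps.chi2.sf(stat, df))
    return GofResult(test="pearson_chi2", statistic=stat, p_value=p, df=df,
                     alpha=alpha, reject=bool(p < alpha))


def _cumulative(y):
    y = np.asarray(y, dtype=float)
    total = y.sum()
    if total <= 0:
        raise ValueError("zero-mass curve")
    return np.cumsum(y) / total


def ks_compare(curve_a, curve_b, alpha=0.05) -> GofResult:
    """Smirnov-Kolmogorov comparison of two curves in normalized cumulative form.

    Both curves (non-negative, same grid) are converted to cumulative
    distributions over the grid; the statistic is the sup-difference.  The
    p-value uses the asymptotic two-sample Kolmogorov distribution with the
    grid length as the per-sample size and is descriptive (grid points are
    not independent draws).
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("curves must be equal-length 1-D arrays")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("curves must be non-negative after offset removal")
    ca, cb = _cumulative(a), _cumulative(b)
    d = float(np.max(np.abs(ca - cb)))
    n = len(a)
    en = np.sqrt(n * n / (2.0 * n))
    p = float(sps.kstwobign.sf((en + 0.12 + 0.11 / en) * d))
    return GofResult(test="smirnov_kolmogorov", statistic=d, p_value=p,
                     alpha=alpha, reject=bool(p < alpha),
                     detail={"descriptive_p": True})


def _ols_line(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean())) / float(xc @ xc)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    return slope, intercept, float(resid @ resid)


def parallelism_test(time_a, values_a, time_b, values_b, alpha=0.05) -> ParallelismResult:
    """Fisher slope-parallelism test on log-transformed decay segments.

    Both decay segments must be strictly positive; they are log-transformed so
    exponential decays become straight lines whose slopes equal -k.  The test
    compares the separate-slopes regression against the common-slope
    regression with an F statistic on (1, nA+nB-4) degrees of freedom; the
    curves are parallel when Fd < Fst.
    """
    ta, ya = np.asarray(time_a, float), np.asarray(values_a, float)
    tb, yb = np.asarray(time_b, float), np.asarray(values_b, float)
    if np.any(ya <= 0) or np.any(yb <= 0):
        raise ValueError("decay segments must be strictly positive for the log transform")
    la, lb = np.log(ya), np.log(yb)
    sa, _, sse_a = _ols_line(ta, la)
    sb, _, sse_b = _ols_line(tb, lb)
    sse_sep = sse_a + sse_b

    # common slope, separate intercepts (pooled within-group regression)
    xac, xbc = ta - ta.mean(), tb - tb.mean()
    yac, ybc = la - la.mean(), lb - lb.mean()
    sxx = float(xac @ xac + xbc @ xbc)
    sxy = float(xac @ yac + xbc @ ybc)
    common = sxy / sxx
    sse_pool = float(yac @ yac + ybc @ ybc) - common * sxy

    df2 = len(ta) + len(tb) - 4
    if df2 <= 0:
        raise ValueError("too few points for the parallelism test")
    denom = sse_sep / df2
    fd = ((sse_pool - sse_sep) / 1.0) / denom if denom > 0 else np.inf
    fd = max(float(fd), 0.0)
    fst = float(sps.f.ppf(1.0 - alpha, 1, df2))
    p = float(sps.f.sf(fd, 1, df2))
    return ParallelismResult(slope_a=sa, slope_b=sb, f_statistic=fd,
                             f_critical=fst, p_value=p, alpha=alpha,
                             parallel=bool(fd < fst))


def gaussianity_check(aligned, alpha=0.05):
    """Shapiro-Wilk normality of replicate scatter at every time point.

    Returns one :class:`GofResult` per grid point plus the fraction of
    applicable points that pass at ``alpha`` (stored on each result's detail).
    Points with (numerically) constant replicate values are degenerate for a
    normality test and are reported as not applicable.
    """
    mat = np.asarray(aligned.values, dtype=float)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 replicates per time point")
    results = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        resid = col - col.mean()
        if np.ptp(resid) <= 1e-12 * max(abs(col).max(), 1.0):
            results.append(GofResult(test="shapiro_wilk", statistic=np.nan,
                                     p_value=np.nan, alpha=alpha, reject=False,
                                     detail={"applicable": False}))
            continue
        stat, p = sps.shapiro(resid)
        results.append(GofResult(test="shapiro_wilk", statistic=float(stat),
                                 p_value=float(p), alpha=alpha,
                                 reject=bool(p < alpha),
                                 detail={"applicable": True}))
    usable = [r for r in results if r.applicable]
    frac = (sum(not r.reject for r in usable) / len(usable)) if usable else np.nan
    for r in results:
        r.detail["pass_fraction"] = frac
    return results
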