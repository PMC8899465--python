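"""Per-time-point F tests of H0: beta(s, t) = 0 for the fitted region.

The statistic at each measurement time is

    F(t) = [(RSS0(t) - RSS1(t)) / K] / [RSS1(t) / (n - K - 1)]

referred to F(K, n-K-1), with RSS0 the null (centered-phenotype) and RSS1
the model residual sum of squares at that time.  K here is the nominal
number of bivariate basis functions (``k_test``, default 15), not the
coefficient count -- see the methods note.  A whole-grid aggregate pooling
RSS over all time points is also reported, clearly labelled as an extra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    """Per-time and aggregate F-test results for one gene region."""

    f_by_time: np.ndarray
    p_by_time: np.ndarray
    df1: int
    df2: int
    f_global: float
    p_global: float
    time_grid: np.ndarray = None
    alpha_decisions: dict = field(default_factory=dict)

    def reject(self, alpha: float) -> np.ndarray:
        return self.p_by_time < alpha


def _f_stat(rss0: float, rss1: float, df1: int, df2: int):
    F = ((rss0 - rss1) / df1) / (rss1 / df2)
    return F, float(stats.f.sf(F, df1, df2))


def _check_df(n: int, k_test: int) -> int:
    df2 = n - k_test - 1
    if df2 <= 0:
        raise ValueError(
            f"degrees of freedom n - K - 1 = {df2} <= 0 (n={n}, K={k_test}); "
            "need more subjects or a smaller K"
        )
    return df2


def f_test_pointwise(fit, time_index: int):
    """F and p at a single time point of a :class:`~lfdat.model.FofrResults`."""
    n = fit.nobs
    df2 = _check_df(n, fit.k_test)
    return _f_stat(
        fit.rss0_by_time[time_index], fit.rss1_by_time[time_index], fit.k_test, df2
    )


def f_test_all(fit, alphas=(0.05, 0.01, 0.001)) -> TestResult:
    """F tests at every time point plus the pooled whole-surface aggregate."""
    n = fit.nobs
    df2 = _check_df(n, fit.k_test)
    Q1 = len(fit.rss0_by_time)
    f = np.empty(Q1)
    p = np.empty(Q1)
    for q in range(Q1):
        f[q], p[q] = _f_stat(fit.rss0_by_time[q], fit.rss1_by_time[q], fit.k_test, df2)
    fg, pg = _f_stat(float(fit.rss0_by_time.sum()), float(fit.rss1_by_time.sum()), fit.k_test, df2)
    return TestResult(
        f_by_time=f,
        p_by_time=p,
        df1=fit.k_test,
        df2=df2,
        f_global=fg,
        p_global=pg,
        time_grid=np.asarray(fit.model.pheno.time_grid) if fit.model is not None else None,
        alpha_decisions={a: p < a for a in alphas},
    )
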