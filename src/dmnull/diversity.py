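"""Shannon diversity and the diversity-vs-population-size regression.

Individual hosts with larger bacterial populations tend, in mid-succession,
to carry *less* diverse communities (dominance of the best colonizer grows
with population size).  The module quantifies this with an ordinary
least-squares fit of Shannon diversity ``H`` (natural log) on
``log10(total CFU per host)``, and compares host lineages with a
likelihood-ratio test: the null model is a single shared regression line for
the pooled hosts, the alternative is a separate line (and, by default, a
separate residual variance) per lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .data_io import CommunityMatrix

__all__ = [
    "LinearFit",
    "LRTResult",
    "shannon",
    "shannon_per_host",
    "diversity_size_fit",
    "diversity_size_lrt",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of diversity on log10 community size."""

    slope: float
    intercept: float
    residual_variance: float  # maximum-likelihood estimate SSE/n
    r2_adjusted: float
    p_slope: float
    n: int
    loglik: float  # Gaussian log-likelihood at the MLE


@dataclass(frozen=True)
class LRTResult:
    """Pooled-vs-separate regression likelihood-ratio test."""

    loglik_h0: float
    loglik_h1: float
    statistic: float
    df: int
    p_value: float


def shannon(counts) -> float:
    """Shannon diversity ``H = -sum p_j ln p_j`` of one host's counts.

    Natural log; zero counts contribute nothing (limit ``p ln p -> 0``).
    The maximum for k species is ``ln k``, attained at even composition.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero host: Shannon diversity undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_host(m: CommunityMatrix) -> pd.DataFrame:
    """Per-host diversity table: host_id, lineage, H, log10_total."""
    totals = m.totals
    if np.any(totals <= 0):
        raise ValueError("zero-total hosts present; filter before computing H")
    H = [shannon(row) for row in m.counts]
    return pd.DataFrame(
        {
            "host_id": list(m.host_ids),
            "lineage": list(m.lineage),
            "H": H,
            "log10_total": np.log10(totals),
        }
    )


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(y)
    sse = float(res.ssr)
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        residual_variance=sse / n,
        r2_adjusted=float(res.rsquared_adj),
        p_slope=float(res.pvalues[1]),
        n=n,
        loglik=float(res.llf),
    )


def diversity_size_fit(m: CommunityMatrix) -> LinearFit:
    """OLS of Shannon H on log10(total CFU per host)."""
    if m.n_hosts < 3:
        raise ValueError("need >= 3 hosts")
    tab = shannon_per_host(m)
    x = tab["log10_total"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 totals")
    return _ols(x, tab["H"].to_numpy())


def _gaussian_loglik(sse: float, n: int) -> float:
    if sse <= 0:
        return np.inf
    return -0.5 * n * (np.log(2.0 * np.pi * sse / n) + 1.0)


def diversity_size_lrt(
    m_a: CommunityMatrix,
    m_b: CommunityMatrix,
    common_variance: bool = False,
) -> LRTResult:
    """Likelihood-ratio test for lineage differences in the H-size relation.

    H0: one line (slope, intercept, residual variance) fits the pooled hosts.
    H1: each lineage gets its own line.  With the default
    ``common_variance=False`` each lineage also gets its own residual
    variance (df = 3: slope, intercept, variance); with
    ``common_variance=True`` the two lines share one variance (df = 2).
    The statistic ``2 (l1 - l0)`` is referred to the upper tail of
    chi-squared with that df.
    """
    fit_a = diversity_size_fit(m_a)
    fit_b = diversity_size_fit(m_b)

    ta, tb = shannon_per_host(m_a), shannon_per_host(m_b)
    x = np.concatenate([ta["log10_total"], tb["log10_total"]])
    y = np.concatenate([ta["H"], tb["H"]])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in pooled log10 totals")
    pooled = _ols(x, y)
    ll0 = pooled.loglik

    if common_variance:
        sse = fit_a.residual_variance * fit_a.n + fit_b.residual_variance * fit_b.n
        ll1 = _gaussian_loglik(sse, fit_a.n + fit_b.n)
        df = 2
    else:
        ll1 = fit_a.loglik + fit_b.loglik
        df = 3

    stat = 2.0 * (ll1 - ll0)
    if stat < -1e-8:
        raise RuntimeError(f"LRT statistic unexpectedly negative: {stat}")
    stat = max(stat, 0.0)
    return LRTResult(
        loglik_h0=float(ll0),
        loglik_h1=float(ll1),
        statistic=float(stat),
        df=df,
        p_value=float(chi2.sf(stat, df)),
    )
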