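"""Crosstalk statistics: z-score, p-value, BH FDR, reduced chi-squared.

The null distribution for a group pair is the vector of link counts over
N randomized network instances.  The z-score standardizes the observed
count against the null sample mean and sample standard deviation
(``ddof=1``); it is transformed into a one-sided upper-tail normal
p-value (enrichment-oriented; depletion shows as z < 0).

Because the p-value is only meaningful if the null counts are roughly
normal, a reduced chi-squared goodness-of-fit statistic is computed for
each pair: the null counts are histogrammed into unit-width integer
bins, compared against the fitted normal via CDF differences, adjacent
bins pooled until each carries expected mass >= 1, and the chi-squared
sum divided by N - 3 degrees of freedom (three constraints: mean,
standard deviation, and the total count N).  Values of order one or less
indicate an acceptable normal fit.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = ["z_score", "p_from_z", "bh_fdr", "reduced_chi_squared"]


def z_score(n_obs: float, n_exp: float, sd: float) -> Optional[float]:
    """(observed - expected) / sd, or None when the null is degenerate (sd = 0)."""
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    if sd == 0:
        return None
    return (n_obs - n_exp) / sd


def p_from_z(z: float) -> float:
    """One-sided upper-tail standard-normal p-value, p = 1 - Phi(z)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(norm.sf(z))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def reduced_chi_squared(
    counts: Sequence[float], dof: str = "randomizations"
) -> Optional[float]:
    """Normality diagnostic for a null link-count sample.

    Parameters
    ----------
    counts:
        The N link counts observed across randomized network instances.
    dof:
        ``"randomizations"`` (default) divides chi-squared by N - 3.
        ``"bins"`` divides by (number of pooled bins - 3) instead, a
        sensitivity alternative for small samples (floored at 1).

    Returns None when the counts are constant (sd = 0), where normality
    is untestable.
    """
    if dof not in ("randomizations", "bins"):
        raise ValueError(f"unknown dof convention {dof!r}")
    x = np.asarray(counts, dtype=float)
    n = x.size
    if n <= 3:
        raise ValueError("need more than 3 null counts")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        return None
    # unit-width bins centred on integers, spanning the observed range
    k = np.rint(x).astype(int)
    lo, hi = int(k.min()), int(k.max())
    centers = np.arange(lo, hi + 1)
    observed = np.bincount(k - lo, minlength=centers.size).astype(float)
    edges = np.concatenate([centers - 0.5, [hi + 0.5]])
    cdf = norm.cdf(edges, loc=mean, scale=sd)
    expected = n * np.diff(cdf)

    # pool adjacent bins left-to-right until each expected mass >= 1
    pooled_o: list[float] = []
    pooled_e: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 1.0:
            pooled_o.append(acc_o)
            pooled_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:
        if pooled_e:
            pooled_o[-1] += acc_o
            pooled_e[-1] += acc_e
        else:  # degenerate: total expected mass below 1
            pooled_o.append(acc_o)
            pooled_e.append(max(acc_e, np.finfo(float).tiny))
    o_arr = np.array(pooled_o)
    e_arr = np.array(pooled_e)
    chi2 = float(np.sum((o_arr - e_arr) ** 2 / e_arr))
    if dof == "randomizations":
        denom = n - 3
    else:
        denom = max(len(pooled_o) - 3, 1)
    return chi2 / denom
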