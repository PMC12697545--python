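"""Shared statistical kernels: variance-ratio F test, weighted aggregated
Cauchy p-value combination (ACAT), and Benjamini-Hochberg FDR.

The Cauchy combination transforms each per-axis p-value to a standard
Cauchy variate, forms the weighted sum T = sum_a w_a tan((0.5 - p_a) pi),
and reads the combined p-value off the Cauchy tail, 0.5 - arctan(T)/pi.
Its tail behaviour is insensitive to dependence between the combined
p-values, which suits per-axis tests computed from the same traces.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: p-values are clipped to [EPS, 1-EPS] before the tangent transform
P_CLIP_EPS = 1e-15


class InvalidDfError(ValueError):
    """Raised on degrees of freedom below 1."""


class InvalidWeightError(ValueError):
    """Raised on non-positive combination weights."""


def variance_ratio_pvalue(
    s2_num: float,
    df_num: float,
    s2_den: float,
    df_den: float,
    tail: str = "lower",
) -> float:
    """One-sided p-value for a ratio of independent sample variances.

    Under equal true variances, s2_num/s2_den ~ F(df_num, df_den).
    ``tail="lower"`` returns P(F <= r) (is the numerator variance smaller?
    — loop calling); ``tail="upper"`` returns P(F >= r) (is it larger?
    — boundary calling).  Returns NaN when either variance is not finite
    or the denominator is 0 (untestable).
    """
    if df_num < 1 or df_den < 1:
        raise InvalidDfError(f"degrees of freedom must be >= 1, got ({df_num}, {df_den})")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    if not (np.isfinite(s2_num) and np.isfinite(s2_den)) or s2_den == 0:
        return float("nan")
    if s2_num < 0 or s2_den < 0:
        raise ValueError("variances must be non-negative")
    r = s2_num / s2_den
    if tail == "lower":
        return float(stats.f.cdf(r, df_num, df_den))
    return float(stats.f.sf(r, df_num, df_den))


def cauchy_combine(
    pvals,
    weights,
    return_stat: bool = False,
):
    """Weighted aggregated-Cauchy combination of per-axis p-values.

    NaN p-values (untestable axes) are dropped and the remaining weights
    renormalized; if every axis is NaN the result is NaN.  p-values are
    clipped to [1e-15, 1 - 1e-15] before the tangent transform to avoid
    overflow.

    Returns the combined p-value, or ``(p, T)`` with the Cauchy statistic
    T when ``return_stat`` is true (larger T = more significant).
    """
    p = np.asarray(pvals, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if p.shape != w.shape:
        raise ValueError("pvals and weights must have the same shape")
    if np.any(w[np.isfinite(w)] <= 0) or not np.all(np.isfinite(w)):
        raise InvalidWeightError("weights must be positive and finite")
    ok = np.isfinite(p)
    if not ok.any():
        return (float("nan"), float("nan")) if return_stat else float("nan")
    p_ok = np.clip(p[ok], P_CLIP_EPS, 1.0 - P_CLIP_EPS)
    w_ok = w[ok] / w[ok].sum()
    t = float(np.sum(w_ok * np.tan((0.5 - p_ok) * np.pi)))
    combined = float(0.5 - np.arctan(t) / np.pi)
    return (combined, t) if return_stat else combined


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries pass through as NaN and do not count toward the number of
    tests m.  Output is capped at 1 and monotone in the input order
    statistics; adjusted values are never below the raw p-values.
    """
    p = np.asarray(pvals, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    ok = np.isfinite(flat)
    m = int(ok.sum())
    if m == 0:
        return out.reshape(p.shape)
    pv = flat[ok]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out_flat = out.ravel()
    out_flat[ok] = res
    return out_flat.reshape(p.shape)
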