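"""Hinge change-point models linking OTU abundance to plant phenotypes.

The hinge model is flat below a threshold and linear above it,

    y = mu + beta * (x - e)_+ + error,

continuous at the threshold e.  It captures the idea that a microbe only
affects the plant once its abundance passes some level.  The threshold is
profiled over the observed abundances (extremes excluded so both segments
keep enough points); for each candidate the two remaining parameters are an
ordinary least-squares fit, and the candidate with minimal residual sum of
squares wins.  Because the threshold makes the usual F-test asymptotics
invalid, the slope's p-value comes from a permutation test that shuffles x
against y and refits the full profile each time.

A Benjamini-Hochberg step-up turns per-OTU p-values into FDR-adjusted ones
for screening whole OTU tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ChangePointFit", "fit_hinge", "fdr_bh", "screen_otus"]

#: distinct x values excluded at each extreme of the candidate grid
EDGE_EXCLUSION = 3


@dataclass(frozen=True)
class ChangePointFit:
    """Fitted hinge model: threshold, segment parameters, fit quality."""

    threshold: float
    mean_before: float
    slope_after: float
    rss: float
    p_value: float | None
    n: int


def _hinge_design_sums(x: np.ndarray, candidates: np.ndarray):
    """Precompute per-candidate hinge design sums (independent of y)."""
    H = np.maximum(x[:, None] - candidates[None, :], 0.0)  # n x n_cand
    s1 = H.sum(axis=0)
    s2 = (H**2).sum(axis=0)
    n = len(x)
    denom = n * s2 - s1**2
    return H, s1, denom


def _profile_hinge_from_sums(
    y: np.ndarray, H: np.ndarray, s1: np.ndarray, denom: np.ndarray,
    candidates: np.ndarray,
):
    """Closed-form OLS per candidate threshold; returns (e, mu, beta, rss).

    Ties in RSS resolve to the smallest threshold (candidates ascend and the
    comparison is strict).
    """
    n = len(y)
    sy = y.sum()
    sxy = H.T @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(denom > 0, (n * sxy - s1 * sy) / denom, 0.0)
    intercept = (sy - slope * s1) / n
    rss = (y**2).sum() - intercept * sy - slope * sxy
    j = int(np.argmin(rss))
    return float(candidates[j]), float(intercept[j]), float(slope[j]), float(rss[j])


def fit_hinge(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> ChangePointFit:
    """Profile-least-squares hinge fit with a permutation p-value for the slope.

    Candidate thresholds are the distinct observed x values with the
    ``EDGE_EXCLUSION`` smallest and largest excluded, keeping at least three
    points on each side of any threshold.  Set ``n_perm=0`` to skip the
    permutation test (p_value is then None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 10:
        raise ValueError("hinge fit needs at least 10 paired observations")
    distinct = np.unique(x)
    if len(distinct) < 2 * EDGE_EXCLUSION - 1 or len(distinct) < 5:
        raise ValueError("hinge fit needs at least 5 distinct x values")
    candidates = distinct[EDGE_EXCLUSION - 1 : len(distinct) - EDGE_EXCLUSION]
    if candidates.size == 0:
        candidates = distinct[1:-1]
    H, s1, denom = _hinge_design_sums(x, candidates)
    e, mu, beta, rss = _profile_hinge_from_sums(y, H, s1, denom, candidates)

    p = None
    if n_perm > 0:
        # The test statistic is the profile RSS reduction (equivalently the
        # likelihood ratio for the slope): under permutation of the x-y
        # pairing, sum((y - mean)^2) is invariant, so counting permutations
        # whose minimised RSS is <= the observed one compares the same
        # statistic while honouring the threshold selection.  Permuting y
        # rather than x leaves the per-candidate design sums reusable.
        rng = np.random.default_rng(seed)
        count_ge = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            _, _, _, rss_p = _profile_hinge_from_sums(yp, H, s1, denom, candidates)
            if rss_p <= rss:
                count_ge += 1
        p = (1 + count_ge) / (1 + n_perm)
    return ChangePointFit(
        threshold=e, mean_before=mu, slope_after=beta, rss=rss,
        p_value=p, n=len(x),
    )


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min over j >= i of (m * p_(j) / j), capped at 1, in the
    original input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def screen_otus(
    abundance: pd.DataFrame,
    y: np.ndarray,
    n_perm: int = 199,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hinge-fit every OTU column of ``abundance`` against phenotype ``y``.

    ``abundance`` is sample x OTU (already subset to the cohort of interest,
    e.g. water-stressed plots of one compartment) aligned row-wise with
    ``y``.  Returns one row per attempted OTU with the fit parameters, the
    permutation p-value, its BH-FDR adjustment and a significance flag;
    per-OTU failures (degenerate abundance vectors) are recorded with NaN
    statistics rather than raised.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(abundance):
        raise ValueError("phenotype must align with abundance rows")
    rng = np.random.default_rng(seed)
    rows = []
    for otu in abundance.columns:
        x = abundance[otu].to_numpy(dtype=float)
        try:
            fit = fit_hinge(x, y, n_perm=n_perm, seed=int(rng.integers(2**31)))
            rows.append(
                {"otu": otu, "threshold": fit.threshold, "mean_before": fit.mean_before,
                 "slope_after": fit.slope_after, "rss": fit.rss, "p_value": fit.p_value,
                 "n": fit.n}
            )
        except ValueError:
            rows.append(
                {"otu": otu, "threshold": np.nan, "mean_before": np.nan,
                 "slope_after": np.nan, "rss": np.nan, "p_value": np.nan,
                 "n": int(np.isfinite(x).sum())}
            )
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = fdr_bh(out.loc[ok, "p_value"].to_numpy())
    out["p_adjusted"] = adj
    out["significant"] = out["p_adjusted"] < alpha
    return out
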