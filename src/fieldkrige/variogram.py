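"""Semivariograms: empirical estimation, model families, fitting, selection.

The semivariogram gamma(h) is half the expected squared difference between
values at two locations separated by distance h.  Six parametric families are
supported, each defined by a nugget (micro-scale variance), a partial sill
(spatially structured variance) and a range parameter (correlation extent);
the Matern forms carry an extra smoothness kappa:

* ``nugget_only``   gamma(h) = nugget for h > 0 (no spatial structure)
* ``exponential``   nugget + psill * (1 - exp(-h/r))
* ``spherical``     nugget + psill * (1.5 h/r - 0.5 (h/r)^3), constant past r
* ``gaussian``      nugget + psill * (1 - exp(-(h/r)^2))
* ``matern``        nugget + psill * (1 - 2^(1-k)/Gamma(k) (h/r)^k K_k(h/r))
* ``stein_matern``  Matern with the rescaled argument h*sqrt(2k)/r

The range parameter r follows the usual geostatistics convention: the
exponential and Gaussian families approach their sill asymptotically (their
effective range is about 3r and sqrt(3)r respectively); the spherical family
reaches the sill exactly at h = r.  ``VariogramModel.effective_range``
reports the derived value so results can be compared with other software
without ambiguity.

Fitting is weighted least squares on the empirical variogram with weights
N_h / h^2 by default (pair count over squared lag distance); the stored
``sse`` is the *unweighted* sum of squared errors so that models are
comparable on the scale conventionally tabulated.  Model selection takes the
minimum-sse fit with no complexity penalty (every family has the same three
free parameters up to the profiled kappa grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FAMILIES",
    "VariogramModel",
    "EmpiricalVariogram",
    "empirical_variogram",
    "model_semivariance",
    "fit_variogram",
    "fit_all_families",
    "select_best_model",
    "VariogramFitError",
]

#: Family order; also the documented tie-break order for model selection.
FAMILIES = (
    "nugget_only",
    "exponential",
    "spherical",
    "gaussian",
    "matern",
    "stein_matern",
)

#: default Matern smoothness; fitting holds kappa fixed unless a profile
#: grid is requested (continuous optimisation of the smoothness is
#: ill-conditioned on a handful of lags).
DEFAULT_KAPPA = 0.5
KAPPA_GRID = (0.3, 0.5, 1.0, 2.0, 5.0)


class VariogramFitError(RuntimeError):
    """The optimiser failed from every starting point."""


@dataclass(frozen=True)
class VariogramModel:
    """A parametric semivariance function gamma(h).

    Parameters are on the scale of the data: nugget and partial_sill in
    squared value units, range_ in plot units.  ``sse`` records the
    unweighted fit criterion when the model came from :func:`fit_variogram`.
    """

    family: str
    nugget: float
    partial_sill: float
    range_: float | None = None
    kappa: float | None = None
    sse: float | None = None
    weighted_sse: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be nonnegative")
        if self.family != "nugget_only":
            if self.range_ is None or self.range_ <= 0:
                raise ValueError(f"{self.family} model requires range > 0")
        if self.family in ("matern", "stein_matern"):
            if self.kappa is None or self.kappa <= 0:
                raise ValueError(f"{self.family} model requires kappa > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def effective_range(self) -> float | None:
        """Distance at which gamma reaches ~95% of the sill (derived)."""
        if self.family == "nugget_only" or self.range_ is None:
            return None
        if self.family == "exponential":
            return 3.0 * self.range_
        if self.family == "gaussian":
            return math.sqrt(3.0) * self.range_
        return self.range_

    def semivariance(self, h: np.ndarray | float) -> np.ndarray:
        """Evaluate gamma at distances h >= 0."""
        return model_semivariance(self, h)

    def covariance(self, h: np.ndarray | float) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h); C(0) = sill."""
        h = np.asarray(h, dtype=float)
        return self.sill - model_semivariance(self, h)


def _matern_correlation(u: np.ndarray, kappa: float) -> np.ndarray:
    """2^(1-k)/Gamma(k) * u^k * K_k(u), with the u -> 0 limit of 1."""
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    pos = u > 0
    up = u[pos]
    with np.errstate(over="ignore", invalid="ignore"):
        val = (2.0 ** (1.0 - kappa) / special.gamma(kappa)) * up**kappa * special.kv(kappa, up)
    # K_k underflows to 0 for large arguments: correlation -> 0 there.
    out[pos] = np.where(np.isfinite(val), np.clip(val, 0.0, 1.0), 0.0)
    return out


def model_semivariance(m: VariogramModel, h: np.ndarray | float) -> np.ndarray:
    """Closed-form semivariance of model ``m`` at distances ``h``.

    gamma(0) = 0 for every family (the nugget is the limit from above).
    Raises on negative distances.  Scalar in, scalar out.
    """
    h_in = np.asarray(h, dtype=float)
    scalar = h_in.ndim == 0
    h = np.atleast_1d(h_in)
    if (h < 0).any():
        raise ValueError("distances must be nonnegative")
    n, s, r = m.nugget, m.partial_sill, m.range_
    if m.family == "nugget_only":
        g = np.where(h > 0, n, 0.0)
    elif m.family == "exponential":
        g = np.where(h > 0, n + s * (1.0 - np.exp(-h / r)), 0.0)
    elif m.family == "spherical":
        hr = np.minimum(h / r, 1.0)
        g = np.where(h > 0, n + s * (1.5 * hr - 0.5 * hr**3), 0.0)
    elif m.family == "gaussian":
        g = np.where(h > 0, n + s * (1.0 - np.exp(-((h / r) ** 2))), 0.0)
    elif m.family == "matern":
        g = np.where(h > 0, n + s * (1.0 - _matern_correlation(h / r, m.kappa)), 0.0)
    elif m.family == "stein_matern":
        u = h * math.sqrt(2.0 * m.kappa) / r
        g = np.where(h > 0, n + s * (1.0 - _matern_correlation(u, m.kappa)), 0.0)
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(m.family)
    return float(g[0]) if scalar else g


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned Matheron semivariance estimates.

    ``lags`` are the mean pair distances within each retained bin, strictly
    increasing; ``gamma`` the semivariance estimates; ``counts`` the number
    of point pairs per bin (empty bins are dropped).
    """

    lags: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        if not (len(lags) == len(gamma) == len(counts)):
            raise ValueError("lags, gamma and counts must have equal length")
        if (np.diff(lags) <= 0).any():
            raise ValueError("lag centers must be strictly increasing")
        if (gamma < 0).any() or (counts < 1).any():
            raise ValueError("gamma must be >= 0 and counts >= 1")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.lags)


def empirical_variogram(
    values: np.ndarray,
    coords: np.ndarray,
    n_lags: int = 15,
    cutoff: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator gamma_hat(h) = sum (z_i - z_j)^2 / (2 N_h) per lag bin.

    Bins are ``n_lags`` equal-width intervals on (0, cutoff]; the default
    cutoff is one third of the maximum inter-point distance.  Empty bins are
    dropped; each retained bin is centred at its mean pair distance.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if values.ndim != 1 or len(values) != len(coords):
        raise ValueError("values must be 1-D and aligned with coords")
    if len(values) < 2:
        raise ValueError("need at least two observations")
    d = pdist(coords)
    if cutoff is None:
        cutoff = float(d.max()) / 3.0
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    keep = (d > 0) & (d <= cutoff)
    if not keep.any():
        raise ValueError(f"no point pairs within cutoff {cutoff}")
    d, sq = d[keep], sq[keep]
    edges = np.linspace(0.0, cutoff, n_lags + 1)
    idx = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_lags - 1)
    lags, gammas, counts = [], [], []
    for b in range(n_lags):
        sel = idx == b
        if not sel.any():
            continue
        lags.append(d[sel].mean())
        gammas.append(sq[sel].mean())
        counts.append(int(sel.sum()))
    return EmpiricalVariogram(np.array(lags), np.array(gammas), np.array(counts))


def _wls_weights(ev: EmpiricalVariogram, scheme: str) -> np.ndarray:
    if scheme == "nh_h2":
        return ev.counts / ev.lags**2
    if scheme == "nh":
        return ev.counts.astype(float)
    if scheme == "uniform":
        return np.ones(len(ev))
    raise ValueError(f"unknown weight scheme {scheme!r}")


def _fit_family_fixed_kappa(
    ev: EmpiricalVariogram, family: str, kappa: float | None, w: np.ndarray
) -> tuple[np.ndarray, float] | None:
    """Best (nugget, psill, range) for one family/kappa; returns params and
    weighted objective, or None if every start failed."""
    sw = np.sqrt(w)
    cutoff = float(ev.lags.max())
    sill0 = float(ev.gamma.mean()) if ev.gamma.mean() > 0 else 1.0

    def resid(theta: np.ndarray) -> np.ndarray:
        m = VariogramModel(family, theta[0], theta[1], theta[2], kappa=kappa)
        return sw * (model_semivariance(m, ev.lags) - ev.gamma)

    best: tuple[np.ndarray, float] | None = None
    for r0 in (cutoff / 10.0, cutoff / 3.0, cutoff):
        x0 = np.array([0.5 * sill0, 0.5 * sill0, r0])
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=([0.0, 0.0, 1e-8], [np.inf, np.inf, 100.0 * cutoff])
            )
        except Exception:
            continue
        obj = float(np.sum(sol.fun**2))
        if best is None or obj < best[1]:
            best = (sol.x, obj)
    return best


def fit_variogram(
    ev: EmpiricalVariogram,
    family: str,
    weights: str = "nh_h2",
    kappa: float | Sequence[float] | None = None,
) -> VariogramModel:
    """Weighted-least-squares fit of one family to an empirical variogram.

    Parameters are box-constrained nonnegative and the optimiser is started
    from several range values (cutoff/10, cutoff/3, cutoff) with the sill
    split evenly between nugget and partial sill; the best start wins.  For
    the Matern families ``kappa`` may be a single value, an iterable to
    profile over, or the string ``"profile"`` for the module-level
    ``KAPPA_GRID`` (default: fixed at ``DEFAULT_KAPPA``).  The returned
    model's ``sse`` is the unweighted sum of squared errors.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    w = _wls_weights(ev, weights)
    if family == "nugget_only":
        if len(ev) < 1:
            raise VariogramFitError("nugget-only fit needs at least one lag")
        nug = float(np.sum(w * ev.gamma) / np.sum(w))
        m = VariogramModel("nugget_only", nug, 0.0)
        resid = model_semivariance(m, ev.lags) - ev.gamma
        return replace(m, sse=float(np.sum(resid**2)),
                       weighted_sse=float(np.sum(w * resid**2)))
    if len(ev) < 3:
        raise VariogramFitError(f"{family} fit needs at least three lags, got {len(ev)}")
    if family in ("matern", "stein_matern"):
        kappas: Iterable[float]
        if kappa is None:
            kappas = (DEFAULT_KAPPA,)
        elif isinstance(kappa, str) and kappa == "profile":
            kappas = KAPPA_GRID
        elif np.isscalar(kappa):
            kappas = (float(kappa),)
        else:
            kappas = tuple(float(k) for k in kappa)
    else:
        kappas = (None,)

    best: tuple[np.ndarray, float, float | None] | None = None
    for k in kappas:
        sol = _fit_family_fixed_kappa(ev, family, k, w)
        if sol is not None and (best is None or sol[1] < best[1]):
            best = (sol[0], sol[1], k)
    if best is None:
        raise VariogramFitError(f"all optimiser starts failed for family {family!r}")
    theta, _, k = best
    m = VariogramModel(family, float(theta[0]), float(theta[1]), float(theta[2]), kappa=k)
    resid = model_semivariance(m, ev.lags) - ev.gamma
    return replace(m, sse=float(np.sum(resid**2)),
                   weighted_sse=float(np.sum(w * resid**2)))


def fit_all_families(
    ev: EmpiricalVariogram,
    families: Sequence[str] = FAMILIES,
    weights: str = "nh_h2",
) -> list[VariogramModel]:
    """Fit every requested family, skipping ones that fail to converge."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_variogram(ev, fam, weights=weights))
        except VariogramFitError:
            continue
    if not fits:
        raise VariogramFitError("no variogram family could be fitted")
    return fits


def select_best_model(fits: Sequence[VariogramModel]) -> VariogramModel:
    """Minimum-error model; exact ties go to the earlier family in ``FAMILIES``.

    Models are compared on the same criterion the fit minimised (the
    weighted sse) when every candidate carries one; otherwise on the
    unweighted sse.  No complexity penalty is applied: all families have
    the same number of free parameters.
    """
    fits = [f for f in fits if f.sse is not None]
    if not fits:
        raise ValueError("no fitted models to select from")
    use_weighted = all(f.weighted_sse is not None for f in fits)
    key = (lambda f: (f.weighted_sse, FAMILIES.index(f.family))) if use_weighted else (
        lambda f: (f.sse, FAMILIES.index(f.family)))
    return min(fits, key=key)


@dataclass(frozen=True)
class SpatialStructureTest:
    """Likelihood-ratio screen for spatial structure in one variable.

    Each candidate correlation structure is compared against the
    intercept-only iid model by REML likelihood ratio; ``is_spatial`` is True
    when any structure reaches p < alpha.  The chi-square reference uses
    df = 1 (the correlation range); because the iid model sits on the
    boundary of each alternative this test is conservative.
    """

    structures: tuple[str, ...]
    lrt_stats: np.ndarray
    p_values: np.ndarray
    best_structure: str | None
    is_spatial: bool
    alpha: float


def test_spatial_structure(
    values: np.ndarray,
    coords: np.ndarray,
    alpha: float = 0.05,
    structures: Sequence[str] | None = None,
) -> SpatialStructureTest:
    """Screen a residualized variable for evidence of spatial structure.

    Fits an intercept-only Gaussian model with iid errors and with each of
    five spatial correlation structures (exponential, gaussian, spherical,
    linear, rational quadratic) by REML; the LRT statistic is twice the
    log-likelihood gain, referred to chi-square with 1 df.  Structures that
    fail to converge are skipped with a warning.
    """
    import warnings

    from scipy.stats import chi2

    from .spatial_lmm import CORRELATION_STRUCTURES, fit_iid, fit_spatial_gls

    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(values) < 10:
        raise ValueError("spatial-structure test needs at least 10 observations")
    if structures is None:
        structures = CORRELATION_STRUCTURES
    X = np.ones((len(values), 1))
    null = fit_iid(values, X)
    names, stats, pvals = [], [], []
    for s in structures:
        try:
            fit = fit_spatial_gls(values, X, coords, structure=s, estimate_nugget=False)
        except Exception as exc:  # non-convergence: skip this structure
            warnings.warn(f"spatial structure {s!r} skipped: {exc}")
            continue
        lrt = max(2.0 * (fit.loglik_reml - null.loglik_reml), 0.0)
        names.append(s)
        stats.append(lrt)
        pvals.append(float(chi2.sf(lrt, 1)))
    stats_arr = np.asarray(stats)
    pvals_arr = np.asarray(pvals)
    best = names[int(np.argmin(pvals_arr))] if names else None
    return SpatialStructureTest(
        structures=tuple(names),
        lrt_stats=stats_arr,
        p_values=pvals_arr,
        best_structure=best,
        is_spatial=bool((pvals_arr < alpha).any()) if names else False,
        alpha=alpha,
    )
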