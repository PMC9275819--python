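"""Gaussian models with spatially correlated errors, fitted by REML.

These are the linear models behind (a) the likelihood-ratio screen for
spatial structure in residualized soil properties and (b) the mixed models
that include kriged covariates alongside the experimental design.  The model
is

    y = X beta + e,    e ~ N(0, sigma^2 * V(theta)),

where V has unit diagonal and off-diagonal entries

    V_ij = (1 - nu) * rho(d_ij / phi)        (same block, if blocks given)
    V_ij = 0                                 (different blocks)

with rho one of five classical correlation functions (exponential,
gaussian, spherical, linear, rational_quadratic), phi > 0 the correlation
range and nu in [0, 1) an optional nugget fraction.  When ``blocks`` is
supplied the correlation is nested within blocks: plots in different blocks
are independent, mirroring a random spatial effect per replicate block.

sigma^2 is profiled out; (phi, nu) are found by maximising the restricted
(REML) log-likelihood over a coarse grid followed by Nelder-Mead polish.
REML values are comparable across models sharing the same fixed-effects
design, which is how the likelihood-ratio test against the iid
(intercept-only covariance) model is formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CORRELATION_STRUCTURES",
    "SpatialGLSFit",
    "correlation_function",
    "fit_iid",
    "fit_spatial_gls",
]

CORRELATION_STRUCTURES = (
    "exponential",
    "gaussian",
    "spherical",
    "linear",
    "rational_quadratic",
)


def correlation_function(structure: str, u: np.ndarray) -> np.ndarray:
    """Correlation rho(u) at scaled distance u = d / phi, rho(0) = 1."""
    u = np.asarray(u, dtype=float)
    if structure == "exponential":
        return np.exp(-u)
    if structure == "gaussian":
        return np.exp(-(u**2))
    if structure == "spherical":
        uc = np.minimum(u, 1.0)
        return 1.0 - 1.5 * uc + 0.5 * uc**3
    if structure == "linear":
        return np.maximum(1.0 - u, 0.0)
    if structure == "rational_quadratic":
        return 1.0 / (1.0 + u**2)
    raise ValueError(f"unknown correlation structure {structure!r}")


@dataclass
class SpatialGLSFit:
    """Result of a REML spatial GLS fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    phi: float | None
    nugget_frac: float
    structure: str | None
    loglik_reml: float
    converged: bool
    n: int
    rank: int

    def wald_chi2(self, index: int) -> tuple[float, float]:
        """Single-df Wald chi-square and p-value for coefficient ``index``."""
        from scipy.stats import chi2

        se2 = self.cov_beta[index, index]
        stat = float(self.beta[index] ** 2 / se2)
        return stat, float(chi2.sf(stat, 1))

    def fitted(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta


def _reml_pieces(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS beta and REML log-likelihood components for covariance V."""
    n, p = X.shape
    c, low = linalg.cho_factor(V, lower=True)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = linalg.cho_solve((c, low), X)
    Vi_y = linalg.cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    XtViy = X.T @ Vi_y
    beta = linalg.solve(XtViX, XtViy, assume_a="pos")
    r = y - X @ beta
    Vi_r = linalg.cho_solve((c, low), r)
    quad = float(r @ Vi_r)
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise linalg.LinAlgError("X'V^-1X not positive definite")
    sigma2 = quad / (n - p)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma2)
        + logdet_V
        + logdet_XtViX
        + (n - p)
    )
    cov_beta = sigma2 * linalg.inv(XtViX)
    return beta, cov_beta, sigma2, float(ll)


def _build_V(
    dists: np.ndarray,
    same_block: np.ndarray | None,
    structure: str,
    phi: float,
    nugget_frac: float,
) -> np.ndarray:
    rho = correlation_function(structure, dists / phi)
    V = (1.0 - nugget_frac) * rho
    if same_block is not None:
        V = V * same_block
    np.fill_diagonal(V, 1.0)
    return V


def fit_iid(y: np.ndarray, X: np.ndarray) -> SpatialGLSFit:
    """OLS with iid errors, reported with its REML log-likelihood."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta, cov_beta, sigma2, ll = _reml_pieces(y, X, np.eye(n))
    return SpatialGLSFit(
        beta=beta, cov_beta=cov_beta, sigma2=sigma2, phi=None, nugget_frac=0.0,
        structure=None, loglik_reml=ll, converged=True, n=n, rank=p,
    )


def fit_spatial_gls(
    y: np.ndarray,
    X: np.ndarray,
    coords: np.ndarray,
    blocks: np.ndarray | None = None,
    structure: str = "exponential",
    estimate_nugget: bool = True,
    phi_bounds: tuple[float, float] | None = None,
) -> SpatialGLSFit:
    """REML fit of y = X beta + spatially correlated error.

    ``blocks`` (optional labels per observation) nests the correlation within
    blocks.  ``estimate_nugget`` adds the nugget fraction nu to the
    covariance parameters (one extra parameter); with it off the only
    covariance parameter beyond sigma^2 is the range phi.
    Raises :class:`numpy.linalg.LinAlgError` (via scipy) if the covariance
    cannot be factorised at the optimum; callers treat that as
    non-convergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, p = X.shape
    if len(y) != n or len(coords) != n:
        raise ValueError("y, X and coords must be aligned")
    dists = squareform(pdist(coords))
    same_block = None
    if blocks is not None:
        blocks = np.asarray(blocks)
        same_block = (blocks[:, None] == blocks[None, :]).astype(float)
    pos = dists[dists > 0]
    if pos.size == 0:
        raise ValueError("all coordinates coincide; no spatial model is identifiable")
    if phi_bounds is None:
        phi_bounds = (max(pos.min() / 4.0, 1e-6), 4.0 * pos.max())
    lo, hi = np.log(phi_bounds[0]), np.log(phi_bounds[1])

    def objective(params: np.ndarray) -> float:
        log_phi = float(np.clip(params[0], lo, hi))
        nu = 1.0 / (1.0 + np.exp(-params[1])) if estimate_nugget else 0.0
        V = _build_V(dists, same_block, structure, np.exp(log_phi), nu)
        try:
            _, _, _, ll = _reml_pieces(y, X, V)
        except linalg.LinAlgError:
            return 1e12
        return -ll

    # coarse grid then Nelder-Mead polish; cheap relative to the chol cost
    phis = np.exp(np.linspace(lo, hi, 8))
    nus = (-2.2, 0.0) if estimate_nugget else (0.0,)
    starts = [np.array([np.log(ph), nu]) for ph in phis for nu in nus]
    best_x, best_f = None, np.inf
    for x0 in starts:
        f0 = objective(x0)
        if f0 < best_f:
            best_x, best_f = x0, f0
    res = optimize.minimize(objective, best_x, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200})
    x = res.x if res.fun <= best_f else best_x
    phi = float(np.exp(np.clip(x[0], lo, hi)))
    nu = float(1.0 / (1.0 + np.exp(-x[1]))) if estimate_nugget else 0.0
    V = _build_V(dists, same_block, structure, phi, nu)
    beta, cov_beta, sigma2, ll = _reml_pieces(y, X, V)
    return SpatialGLSFit(
        beta=beta, cov_beta=cov_beta, sigma2=sigma2, phi=phi, nugget_frac=nu,
        structure=structure, loglik_reml=ll, converged=bool(np.isfinite(ll)),
        n=n, rank=p,
    )
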