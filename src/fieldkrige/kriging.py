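"""Ordinary kriging and leave-one-out cross-validation.

Ordinary kriging predicts the value at an unsampled location as a weighted
average of the observations, z0_hat = sum_i lambda_i z_i, with the weights
constrained to sum to one so the predictor is unbiased under an unknown
constant mean.  The weights solve the augmented linear system

    [ Gamma  1 ] [ lambda ]   [ gamma0 ]
    [ 1^T    0 ] [   mu   ] = [   1    ]

where Gamma is the matrix of semivariances between observations, gamma0 the
vector of semivariances from the target to each observation, and mu a
Lagrange multiplier.  The kriging variance is lambda^T gamma0 + mu.

All observations participate in every prediction (a global neighbourhood):
the fields this package targets have at most a few hundred plots, so no
search-radius machinery is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist, pdist, squareform

from .variogram import VariogramModel, model_semivariance

__all__ = ["KrigingPrediction", "KrigingError", "krige", "loocv"]


class KrigingError(RuntimeError):
    """The kriging system is singular or otherwise unsolvable."""


@dataclass(frozen=True)
class KrigingPrediction:
    """Prediction at one target: value, kriging variance, and weights."""

    prediction: float
    variance: float
    weights: np.ndarray
    lagrange: float


def _check_duplicates(coords: np.ndarray, m: VariogramModel) -> None:
    d = pdist(coords)
    if (d == 0).any() and m.nugget == 0:
        dup = np.argwhere(squareform(d == 0) & ~np.eye(len(coords), dtype=bool))
        pairs = sorted({tuple(sorted(p)) for p in dup.tolist()})
        raise KrigingError(
            f"duplicate coordinates with zero nugget make the system singular: "
            f"observation pairs {pairs[:5]}"
        )


def krige(
    m: VariogramModel,
    obs_coords: np.ndarray,
    obs_values: np.ndarray,
    target_coords: np.ndarray,
) -> list[KrigingPrediction]:
    """Ordinary-kriging predictions at each target location.

    The same factorisation of the augmented system serves every target.
    A target coinciding with an observation reproduces that observation
    exactly (gamma(0) = 0), with zero kriging variance when the nugget is
    zero.
    """
    obs_coords = np.atleast_2d(np.asarray(obs_coords, dtype=float))
    target_coords = np.atleast_2d(np.asarray(target_coords, dtype=float))
    z = np.asarray(obs_values, dtype=float)
    n = len(z)
    if n < 2:
        raise KrigingError("ordinary kriging needs at least two observations")
    _check_duplicates(obs_coords, m)

    Gamma = model_semivariance(m, squareform(pdist(obs_coords)))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = Gamma
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    try:
        lu, piv = linalg.lu_factor(A)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise KrigingError(f"kriging system is singular: {exc}") from exc

    G0 = model_semivariance(m, cdist(target_coords, obs_coords))
    preds: list[KrigingPrediction] = []
    for g0 in G0:
        rhs = np.append(g0, 1.0)
        sol = linalg.lu_solve((lu, piv), rhs)
        lam, mu = sol[:n], float(sol[n])
        var = float(lam @ g0 + mu)
        preds.append(
            KrigingPrediction(
                prediction=float(lam @ z),
                variance=max(var, 0.0) if var > -1e-8 else var,
                weights=lam,
                lagrange=mu,
            )
        )
    return preds


def loocv(
    m: VariogramModel,
    obs_coords: np.ndarray,
    obs_values: np.ndarray,
    refit: bool = False,
    n_lags: int = 15,
) -> dict[str, np.ndarray]:
    """Leave-one-out cross-validation of kriging predictions.

    For each observation i the value is predicted from all others; the
    standardized error is (zhat_-i - z_i) / sqrt(kriging variance_i).  Under
    a well-specified model the standardized errors resemble a standard
    normal sample.  By default the variogram model is held fixed across
    folds; ``refit=True`` refits the chosen family to each fold's empirical
    variogram instead.
    """
    from .variogram import empirical_variogram, fit_variogram

    obs_coords = np.atleast_2d(np.asarray(obs_coords, dtype=float))
    z = np.asarray(obs_values, dtype=float)
    n = len(z)
    if n < 3:
        raise KrigingError("LOOCV needs at least three observations")
    pred = np.empty(n)
    var = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        mi = m
        if refit:
            ev = empirical_variogram(z[keep], obs_coords[keep], n_lags=n_lags)
            mi = fit_variogram(ev, m.family, kappa=m.kappa)
        p = krige(mi, obs_coords[keep], z[keep], obs_coords[i : i + 1])[0]
        pred[i] = p.prediction
        var[i] = p.variance
    err = pred - z
    with np.errstate(divide="ignore", invalid="ignore"):
        std_err = err / np.sqrt(var)
    return {
        "prediction": pred,
        "variance": var,
        "error": err,
        "standardized_error": std_err,
    }
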