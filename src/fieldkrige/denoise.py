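"""Principal-component regression: collapse soil noise, then remove it.

The stages, in pipeline order:

1. :func:`pca_residual_soil` — PCA of the design-residualized soil
   properties (centered, scaled to unit variance so ppm-scale properties do
   not dominate pH-scale ones).
2. :func:`select_pcs` — keep components explaining at least ``min_pct`` %
   of variance, at most (number of replicate blocks - 3) of them, so the
   design effects stay estimable.
3. :func:`krige_pc_scores` — each retained PC score surface is itself
   spatially structured; fit all variogram families, select the best, and
   krige scores to every plot.
4. :func:`pcr_adjust_continuous` — linear mixed model
   trait ~ intercept + kriged PCs + spatial error nested in blocks; the
   adjusted trait subtracts the estimated PC contribution only, keeping the
   intercept so values stay on the original scale.
5. :func:`pcr_adjust_counts` — per OTU and compartment, a zero-inflated
   negative-binomial regression of counts on the kriged PCs; adjusted
   counts divide the observation by the exponentiated per-sample PC linear
   predictor, so zeros stay zero and positives stay positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .core import OTUTable, PlotGrid
from .kriging import krige
from .residualize import ResidualTable
from .spatial_lmm import fit_iid, fit_spatial_gls
from .variogram import (
    VariogramModel,
    empirical_variogram,
    fit_all_families,
    select_best_model,
)

__all__ = [
    "PCModel",
    "AdjustedTable",
    "AdjustedCounts",
    "adjust_counts_from_coefs",
    "pca_residual_soil",
    "select_pcs",
    "property_contributions",
    "krige_pc_scores",
    "pcr_adjust_continuous",
    "pcr_adjust_counts",
]


@dataclass(frozen=True)
class PCModel:
    """PCA of residualized soil properties.

    ``loadings`` is property x component with orthonormal columns;
    ``scores`` is plot x component (only plots with complete soil data);
    ``percent_variance`` sums to 100 over all components.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    percent_variance: np.ndarray
    center: pd.Series
    scale: pd.Series

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class AdjustedTable:
    """Adjusted continuous trait: observed, adjusted, change and its interval.

    ``change`` = adjusted - observed = minus the estimated PC contribution;
    the interval is the empirical 2.5/97.5 percentile band of the changes.
    """

    frame: pd.DataFrame
    change_interval: tuple[float, float]
    coefficients: dict[str, float]
    converged: bool

    def to_csv(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        self.frame.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class AdjustedCounts:
    """Adjusted OTU counts plus per-OTU coefficients and a retention report."""

    table: OTUTable
    coefficients: pd.DataFrame
    retention: dict[str, dict[str, int]]

    @property
    def retained_fraction(self) -> float:
        attempted = sum(r["attempted"] for r in self.retention.values())
        kept = sum(r["converged"] for r in self.retention.values())
        return kept / attempted if attempted else float("nan")


def pca_residual_soil(r: ResidualTable, properties: list[str] | None = None) -> PCModel:
    """PCA of residualized soil properties, centered and scaled to unit variance.

    Uses plots where every property is observed.  The sign of each component
    is fixed by making its largest-magnitude loading positive, so results
    are deterministic across linear-algebra backends.
    """
    props = properties if properties is not None else r.properties
    if len(props) < 2:
        raise ValueError("PCA needs at least two properties")
    df = r.residuals[["plot_id"] + props].dropna()
    if len(df) < 3:
        raise ValueError("PCA needs at least three complete plots")
    X = df[props].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = scale == 0
    if zero.any():
        bad = [p for p, z in zip(props, zero) if z]
        raise ValueError(f"constant propert{'y' if len(bad)==1 else 'ies'}: {bad}")
    Z = (X - center) / scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = s**2
    pct = 100.0 * var / var.sum()
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    loadings = pd.DataFrame(Vt.T, index=props, columns=comp_names)
    scores = pd.DataFrame(U * s, index=pd.Index(df["plot_id"], name="plot_id"),
                          columns=comp_names)
    return PCModel(
        loadings=loadings,
        scores=scores,
        percent_variance=pct,
        center=pd.Series(center, index=props),
        scale=pd.Series(scale, index=props),
    )


def select_pcs(p: PCModel, min_pct: float = 10.0, n_blocks: int = 8) -> list[int]:
    """Indices (0-based) of components to carry into the regression.

    Keeps components explaining at least ``min_pct`` percent of variance,
    capped at (n_blocks - 3) so the design remains estimable; an empty
    selection is returned as an empty list for the caller to handle.
    """
    if n_blocks < 4:
        raise ValueError("need at least 4 replicate blocks to spend PCs on")
    idx = [k for k, v in enumerate(p.percent_variance) if v >= min_pct]
    return idx[: n_blocks - 3]


def property_contributions(p: PCModel, k: int) -> pd.Series:
    """Percent contribution of each property to component ``k`` (0-based).

    With orthonormal loadings the squared loadings of one component sum to
    one, so contributions sum to 100.
    """
    if not 0 <= k < p.n_components:
        raise IndexError(f"component index {k} out of range")
    v = p.loadings.iloc[:, k].to_numpy()
    return pd.Series(100.0 * v**2, index=p.loadings.index, name=p.loadings.columns[k])


def krige_pc_scores(
    p: PCModel,
    layout: PlotGrid,
    components: list[int] | None = None,
    n_lags: int = 15,
    cutoff: float | None = None,
) -> tuple[pd.DataFrame, dict[str, VariogramModel]]:
    """Krige each selected PC score surface to every plot of the field.

    Per component: empirical variogram of the scores at sampled plots, fit
    of all six families, minimum-sse selection, then ordinary kriging to the
    full layout.  Sampled plots keep their observed scores exactly (ordinary
    kriging is an exact interpolator).  Returns (plot x PC_krig frame,
    chosen variogram model per component).
    """
    if components is None:
        components = list(range(p.n_components))
    obs_coords = layout.coords(p.scores.index)
    all_coords = layout.coords()
    out = pd.DataFrame({"plot_id": layout.frame["plot_id"]})
    models: dict[str, VariogramModel] = {}
    for k in components:
        name = p.scores.columns[k]
        z = p.scores.iloc[:, k].to_numpy(dtype=float)
        ev = empirical_variogram(z, obs_coords, n_lags=n_lags, cutoff=cutoff)
        best = select_best_model(fit_all_families(ev))
        preds = krige(best, obs_coords, z, all_coords)
        out[f"{name}_krig"] = [pr.prediction for pr in preds]
        models[name] = best
    return out, models


def _pc_matrix(pcs: pd.DataFrame, layout: PlotGrid) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in pcs.columns if c != "plot_id"]
    df = pcs.set_index("plot_id").loc[layout.frame["plot_id"], cols]
    return df.to_numpy(dtype=float), cols


def pcr_adjust_continuous(
    y: pd.Series | np.ndarray,
    pcs: pd.DataFrame,
    layout: PlotGrid,
    structure: str = "exponential",
) -> AdjustedTable:
    """Remove estimated soil-PC effects from one continuous trait.

    Fits trait = alpha + sum_j beta_j PCj_krig + spatial error nested in
    blocks (REML); the adjusted value is observed - sum_j beta_j PCj_krig,
    keeping alpha so adjusted values stay on the original scale.  On
    non-convergence the fit falls back to fixed effects with a warning.
    """
    yv = np.asarray(y, dtype=float)
    frame = layout.frame
    if len(yv) != len(frame):
        raise ValueError("trait must align with the layout (one value per plot)")
    P, names = _pc_matrix(pcs, layout)
    mask = np.isfinite(yv) & np.isfinite(P).all(axis=1)
    if mask.sum() < 20:
        raise ValueError("need at least 20 observed plots for the PC regression")
    X = np.column_stack([np.ones(mask.sum()), P[mask]])
    converged = True
    try:
        fit = fit_spatial_gls(
            yv[mask], X, layout.coords()[mask],
            blocks=frame["block"].to_numpy()[mask], structure=structure,
        )
    except Exception as exc:
        warnings.warn(f"spatial fit failed ({exc}); falling back to fixed effects")
        fit = fit_iid(yv[mask], X)
        converged = False
    beta = fit.beta[1:]
    pc_effect = np.full(len(yv), np.nan)
    pc_effect[np.isfinite(P).all(axis=1)] = P[np.isfinite(P).all(axis=1)] @ beta
    adjusted = yv - pc_effect
    change = adjusted - yv
    finite_change = change[np.isfinite(change) & np.isfinite(yv)]
    lo, hi = np.percentile(finite_change, [2.5, 97.5])
    out = pd.DataFrame(
        {
            "plot_id": frame["plot_id"],
            "observed": yv,
            "adjusted": adjusted,
            "change": change,
        }
    )
    out["outside_interval"] = (out["change"] < lo) | (out["change"] > hi)
    coefs = {"alpha": float(fit.beta[0])}
    coefs.update({n: float(b) for n, b in zip(names, beta)})
    return AdjustedTable(
        frame=out, change_interval=(float(lo), float(hi)),
        coefficients=coefs, converged=converged,
    )


def adjust_counts_from_coefs(
    observed: np.ndarray,
    P: np.ndarray,
    b: np.ndarray,
    literal_constant: bool = False,
) -> np.ndarray:
    """Back-transform counts given fitted PC coefficients.

    adjusted_i = observed_i / exp(sum_j b_j P_ij) — the per-sample linear
    predictor form; with ``literal_constant`` the divisor is the constant
    exp(sum_j b_j) for every sample.  b = 0 returns the observations
    unchanged; zeros are preserved; the adjustment direction is opposite to
    the sign of the linear predictor.
    """
    observed = np.asarray(observed, dtype=float)
    P = np.atleast_2d(np.asarray(P, dtype=float))
    b = np.asarray(b, dtype=float)
    if literal_constant:
        return observed / np.exp(b.sum())
    return observed / np.exp(P @ b)


def _fit_zinb(y: np.ndarray, X: np.ndarray, maxiter: int = 200):
    """One ZINB fit (intercept-only inflation); returns params or None."""
    import statsmodels.api as sm

    model = sm.ZeroInflatedNegativeBinomialP(
        y, X, exog_infl=np.ones((len(y), 1)), p=2
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="bfgs", maxiter=maxiter, disp=0)
        except Exception:
            return None
    if not np.all(np.isfinite(res.params)):
        return None
    converged = res.mle_retvals.get("converged", False)
    return res if converged else None


def pcr_adjust_counts(
    t: OTUTable,
    pcs: pd.DataFrame,
    layout: PlotGrid,
    include_block: bool = True,
    literal_constant: bool = False,
    min_positive: int = 10,
) -> AdjustedCounts:
    """Adjust OTU counts for soil-PC effects, per OTU and compartment.

    Each OTU (rounded to integer counts for the likelihood) is modelled
    independently within each compartment as zero-inflated negative binomial
    with log-mean = alpha + sum_j b_j PCj_krig (+ block effects when
    ``include_block``), intercept-only zero inflation and per-OTU
    dispersion.  Adjusted counts divide the observation by
    exp(sum_j b_j PCj_krig,i), the per-sample linear predictor; the
    ``literal_constant`` flag instead divides every sample by the constant
    exp(sum_j b_j), which rescales but does not reorder samples.

    OTUs with fewer than ``min_positive`` positive counts or failing
    convergence are dropped and tallied in the retention report; failures
    are never fatal.
    """
    P_all, names = _pc_matrix(pcs, layout)
    pc_by_plot = pd.DataFrame(P_all, index=layout.frame["plot_id"], columns=names)
    adjusted_parts, meta_parts, coef_rows = [], [], []
    retention: dict[str, dict[str, int]] = {}
    for comp in pd.unique(t.samples["compartment"]):
        mask = (t.samples["compartment"] == comp).to_numpy()
        meta = t.samples.loc[mask].reset_index(drop=True)
        counts = t.counts.loc[mask]
        P = pc_by_plot.loc[meta["plot_id"]].to_numpy(dtype=float)
        Xcols = [np.ones(len(meta)), P]
        if include_block:
            blocks = layout.frame.set_index("plot_id").loc[meta["plot_id"], "block"]
            dummies = pd.get_dummies(blocks, drop_first=True).to_numpy(dtype=float)
            Xcols.append(dummies)
        X = np.column_stack(Xcols)
        attempted = converged = 0
        adj = {}
        for otu in counts.columns:
            yobs = counts[otu].to_numpy(dtype=float)
            yint = np.round(yobs).astype(int)
            if (yint > 0).sum() < min_positive:
                continue
            attempted += 1
            res = _fit_zinb(yint, X)
            if res is None:
                continue
            converged += 1
            # params: [infl intercept, alpha, b_1..b_k, block effects..., ln alpha_disp]
            b = np.asarray(res.params[2 : 2 + P.shape[1]], dtype=float)
            adj[otu] = adjust_counts_from_coefs(yobs, P, b, literal_constant)
            coef_rows.append(
                {"compartment": comp, "otu": otu,
                 **{n: float(v) for n, v in zip(names, b)}}
            )
        retention[comp] = {"attempted": attempted, "converged": converged}
        if adj:
            adjusted_parts.append(pd.DataFrame(adj, index=meta["sample_id"]))
            meta_parts.append(meta)
    if not adjusted_parts:
        raise ValueError("no OTU could be modelled in any compartment")
    all_meta = pd.concat(meta_parts, ignore_index=True)
    all_counts = pd.concat(adjusted_parts, axis=0).fillna(0.0)
    table = OTUTable(samples=all_meta, counts=all_counts.loc[all_meta["sample_id"]],
                     layout=t.layout)
    return AdjustedCounts(
        table=table,
        coefficients=pd.DataFrame(coef_rows),
        retention=retention,
    )
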