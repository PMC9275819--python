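"""Remove experimental-design effects from plot-level variables.

Spatial modelling assumes stationarity: the mean must not vary with
location.  In a designed trial the mean does vary — through the watering
treatment, the genotype, and their interaction — so before any variogram is
estimated each variable is residualized against the full-factorial design

    value = intercept + Treatment + Genotype + Treatment:Genotype + error

by ordinary least squares, and the residuals (observed minus fitted) carry
forward.  Sum-to-zero contrasts are used throughout so that downstream
type-III tests are meaningful.  The fit uses only plots where the variable
is observed; residuals are defined only there (kriging fills in the rest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy

from .core import PhenotypeTable, PlotGrid, SoilTable

__all__ = ["ResidualTable", "design_matrix", "residualize", "residualize_column"]

DESIGN_FORMULA = "C(treatment, Sum) * C(genotype, Sum)"


@dataclass(frozen=True)
class ResidualTable:
    """Residuals and fitted values per plot and property.

    ``residuals`` and ``fitted`` are aligned DataFrames with a plot_id
    column; residual + fitted = observed exactly wherever observed.
    """

    residuals: pd.DataFrame
    fitted: pd.DataFrame

    @property
    def properties(self) -> list[str]:
        return [c for c in self.residuals.columns if c != "plot_id"]

    def values_for(self, prop: str) -> tuple[np.ndarray, pd.Index]:
        """Non-missing residuals for one property and their plot_ids."""
        col = self.residuals[prop]
        mask = col.notna()
        return col[mask].to_numpy(dtype=float), pd.Index(
            self.residuals.loc[mask, "plot_id"]
        )

    def to_csv(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        self.residuals.to_csv(path, sep=sep, index=False)


def design_matrix(layout_frame: pd.DataFrame, formula: str = DESIGN_FORMULA):
    """Full-factorial design matrix with sum-to-zero contrasts."""
    return patsy.dmatrix(formula, layout_frame, return_type="dataframe")


def _ols_residuals(y: np.ndarray, X: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit via pivoted decomposition; rank deficiency warns."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"design matrix for {what} is rank deficient "
            f"({rank} < {X.shape[1]}); unestimable contrasts dropped"
        )
    fitted = X @ beta
    return y - fitted, fitted


def residualize_column(
    values: pd.Series,
    plot_ids: pd.Series,
    layout: PlotGrid,
    formula: str = DESIGN_FORMULA,
) -> tuple[pd.Series, pd.Series]:
    """Residualize one named column against the design; returns (resid, fitted).

    Output series are indexed like ``values``; entries missing on input stay
    missing.
    """
    mask = values.notna().to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"column {values.name!r} has no observed values")
    ids = plot_ids[mask].astype(str)
    design_rows = layout.frame.set_index("plot_id").loc[ids]
    X = design_matrix(design_rows, formula).to_numpy(dtype=float)
    if mask.sum() < X.shape[1]:
        warnings.warn(
            f"column {values.name!r}: fewer observations ({mask.sum()}) than "
            f"design parameters ({X.shape[1]}); fit is saturated"
        )
    resid, fitted = _ols_residuals(values[mask].to_numpy(dtype=float), X, str(values.name))
    r = pd.Series(np.nan, index=values.index, name=values.name, dtype=float)
    f = pd.Series(np.nan, index=values.index, name=values.name, dtype=float)
    r[mask] = resid
    f[mask] = fitted
    return r, f


def residualize(
    table: SoilTable | PhenotypeTable,
    layout: PlotGrid,
    columns: list[str] | None = None,
    formula: str = DESIGN_FORMULA,
) -> ResidualTable:
    """Residualize every (or selected) column of a plot-level table.

    Each column is fitted independently on its observed plots only, so
    different missingness patterns across properties are handled naturally.
    """
    df = table.frame
    if columns is None:
        columns = [c for c in df.columns if c != "plot_id"]
    resid = pd.DataFrame({"plot_id": df["plot_id"]})
    fitted = pd.DataFrame({"plot_id": df["plot_id"]})
    for c in columns:
        r, f = residualize_column(df[c], df["plot_id"], layout, formula)
        resid[c] = r
        fitted[c] = f
    return ResidualTable(residuals=resid, fitted=fitted)
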