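"""Domain containers and table I/O for split-plot field trials.

The containers are thin, validated wrappers around :class:`pandas.DataFrame`
holding the four tables every stage of the pipeline consumes:

* :class:`PlotGrid` -- the field layout: one row per plot with integer grid
  coordinates and the split-plot design factors (block, watering treatment,
  genotype).
* :class:`SoilTable` -- plot-level soil-property measurements (ppm, mmho/cm,
  %, pH ...); missing values mark unsampled plots.
* :class:`PhenotypeTable` -- continuous plot-level traits (height, fresh and
  dry weight, isotope ratios ...).
* :class:`OTUTable` -- a sample x OTU count matrix with per-sample plot and
  compartment (root / rhizosphere / soil) metadata.

All tables read and write delimited text (TSV by default, CSV by extension).
Distances between plots are Euclidean in plot units on the integer
(row, col) grid; no metric field dimensions are assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "LayoutError",
    "ReferentialError",
    "EmptyTableError",
    "PlotGrid",
    "SoilTable",
    "PhenotypeTable",
    "OTUTable",
    "read_tables",
    "read_layout",
    "read_soil",
    "read_phenotypes",
    "read_otu_table",
    "filter_otu_table",
    "scale_to_common_depth",
]

LAYOUT_COLUMNS = ("plot_id", "row", "col", "block", "treatment", "genotype")
OTU_META_COLUMNS = ("sample_id", "plot_id", "compartment")
COMPARTMENTS = ("root", "rhizosphere", "soil")


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed one."""


class LayoutError(ValueError):
    """The field layout violates a structural invariant (e.g. duplicate coordinates)."""


class ReferentialError(ValueError):
    """A data table references a plot_id absent from the layout."""


class EmptyTableError(ValueError):
    """An operation removed every row of a table."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass(frozen=True)
class PlotGrid:
    """Field layout: plot coordinates plus split-plot design factors."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.frame, LAYOUT_COLUMNS, "layout")
        df = self.frame.reset_index(drop=True).copy()
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
        for c in ("plot_id", "block", "treatment", "genotype"):
            if df[c].isna().any():
                raise LayoutError(f"layout column {c!r} has missing values")
            df[c] = df[c].astype(str)
        if df["plot_id"].duplicated().any():
            dups = df.loc[df["plot_id"].duplicated(), "plot_id"].tolist()
            raise LayoutError(f"duplicate plot_id(s): {dups[:5]}")
        rc = df[["row", "col"]].apply(tuple, axis=1)
        if rc.duplicated().any():
            dups = rc[rc.duplicated()].tolist()
            raise LayoutError(f"duplicate (row, col) coordinate(s): {dups[:5]}")
        object.__setattr__(self, "frame", df[list(LAYOUT_COLUMNS)])

    @property
    def plot_ids(self) -> pd.Index:
        return pd.Index(self.frame["plot_id"])

    def coords(self, plot_ids: Iterable[str] | None = None) -> np.ndarray:
        """(n, 2) float array of (row, col) positions, in layout or given order."""
        df = self.frame.set_index("plot_id")
        if plot_ids is not None:
            df = df.loc[list(plot_ids)]
        return df[["row", "col"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, sep=_sep_for(path), index=False)


def _check_plot_ids(ids: pd.Series, layout: PlotGrid | None, what: str) -> None:
    if layout is None:
        return
    unknown = set(ids.astype(str)) - set(layout.plot_ids)
    if unknown:
        raise ReferentialError(
            f"{what} references plot_id(s) absent from the layout: {sorted(unknown)[:5]}"
        )


@dataclass(frozen=True)
class SoilTable:
    """Plot-level soil-property measurements; NaN marks unsampled plots."""

    frame: pd.DataFrame
    layout: PlotGrid | None = None

    def __post_init__(self) -> None:
        _require_columns(self.frame, ("plot_id",), "soil table")
        df = self.frame.reset_index(drop=True).copy()
        df["plot_id"] = df["plot_id"].astype(str)
        if df["plot_id"].duplicated().any():
            raise SchemaError("soil table has duplicate plot_id rows")
        _check_plot_ids(df["plot_id"], self.layout, "soil table")
        vals = df[self.property_columns(df)].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise SchemaError("soil table contains non-finite values")
        object.__setattr__(self, "frame", df)

    @staticmethod
    def property_columns(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c != "plot_id"]

    @property
    def properties(self) -> list[str]:
        return self.property_columns(self.frame)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, sep=_sep_for(path), index=False)


@dataclass(frozen=True)
class PhenotypeTable:
    """Continuous plot-level traits; NaN marks unmeasured plots."""

    frame: pd.DataFrame
    layout: PlotGrid | None = None

    def __post_init__(self) -> None:
        _require_columns(self.frame, ("plot_id",), "phenotype table")
        df = self.frame.reset_index(drop=True).copy()
        df["plot_id"] = df["plot_id"].astype(str)
        _check_plot_ids(df["plot_id"], self.layout, "phenotype table")
        vals = df[[c for c in df.columns if c != "plot_id"]].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise SchemaError("phenotype table contains non-finite values")
        object.__setattr__(self, "frame", df)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.frame.columns if c != "plot_id"]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, sep=_sep_for(path), index=False)


@dataclass(frozen=True)
class OTUTable:
    """Sample x OTU counts with per-sample plot and compartment metadata.

    ``samples`` has columns (sample_id, plot_id, compartment); ``counts`` is
    indexed by sample_id with one column per OTU.  Counts are nonnegative;
    they may be non-integer after proportional depth scaling.
    """

    samples: pd.DataFrame
    counts: pd.DataFrame
    layout: PlotGrid | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        _require_columns(self.samples, OTU_META_COLUMNS, "OTU sample metadata")
        meta = self.samples.reset_index(drop=True).copy()
        for c in OTU_META_COLUMNS:
            meta[c] = meta[c].astype(str)
        if meta["sample_id"].duplicated().any():
            raise SchemaError("OTU table has duplicate sample_id rows")
        _check_plot_ids(meta["plot_id"], self.layout, "OTU table")
        counts = self.counts.copy()
        counts.index = counts.index.astype(str)
        if set(counts.index) != set(meta["sample_id"]):
            raise SchemaError("OTU counts index does not match sample metadata")
        counts = counts.loc[meta["sample_id"]]
        if (counts.to_numpy() < 0).any():
            raise SchemaError("OTU counts must be nonnegative")
        object.__setattr__(self, "samples", meta[list(OTU_META_COLUMNS)])
        object.__setattr__(self, "counts", counts)

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def sample_depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def n_samples(self) -> int:
        return len(self.samples)

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide export: metadata columns followed by one column per OTU."""
        return pd.concat(
            [self.samples.reset_index(drop=True), self.counts.reset_index(drop=True)],
            axis=1,
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_wide_frame().to_csv(path, sep=_sep_for(path), index=False)

    def subset(self, mask: pd.Series | np.ndarray) -> "OTUTable":
        mask = np.asarray(mask, dtype=bool)
        return OTUTable(
            samples=self.samples.loc[mask].reset_index(drop=True),
            counts=self.counts.loc[mask],
            layout=self.layout,
        )


def read_layout(path: str | Path) -> PlotGrid:
    path = Path(path)
    return PlotGrid(pd.read_csv(path, sep=_sep_for(path)))


def read_soil(path: str | Path, layout: PlotGrid | None = None) -> SoilTable:
    path = Path(path)
    return SoilTable(pd.read_csv(path, sep=_sep_for(path)), layout=layout)


def read_phenotypes(path: str | Path, layout: PlotGrid | None = None) -> PhenotypeTable:
    path = Path(path)
    return PhenotypeTable(pd.read_csv(path, sep=_sep_for(path)), layout=layout)


def read_otu_table(path: str | Path, layout: PlotGrid | None = None) -> OTUTable:
    """Read a wide OTU table: sample_id, plot_id, compartment, then OTU columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(df, OTU_META_COLUMNS, "OTU table")
    otu_cols = [c for c in df.columns if c not in OTU_META_COLUMNS]
    counts = df[otu_cols].copy()
    counts.index = df["sample_id"].astype(str)
    return OTUTable(samples=df[list(OTU_META_COLUMNS)], counts=counts, layout=layout)


def read_tables(
    layout_path: str | Path,
    soil_path: str | Path | None = None,
    phenotype_path: str | Path | None = None,
    otu_path: str | Path | None = None,
) -> tuple[PlotGrid, SoilTable | None, PhenotypeTable | None, OTUTable | None]:
    """Read and cross-validate the study tables against the layout.

    Data tables referencing plots absent from the layout raise
    :class:`ReferentialError`; missing required columns raise
    :class:`SchemaError`.
    """
    layout = read_layout(layout_path)
    soil = read_soil(soil_path, layout) if soil_path is not None else None
    pheno = read_phenotypes(phenotype_path, layout) if phenotype_path is not None else None
    otu = read_otu_table(otu_path, layout) if otu_path is not None else None
    return layout, soil, pheno, otu


def filter_otu_table(
    t: OTUTable,
    min_sample_depth: float = 10_000,
    min_otu_total: float = 100,
    max_otu_total: float = 200_000,
) -> OTUTable:
    """Quality-control filter for raw OTU counts.

    Samples whose total count over all OTUs is strictly below
    ``min_sample_depth`` are dropped first; then OTUs whose grand total over
    the *retained* samples is strictly below ``min_otu_total`` or strictly
    above ``max_otu_total`` are dropped.  The operation is idempotent only in
    the typical case; re-filtering can drop further OTUs if removing deep
    samples lowered totals, so callers should filter once on raw counts.
    """
    depths = t.sample_depths
    keep_samples = depths >= min_sample_depth
    if not keep_samples.any():
        raise EmptyTableError(
            f"all {len(depths)} samples fall below min_sample_depth={min_sample_depth}"
        )
    samples = t.samples.loc[keep_samples.to_numpy()].reset_index(drop=True)
    counts = t.counts.loc[keep_samples]
    totals = counts.sum(axis=0)
    keep_otus = (totals >= min_otu_total) & (totals <= max_otu_total)
    return OTUTable(samples=samples, counts=counts.loc[:, keep_otus], layout=t.layout)


def scale_to_common_depth(t: OTUTable) -> OTUTable:
    """Proportionally rescale every sample to the maximum observed depth.

    Each sample's counts are multiplied by (max depth / its depth), so all
    sample totals equal the maximum total while within-sample proportions
    (and zeros) are preserved.  Scaled values are real numbers; downstream
    count models round their own copies.
    """
    depths = t.sample_depths
    if (depths <= 0).any():
        bad = depths.index[depths <= 0].tolist()
        raise EmptyTableError(f"sample(s) with zero total count cannot be scaled: {bad[:5]}")
    target = float(depths.max())
    scaled = t.counts.mul(target / depths, axis=0)
    return OTUTable(samples=t.samples, counts=scaled, layout=t.layout)
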