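"""Synthetic split-plot field studies with known spatial structure.

The generator emulates the layout of a sorghum drought trial: 24 genotypes
by 2 watering treatments (well-watered ``WW``, water-stressed ``WS``)
replicated in 8 blocks, i.e. a 16 x 24 grid of 384 plots.  Blocks are
vertical bands of columns; each block splits into two whole-plots (one per
treatment) and genotypes are randomized within whole-plots.

Soil properties are linear mixes of a few latent Gaussian random fields
(GRFs) simulated exactly from a variogram model, so groups of properties
share spatial structure and are mutually correlated, as real soil panels
are.  Phenotypes receive genotype, treatment, interaction and soil-gradient
effects plus iid noise; OTU counts are zero-inflated negative binomial with
log-means driven by the same latent gradients.  Every generating parameter
is kept in a truth record so downstream stages can be tested for parameter
recovery.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children, in the fixed stream order
(layout, latent, soil, phenotype, otu); adding consumers never perturbs
existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import OTUTable, PhenotypeTable, PlotGrid, SoilTable
from .variogram import VariogramModel

__all__ = [
    "PhenotypeSpec",
    "OTUSpec",
    "SimConfig",
    "simulate_grf",
    "make_layout",
    "simulate_field_study",
]

SOIL_PROPERTY_GROUPS: Mapping[str, int] = {
    # latent gradient index driving each property (cation block, salinity
    # block, nutrient block) -- mirrors typical soil-panel correlation blocks
    "calcium": 0,
    "magnesium": 0,
    "potassium": 0,
    "sodium": 0,
    "sum_cations": 0,
    "sulfate": 1,
    "salinity": 1,
    "ph": 1,
    "buffer_ph": 1,
    "phosphate": 2,
    "nitrate": 2,
    "organic_matter": 2,
}


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generating effects for one continuous trait.

    ``soil_coefs`` multiply the standardized latent gradients; the trait is
    intercept + genotype + treatment + interaction + soil term + N(0, noise_sd).
    """

    genotype_sd: float = 1.0
    treatment_effect: float = 2.0
    interaction_sd: float = 0.3
    soil_coefs: tuple[float, ...] = (1.0, 0.5, 0.0)
    noise_sd: float = 1.0
    intercept: float = 100.0


@dataclass(frozen=True)
class OTUSpec:
    """Generating parameters for the zero-inflated negative-binomial counts.

    ``coef_sd`` is the spread of per-OTU latent-gradient coefficients when
    explicit ``coefs`` are not supplied.  ``dispersion`` is the NB size
    parameter theta (var = mu + mu^2/theta); ``zero_inflation`` the
    structural-zero probability.
    """

    n_otus: int = 100
    compartments: tuple[str, ...] = ("root", "rhizosphere", "soil")
    baseline_log_mean: tuple[float, float] = (3.0, 6.0)
    coef_sd: float = 0.3
    coefs: np.ndarray | None = None
    compartment_effect_sd: float = 0.5
    zero_inflation: float = 0.2
    dispersion: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated split-plot field study."""

    rows: int = 16
    cols: int = 24
    n_blocks: int = 8
    n_genotypes: int = 24
    treatments: tuple[str, str] = ("WW", "WS")
    soil_properties: tuple[str, ...] = tuple(SOIL_PROPERTY_GROUPS)
    latent_models: tuple[VariogramModel, ...] = (
        VariogramModel("exponential", 0.1, 1.0, 4.0),
        VariogramModel("exponential", 0.1, 1.0, 4.0),
        VariogramModel("exponential", 0.1, 1.0, 4.0),
    )
    property_loading: float = 1.0
    property_noise_sd: float = 0.3
    property_center: float = 10.0
    soil_sample_step: int = 2
    phenotypes: Mapping[str, PhenotypeSpec] = field(
        default_factory=lambda: {"height": PhenotypeSpec()}
    )
    otu: OTUSpec | None = field(default_factory=OTUSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < self.n_blocks * 2 * self.n_genotypes:
            raise ValueError(
                "grid too small for n_blocks x 2 treatments x n_genotypes plots"
            )
        if self.cols % self.n_blocks != 0:
            raise ValueError("cols must be divisible by n_blocks (blocks are column bands)")
        for m in self.latent_models:
            if m.nugget < 0 or m.partial_sill < 0:
                raise ValueError("nugget and partial sill must be nonnegative")
        if self.otu is not None:
            if not (0.0 <= self.otu.zero_inflation < 1.0):
                raise ValueError("zero_inflation must be in [0, 1)")
            if self.otu.dispersion <= 0:
                raise ValueError("dispersion must be positive")


def simulate_grf(
    coords: np.ndarray,
    model: VariogramModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw one zero-mean Gaussian random field exactly at ``coords``.

    The covariance is C(h) = sill - gamma(h) from the variogram model, and
    the draw uses a dense Cholesky factorisation (exact at field scale).  A
    tiny escalating jitter keeps numerically semi-definite covariances
    (e.g. the gaussian family) factorisable; if jitter up to 1e-4 * sill
    fails, an error naming the model is raised.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    sill = model.sill
    if sill == 0.0:
        return np.zeros(n)
    from scipy.spatial.distance import pdist, squareform

    C = model.covariance(squareform(pdist(coords)))
    np.fill_diagonal(C, sill)
    z = rng.standard_normal(n)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            L = np.linalg.cholesky(C + jitter * sill * np.eye(n))
            return L @ z
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"covariance for {model.family} model (nugget={model.nugget}, "
        f"partial_sill={model.partial_sill}, range={model.range_}) is not "
        "positive semi-definite even after jitter"
    )


def make_layout(cfg: SimConfig, rng: np.random.Generator) -> PlotGrid:
    """Randomized split-plot layout on the grid.

    Blocks are contiguous column bands; each block's rows split into two
    whole-plots that receive the treatments in random order; genotypes are
    randomized within each whole-plot.
    """
    band = cfg.cols // cfg.n_blocks
    rows_half = cfg.rows // 2
    records = []
    for b in range(cfg.n_blocks):
        trt_order = list(cfg.treatments)
        rng.shuffle(trt_order)
        for w, trt in enumerate(trt_order):
            cells = [
                (r, c)
                for r in range(w * rows_half, (w + 1) * rows_half)
                for c in range(b * band, (b + 1) * band)
            ]
            genos = [f"G{g + 1:02d}" for g in range(cfg.n_genotypes)]
            rng.shuffle(genos)
            # pad with repeats when the whole-plot has spare cells
            while len(genos) < len(cells):
                genos.append(genos[len(genos) % cfg.n_genotypes])
            for (r, c), g in zip(cells, genos):
                records.append(
                    {
                        "plot_id": f"P{r:02d}_{c:02d}",
                        "row": r,
                        "col": c,
                        "block": f"B{b + 1}",
                        "treatment": trt,
                        "genotype": g,
                    }
                )
    return PlotGrid(pd.DataFrame.from_records(records))


def _zinb_draw(
    rng: np.random.Generator, mu: np.ndarray, theta: float, pi: float
) -> np.ndarray:
    """Zero-inflated NB via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    y = rng.poisson(lam)
    structural = rng.random(mu.shape) < pi
    y[structural] = 0
    return y


def simulate_field_study(cfg: SimConfig):
    """Generate (layout, soil, phenotypes, otu, truth) for one field study.

    The truth record holds the latent gradient values per plot (standardized,
    as used by every downstream effect), all generating coefficients, and
    the configuration, enabling parameter-recovery tests end to end.
    """
    root = np.random.SeedSequence(cfg.seed)
    kids = root.spawn(5)  # fixed stream order: layout, latent, soil, phenotype, otu
    rng_layout, rng_latent, rng_soil, rng_pheno, rng_otu = (
        np.random.default_rng(k) for k in kids
    )

    layout = make_layout(cfg, rng_layout)
    coords = layout.coords()
    n_plots = len(layout)
    n_latent = len(cfg.latent_models)

    latent = np.column_stack(
        [simulate_grf(coords, m, rng_latent) for m in cfg.latent_models]
    )
    latent_std = (latent - latent.mean(axis=0)) / latent.std(axis=0, ddof=0)

    # soil properties: one dominant latent gradient per property group
    soil = pd.DataFrame({"plot_id": layout.frame["plot_id"]})
    for prop in cfg.soil_properties:
        g = SOIL_PROPERTY_GROUPS.get(prop, 0) % n_latent
        vals = (
            cfg.property_center
            + cfg.property_loading * latent[:, g]
            + rng_soil.normal(0.0, cfg.property_noise_sd, n_plots)
        )
        soil[prop] = vals
    # sparse sampling mask: regular lattice, ~1/step^2 of plots sampled
    step = cfg.soil_sample_step
    sampled = (layout.frame["row"] % step == 0) & (layout.frame["col"] % step == 0)
    soil.loc[~sampled.to_numpy(), cfg.soil_properties] = np.nan

    # phenotypes
    geno_levels = sorted(layout.frame["genotype"].unique())
    trt_levels = list(cfg.treatments)
    pheno = pd.DataFrame({"plot_id": layout.frame["plot_id"]})
    pheno_truth = {}
    for trait, spec in cfg.phenotypes.items():
        geno_eff = dict(
            zip(geno_levels, rng_pheno.normal(0.0, spec.genotype_sd, len(geno_levels)))
        )
        trt_eff = {trt_levels[0]: 0.0, trt_levels[1]: -spec.treatment_effect}
        inter_eff = {
            (g, t): rng_pheno.normal(0.0, spec.interaction_sd)
            for g in geno_levels
            for t in trt_levels
        }
        coefs = np.asarray(spec.soil_coefs, dtype=float)[:n_latent]
        soil_term = latent_std[:, : len(coefs)] @ coefs
        y = (
            spec.intercept
            + layout.frame["genotype"].map(geno_eff).to_numpy()
            + layout.frame["treatment"].map(trt_eff).to_numpy()
            + np.array(
                [
                    inter_eff[(g, t)]
                    for g, t in zip(layout.frame["genotype"], layout.frame["treatment"])
                ]
            )
            + soil_term
            + rng_pheno.normal(0.0, spec.noise_sd, n_plots)
        )
        pheno[trait] = y
        pheno_truth[trait] = {
            "genotype_effects": geno_eff,
            "treatment_effects": trt_eff,
            "soil_coefs": coefs.tolist(),
            "spec": spec,
        }

    # OTU counts
    otu_table = None
    otu_truth = None
    if cfg.otu is not None:
        o = cfg.otu
        if o.coefs is not None:
            B = np.asarray(o.coefs, dtype=float)
            if B.shape != (o.n_otus, n_latent):
                raise ValueError("otu.coefs must have shape (n_otus, n_latent)")
        else:
            B = rng_otu.normal(0.0, o.coef_sd, (o.n_otus, n_latent))
        base = rng_otu.uniform(*o.baseline_log_mean, o.n_otus)
        comp_eff = rng_otu.normal(0.0, o.compartment_effect_sd, (len(o.compartments), o.n_otus))
        metas, blocks_of_counts = [], []
        for ci, comp in enumerate(o.compartments):
            log_mu = base[None, :] + comp_eff[ci][None, :] + latent_std @ B.T
            mu = np.exp(log_mu)
            counts = _zinb_draw(rng_otu, mu, o.dispersion, o.zero_inflation)
            metas.append(
                pd.DataFrame(
                    {
                        "sample_id": [
                            f"S_{comp}_{pid}" for pid in layout.frame["plot_id"]
                        ],
                        "plot_id": layout.frame["plot_id"],
                        "compartment": comp,
                    }
                )
            )
            blocks_of_counts.append(counts)
        samples = pd.concat(metas, ignore_index=True)
        counts = pd.DataFrame(
            np.vstack(blocks_of_counts),
            index=samples["sample_id"],
            columns=[f"OTU{j + 1:04d}" for j in range(o.n_otus)],
        )
        otu_table = OTUTable(samples=samples, counts=counts, layout=layout)
        otu_truth = {"coefs": B, "baseline_log_mean": base, "spec": o}

    truth = {
        "config": cfg,
        "latent": pd.DataFrame(
            latent_std,
            index=layout.frame["plot_id"],
            columns=[f"latent{j + 1}" for j in range(n_latent)],
        ),
        "latent_raw": latent,
        "phenotypes": pheno_truth,
        "otu": otu_truth,
    }
    return (
        layout,
        SoilTable(soil, layout=layout),
        PhenotypeTable(pheno, layout=layout),
        otu_table,
        truth,
    )
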