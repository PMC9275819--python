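"""Association tests between soil gradients and responses.

Two complementary testing routes, mirroring the response types of a field
microbiome study:

* multivariate (community composition): a Canberra distance matrix is
  embedded by principal-coordinate analysis and a *constrained* permutation
  ANOVA (distance-based redundancy analysis) tests one term — typically a
  kriged soil property — after conditioning on the experimental design,
  with a permutation p-value;
* univariate (a single trait): a linear mixed model with the full design,
  the kriged property, and a spatial random structure nested within blocks,
  tested by a single-df type-III Wald chi-square for the property.

A design partial-R^2 decomposition quantifies how much of the (possibly
multivariate) response each design term explains with all other terms
included; comparing it before and after soil adjustment measures the gain
in design resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import patsy
from scipy.spatial.distance import pdist, squareform

from .core import PlotGrid
from .spatial_lmm import fit_iid, fit_spatial_gls

__all__ = [
    "AssociationResult",
    "canberra_distance",
    "pcoa_embedding",
    "constrained_permanova",
    "type3_property_test",
    "design_partial_r2",
]

DESIGN_TERMS = (
    "C(treatment, Sum)",
    "C(genotype, Sum)",
    "C(treatment, Sum):C(genotype, Sum)",
)


@dataclass(frozen=True)
class AssociationResult:
    """One tested term: statistic, p-value and testing context."""

    term: str
    statistic: float
    p_value: float
    statistic_name: str = "pseudo-F"
    n_perm: int | None = None
    df: tuple[int, int] | None = None
    conditioned_on: tuple[str, ...] = ()
    extra: dict = dc_field(default_factory=dict)


def canberra_distance(m: np.ndarray) -> np.ndarray:
    """Pairwise Canberra distances between rows of a nonnegative matrix.

    d(x, y) = sum_k |x_k - y_k| / (x_k + y_k) over features where
    x_k + y_k > 0; 0/0 terms contribute nothing.  Returns a dense symmetric
    matrix with zero diagonal.
    """
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("Canberra distance requires nonnegative entries")
    # scipy's canberra sums |x-y|/(|x|+|y|) and treats 0/0 as 0: identical
    # to skipping the term for nonnegative data.
    return squareform(pdist(m, metric="canberra"))


def pcoa_embedding(d: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, dict]:
    """Principal-coordinate embedding of a distance matrix.

    Eigendecomposes the Gower-centered matrix -0.5 J D^2 J and keeps the
    axes with positive eigenvalues; for semimetric distances (Canberra
    included) negative-eigenvalue axes are dropped with a warning and their
    summed inertia reported in the info dict.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d**2) @ J
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), 1.0)
    pos = evals > tol * scale
    neg_inertia = float(-evals[evals < -tol * scale].sum())
    if neg_inertia > 0:
        warnings.warn(
            f"dropping negative-eigenvalue axes (summed negative inertia "
            f"{neg_inertia:.4g})"
        )
    Y = evecs[:, pos] * np.sqrt(evals[pos])
    return Y, {"eigenvalues": evals, "negative_inertia": neg_inertia}


def _hat_basis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing)."""
    if X.size == 0:
        return np.zeros((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > tol * s[0]).sum()) if s.size else 0
    return U[:, :rank]


def constrained_permanova(
    d: np.ndarray,
    data: pd.DataFrame,
    test_term: str,
    condition_terms: tuple[str, ...] | list[str] = (),
    n_perm: int = 999,
    seed: int = 0,
    permute_within: str | None = None,
) -> AssociationResult:
    """Permutation ANOVA of one term on a distance matrix, conditioned on others.

    The distance matrix is embedded by PCoA; both the embedding and the test
    design column(s) are residualized on the condition terms (plus an
    intercept); the pseudo-F compares the test term's explained sum of
    squares to the residual.  Significance comes from freely permuting the
    reduced-model residual rows (``permute_within`` restricts permutations
    to stay inside a grouping column), with

        p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    ``test_term`` and ``condition_terms`` are patsy formula terms evaluated
    against ``data`` (one row per object of ``d``).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if len(data) != n:
        raise ValueError("data must have one row per distance-matrix object")
    Y, info = pcoa_embedding(d)

    cond_formula = "1" if not condition_terms else "1 + " + " + ".join(condition_terms)
    Xc = np.asarray(patsy.dmatrix(cond_formula, data), dtype=float)
    Xt = np.asarray(patsy.dmatrix(f"0 + {test_term}", data), dtype=float)

    Qc = _hat_basis(Xc)
    R = Y - Qc @ (Qc.T @ Y)
    Xt_res = Xt - Qc @ (Qc.T @ Xt)
    # rank relative to the scale of the *unresidualized* test columns, so a
    # term fully absorbed by the conditions is detected as collinear
    scale = np.linalg.norm(Xt, 2)
    U, s, _ = np.linalg.svd(Xt_res, full_matrices=False)
    df_t = int((s > 1e-8 * max(scale, 1e-300)).sum())
    if df_t == 0:
        raise ValueError(
            f"test term {test_term!r} is collinear with the condition terms"
        )
    Qt = U[:, :df_t]
    df_res = n - Qc.shape[1] - df_t
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ss_total = float((R**2).sum())
    ss_test = float(((Qt.T @ R) ** 2).sum())
    ss_res = ss_total - ss_test
    f_obs = (ss_test / df_t) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    if permute_within is not None:
        groups = data[permute_within].to_numpy()
        group_idx = [np.flatnonzero(groups == g) for g in pd.unique(groups)]

    count_ge = 0
    for _ in range(n_perm):
        if permute_within is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for idx in group_idx:
                perm[idx] = idx[rng.permutation(len(idx))]
        Rp = R[perm]
        # Freedman-Lane: re-residualize the permuted residuals on the
        # conditions, so the permuted total excludes what the reduced model
        # reabsorbs (Qt is already orthogonal to the condition space)
        ss_t = float(((Qt.T @ Rp) ** 2).sum())
        ss_c = float(((Qc.T @ Rp) ** 2).sum())
        f_p = (ss_t / df_t) / ((ss_total - ss_c - ss_t) / df_res)
        if f_p >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return AssociationResult(
        term=test_term,
        statistic=float(f_obs),
        p_value=float(p),
        statistic_name="pseudo-F",
        n_perm=n_perm,
        df=(df_t, df_res),
        conditioned_on=tuple(condition_terms),
        extra={"negative_inertia": info["negative_inertia"], "ss_test": ss_test,
               "ss_res": ss_res, "r2": ss_test / ss_total},
    )


def type3_property_test(
    y: np.ndarray,
    prop_krig: np.ndarray,
    layout: PlotGrid,
    structure: str = "exponential",
) -> AssociationResult:
    """Type-III Wald chi-square for a kriged property in the design mixed model.

    Model: y = design (sum-to-zero treatment, genotype, interaction)
    + beta * property_krig + spatial error nested within blocks.  With
    sum-to-zero contrasts the single-df Wald chi-square on beta equals the
    type-III test for the property.  Falls back to a fixed-effects (iid)
    fit with a warning when the spatial fit cannot be computed.
    """
    y = np.asarray(y, dtype=float)
    prop_krig = np.asarray(prop_krig, dtype=float)
    frame = layout.frame
    if len(y) != len(frame) or len(prop_krig) != len(frame):
        raise ValueError("y and prop_krig must align with the layout")
    X_design = np.asarray(
        patsy.dmatrix("1 + " + " + ".join(DESIGN_TERMS), frame), dtype=float
    )
    X = np.column_stack([X_design, prop_krig])
    idx = X.shape[1] - 1
    try:
        fit = fit_spatial_gls(
            y, X, layout.coords(), blocks=frame["block"].to_numpy(), structure=structure
        )
    except Exception as exc:
        warnings.warn(f"spatial fit failed ({exc}); falling back to fixed effects")
        fit = fit_iid(y, X)
    stat, p = fit.wald_chi2(idx)
    return AssociationResult(
        term="property_krig",
        statistic=stat,
        p_value=p,
        statistic_name="wald-chi2",
        df=(1, fit.n - fit.rank),
        conditioned_on=("treatment", "genotype", "treatment:genotype"),
        extra={"beta": float(fit.beta[idx]), "structure": fit.structure,
               "phi": fit.phi, "nugget_frac": fit.nugget_frac},
    )


def design_partial_r2(
    response: np.ndarray,
    layout: PlotGrid,
    terms: tuple[str, ...] = ("treatment", "genotype", "treatment:genotype"),
) -> dict[str, float]:
    """Per-term partial R^2 of the experimental design.

    ``response`` is either a 1-D trait vector (linear model) or a square
    distance matrix (distance-based, via PCoA embedding).  For each design
    term, partial R^2 = SS_term / SS_total where SS_term is the drop in
    residual sum of squares when the term is added last to a model holding
    all other design terms.
    """
    response = np.asarray(response, dtype=float)
    frame = layout.frame
    if response.ndim == 2 and response.shape[0] == response.shape[1]:
        Y, _ = pcoa_embedding(response)
    elif response.ndim == 1:
        if len(response) != len(frame):
            raise ValueError("response must align with the layout")
        Y = response[:, None] - response.mean()
    else:
        raise ValueError("response must be a vector or a square distance matrix")

    term_formula = {
        "treatment": "C(treatment, Sum)",
        "genotype": "C(genotype, Sum)",
        "treatment:genotype": "C(treatment, Sum):C(genotype, Sum)",
    }
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())

    # build the full sum-to-zero design once and drop term columns by slice,
    # so reduced models cannot re-span a dropped term through recoded
    # interaction contrasts
    dm = patsy.dmatrix("1 + " + " + ".join(term_formula[t] for t in terms), frame)
    X_full = np.asarray(dm, dtype=float)
    slices = {}
    for t in terms:
        name = [n for n in dm.design_info.term_names
                if n.replace(" ", "") == term_formula[t].replace(" ", "")][0]
        slices[t] = dm.design_info.term_name_slices[name]

    def rss(X: np.ndarray) -> float:
        Q = _hat_basis(X)
        return float((Y**2).sum() - ((Q.T @ Y) ** 2).sum())

    rss_full = rss(X_full)
    out = {}
    for t in terms:
        keep = np.ones(X_full.shape[1], dtype=bool)
        keep[slices[t]] = False
        out[t] = max(rss(X_full[:, keep]) - rss_full, 0.0) / ss_total
    return out
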