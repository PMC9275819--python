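"""Canberra distances, constrained PERMANOVA (with exhaustive and external
oracles), the type-III mixed-model property test, and design partial R^2."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fieldkrige.association import (
    canberra_distance,
    constrained_permanova,
    design_partial_r2,
    pcoa_embedding,
    type3_property_test,
)
from fieldkrige.core import PlotGrid


class TestCanberra:
    def test_identity_and_hand_value(self):
        x = np.array([[1.0, 2.0, 0.0]])
        assert canberra_distance(np.vstack([x, x]))[0, 1] == 0.0
        d = canberra_distance(np.array([[1.0], [3.0]]))
        assert np.isclose(d[0, 1], 0.5)

    def test_zero_zero_features_skipped(self):
        d = canberra_distance(np.array([[0.0, 1.0], [0.0, 3.0]]))
        assert np.isclose(d[0, 1], 0.5)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            canberra_distance(np.array([[1.0, -0.5]]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_symmetric_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0, 5, (6, 4))
        m[rng.random((6, 4)) < 0.3] = 0.0
        d = canberra_distance(m)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestConstrainedPermanova:
    def test_matches_external_permanova_on_metric_distances(self):
        # unconditioned one-factor case equals the classical PERMANOVA
        # pseudo-F computed by scikit-bio straight from the distances
        from skbio.stats.distance import DistanceMatrix, permanova
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(0)
        grp = np.repeat(["a", "b", "c"], 8)
        X = rng.normal(size=(24, 5))
        X[grp == "b"] += 0.7
        d = squareform(pdist(X))
        mine = constrained_permanova(d, pd.DataFrame({"grp": grp}), "C(grp)",
                                     n_perm=499, seed=3)
        ref = permanova(DistanceMatrix(d), grp, permutations=499)
        assert np.isclose(mine.statistic, ref["test statistic"], atol=1e-8)
        assert abs(mine.p_value - ref["p-value"]) < 0.05

    def test_scale_invariance_of_pseudo_f(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 4, (18, 6))
        d = canberra_distance(X)
        data = pd.DataFrame({"g": np.repeat(["u", "v", "w"], 6)})
        a = constrained_permanova(d, data, "C(g)", n_perm=99, seed=0)
        b = constrained_permanova(3.7 * d, data, "C(g)", n_perm=99, seed=0)
        assert np.isclose(a.statistic, b.statistic)
        assert a.p_value == b.p_value  # bit-reproducible given the seed

    def test_p_floor_under_strong_effect(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 40)
        Y = np.outer(x, np.ones(4)) + rng.normal(0, 0.01, (40, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(Y))
        r = constrained_permanova(d, pd.DataFrame({"x": x}), "x",
                                  n_perm=999, seed=0)
        assert r.p_value == 1.0 / 1000.0

    def test_matches_exhaustive_enumeration_small_n(self):
        # n = 6: compare the sampled permutation p with the exact one from
        # enumerating all 720 relabelings of the residual rows
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3))
        X[3:] += 1.2
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(X))
        data = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3})
        r = constrained_permanova(d, data, "C(g)", n_perm=999, seed=5)
        Y, _ = pcoa_embedding(d)
        R = Y - Y.mean(axis=0)
        import patsy

        Xt = np.asarray(patsy.dmatrix("0 + C(g)", data), float)
        Xt = Xt - Xt.mean(axis=0)
        U, s, _ = np.linalg.svd(Xt, full_matrices=False)
        Q = U[:, s > 1e-10]
        df_t, df_res = Q.shape[1], 6 - 1 - Q.shape[1]
        sst = (R**2).sum()

        def f_of(perm):
            Rp = R[list(perm)]
            ss = ((Q.T @ Rp) ** 2).sum()
            return (ss / df_t) / ((sst - ss) / df_res)

        f_obs = f_of(range(6))
        fs = np.array([f_of(p) for p in itertools.permutations(range(6))])
        exact_p = (fs >= f_obs - 1e-12).mean()
        assert np.isclose(r.statistic, f_obs)
        assert abs(r.p_value - exact_p) < 0.08

    def test_collinear_test_term_rejected(self):
        d = canberra_distance(np.random.default_rng(0).uniform(1, 2, (12, 3)))
        data = pd.DataFrame({"g": np.repeat(["a", "b"], 6)})
        with pytest.raises(ValueError, match="collinear"):
            constrained_permanova(d, data, "C(g)", condition_terms=("C(g)",))

    def test_type_one_error_near_nominal(self):
        # exchangeable null: rejection rate at alpha=0.05 stays near nominal
        rng = np.random.default_rng(7)
        rejections = 0
        n_sims = 60
        for _ in range(n_sims):
            X = rng.uniform(0, 3, (20, 4))
            d = canberra_distance(X)
            data = pd.DataFrame({"g": rng.permutation(np.repeat(["a", "b"], 10))})
            r = constrained_permanova(d, data, "C(g)", n_perm=99,
                                      seed=int(rng.integers(2**31)))
            rejections += r.p_value <= 0.05
        assert rejections / n_sims < 0.15


def _layout_for_assoc(n_geno=4, n_blocks=2, cols=8):
    """Deterministic balanced 2-treatment layout on a grid."""
    records = []
    i = 0
    for b in range(n_blocks):
        for w, trt in enumerate(["WW", "WS"]):
            for k in range(n_geno):
                r, c = divmod(i, cols)
                records.append({"plot_id": f"p{i}", "row": r, "col": c,
                                "block": f"B{b+1}", "treatment": trt,
                                "genotype": f"G{k+1}"})
                i += 1
    return PlotGrid(pd.DataFrame(records))


class TestType3PropertyTest:
    def test_perfect_signal_detected(self):
        layout = _layout_for_assoc(n_geno=6, n_blocks=4)
        rng = np.random.default_rng(0)
        prop = rng.normal(size=len(layout))
        geno_eff = layout.frame["genotype"].map(
            {f"G{i+1}": i * 0.5 for i in range(6)}
        ).to_numpy()
        y = geno_eff + 2.0 * prop + rng.normal(0, 1e-8, len(layout))
        r = type3_property_test(y, prop, layout)
        assert r.p_value < 1e-6

    def test_chi2_equals_squared_wald_z(self):
        layout = _layout_for_assoc(n_geno=6, n_blocks=4)
        rng = np.random.default_rng(1)
        prop = rng.normal(size=len(layout))
        y = rng.normal(size=len(layout)) + 0.5 * prop
        r = type3_property_test(y, prop, layout)
        z2 = r.extra["beta"] ** 2
        # statistic = (beta/se)^2, so beta^2 / statistic = se^2 > 0
        assert r.statistic > 0
        assert z2 / r.statistic > 0

    def test_null_p_values_roughly_uniform(self):
        from scipy.stats import kstest

        layout = _layout_for_assoc(n_geno=6, n_blocks=4)
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(80):
            prop = rng.normal(size=len(layout))
            y = rng.normal(size=len(layout))
            pvals.append(type3_property_test(y, prop, layout).p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestDesignPartialR2:
    def test_pure_genotype_signal(self):
        layout = _layout_for_assoc(n_geno=4, n_blocks=4)
        y = layout.frame["genotype"].map(
            {"G1": 0.0, "G2": 1.0, "G3": 2.0, "G4": 3.0}
        ).to_numpy()
        r2 = design_partial_r2(y, layout)
        assert r2["genotype"] > 0.99
        assert r2["treatment"] < 1e-8
        assert r2["treatment:genotype"] < 1e-8

    def test_terms_bounded_by_total(self):
        layout = _layout_for_assoc(n_geno=4, n_blocks=4)
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(layout))
        r2 = design_partial_r2(y, layout)
        assert sum(r2.values()) <= 1.0 + 1e-10

    def test_univariate_matches_hand_anova_2x3(self):
        records = []
        i = 0
        for rep in range(4):
            for t in ["WW", "WS"]:
                for g in ["G1", "G2", "G3"]:
                    r, c = divmod(i, 6)
                    records.append({"plot_id": f"p{i}", "row": r, "col": c,
                                    "block": f"B{rep+1}", "treatment": t,
                                    "genotype": g})
                    i += 1
        layout = PlotGrid(pd.DataFrame(records))
        rng = np.random.default_rng(4)
        y = rng.normal(size=24)
        r2 = design_partial_r2(y, layout)
        # hand ANOVA: balanced design, marginal SS equals classical SS
        df = layout.frame.assign(y=y)
        grand = y.mean()
        sst = ((y - grand) ** 2).sum()
        ss_t = sum(
            len(sub) * (sub["y"].mean() - grand) ** 2
            for _, sub in df.groupby("treatment")
        )
        ss_g = sum(
            len(sub) * (sub["y"].mean() - grand) ** 2
            for _, sub in df.groupby("genotype")
        )
        assert np.isclose(r2["treatment"], ss_t / sst, atol=1e-8)
        assert np.isclose(r2["genotype"], ss_g / sst, atol=1e-8)

    def test_multivariate_distance_input(self):
        layout = _layout_for_assoc(n_geno=4, n_blocks=4)
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 2, (len(layout), 5))
        X[layout.frame["treatment"] == "WS"] += 2.0
        d = canberra_distance(X)
        r2 = design_partial_r2(d, layout)
        assert r2["treatment"] > r2["genotype"]
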