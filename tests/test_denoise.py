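"""PCA of soil residuals, PC selection, kriged scores, and the PC-regression
adjustments for continuous traits and counts."""

import numpy as np
import pandas as pd
import pytest

from fieldkrige.core import OTUTable, SoilTable
from fieldkrige.denoise import (
    PCModel,
    adjust_counts_from_coefs,
    krige_pc_scores,
    pca_residual_soil,
    pcr_adjust_continuous,
    pcr_adjust_counts,
    property_contributions,
    select_pcs,
)
from fieldkrige.residualize import ResidualTable
from fieldkrige.synthetic import OTUSpec, SimConfig, simulate_field_study


def _residual_table(df: pd.DataFrame) -> ResidualTable:
    return ResidualTable(residuals=df, fitted=df.copy())


def _random_resid(n_plots=30, n_props=4, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n_plots, n_props)),
                      columns=[f"prop{j}" for j in range(n_props)])
    df.insert(0, "plot_id", [f"p{i}" for i in range(n_plots)])
    return _residual_table(df)


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_pc1(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        df = pd.DataFrame({"plot_id": [f"p{i}" for i in range(20)],
                           "x": a, "y": 3.0 * a + 1.0})
        p = pca_residual_soil(_residual_table(df))
        assert np.isclose(p.percent_variance[0], 100.0)
        contrib = property_contributions(p, 0)
        assert np.allclose(contrib.to_numpy(), [50.0, 50.0])

    def test_percent_variance_sums_to_100(self):
        p = pca_residual_soil(_random_resid())
        assert abs(p.percent_variance.sum() - 100.0) < 1e-6

    def test_eigenvalues_match_covariance_eigendecomposition(self):
        r = _random_resid(n_plots=5, n_props=4, seed=9)
        p = pca_residual_soil(r)
        X = r.residuals[p.loadings.index].to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
        sv = np.sort(p.percent_variance)[::-1]
        assert np.allclose(100 * evals / evals.sum(), sv, atol=1e-8)

    def test_scores_reproduce_scaled_input_with_all_components(self):
        r = _random_resid(seed=3)
        p = pca_residual_soil(r)
        X = r.residuals[p.loadings.index].to_numpy()
        Z = (X - p.center.to_numpy()) / p.scale.to_numpy()
        recon = p.scores.to_numpy() @ p.loadings.to_numpy().T
        assert np.allclose(recon, Z, atol=1e-8)
        # orthonormal loadings
        L = p.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_constant_property_rejected_by_name(self):
        df = pd.DataFrame({"plot_id": ["a", "b", "c"],
                           "flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            pca_residual_soil(_residual_table(df))


class TestSelectPCs:
    def test_threshold_rule(self):
        p = _pc_with_percents([40, 26, 11, 9, 8, 6])
        assert select_pcs(p, n_blocks=8) == [0, 1, 2]

    def test_cap_at_blocks_minus_three(self):
        p = _pc_with_percents([60, 15, 12, 11, 10.5, 10.2])
        assert select_pcs(p, n_blocks=8) == [0, 1, 2, 3, 4]

    def test_empty_selection(self):
        p = _pc_with_percents([9, 8, 7])
        assert select_pcs(p, n_blocks=8) == []

    def test_needs_four_blocks(self):
        with pytest.raises(ValueError):
            select_pcs(_pc_with_percents([50, 50]), n_blocks=3)


def _pc_with_percents(pcts):
    k = len(pcts)
    eye = np.eye(k)
    names = [f"PC{i+1}" for i in range(k)]
    props = [f"prop{i}" for i in range(k)]
    return PCModel(
        loadings=pd.DataFrame(eye, index=props, columns=names),
        scores=pd.DataFrame(np.zeros((k, k)), index=props, columns=names),
        percent_variance=np.asarray(pcts, dtype=float),
        center=pd.Series(np.zeros(k), index=props),
        scale=pd.Series(np.ones(k), index=props),
    )


class TestContributions:
    def test_sum_to_100_and_match_squared_loadings(self):
        p = pca_residual_soil(_random_resid(n_props=6, seed=12))
        for k in range(3):
            c = property_contributions(p, k)
            assert abs(c.sum() - 100.0) < 1e-8
            assert np.allclose(c.to_numpy(),
                               100 * p.loadings.iloc[:, k].to_numpy() ** 2)

    def test_bad_index(self):
        p = pca_residual_soil(_random_resid())
        with pytest.raises(IndexError):
            property_contributions(p, 99)


class TestKrigePCScores:
    @pytest.fixture(scope="class")
    @staticmethod
    def field():
        cfg = SimConfig(seed=17, otu=None)
        layout, soil, pheno, _, truth = simulate_field_study(cfg)
        from fieldkrige.residualize import residualize
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = residualize(soil, layout)
        return layout, res

    def test_sampled_plots_keep_observed_scores(self, field):
        layout, res = field
        p = pca_residual_soil(res)
        pcs, models = krige_pc_scores(p, layout, components=[0])
        got = pcs.set_index("plot_id").loc[p.scores.index, "PC1_krig"]
        assert np.abs(got.to_numpy() - p.scores["PC1"].to_numpy()).max() < 1e-6

    def test_deterministic(self, field):
        layout, res = field
        p = pca_residual_soil(res)
        a, _ = krige_pc_scores(p, layout, components=[0, 1])
        b, _ = krige_pc_scores(p, layout, components=[0, 1])
        pd.testing.assert_frame_equal(a, b)


class TestAdjustContinuous:
    @pytest.fixture(scope="class")
    @staticmethod
    def layout_and_pcs():
        cfg = SimConfig(seed=23, otu=None, soil_sample_step=1)
        layout, soil, pheno, _, truth = simulate_field_study(cfg)
        from fieldkrige.residualize import residualize

        res = residualize(soil, layout)
        pcm = pca_residual_soil(res)
        pcs, _ = krige_pc_scores(pcm, layout, components=[0, 1, 2])
        return layout, pcs

    def test_exact_linear_function_of_pc_gives_constant_adjusted(self, layout_and_pcs):
        layout, pcs = layout_and_pcs
        y = 5.0 + 2.0 * pcs["PC1_krig"].to_numpy()
        adj = pcr_adjust_continuous(y, pcs[["plot_id", "PC1_krig"]], layout)
        assert np.abs(adj.frame["adjusted"].to_numpy() - 5.0).max() < 1e-4

    def test_change_identity(self, layout_and_pcs):
        layout, pcs = layout_and_pcs
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(layout)) + pcs["PC2_krig"].to_numpy()
        adj = pcr_adjust_continuous(y, pcs, layout)
        names = [c for c in pcs.columns if c != "plot_id"]
        P = pcs[names].to_numpy()
        beta = np.array([adj.coefficients[n] for n in names])
        assert np.allclose(adj.frame["change"].to_numpy(), -(P @ beta), atol=1e-10)
        lo, hi = adj.change_interval
        frac_outside = adj.frame["outside_interval"].mean()
        assert frac_outside <= 0.06

    def test_idempotent_readjustment(self, layout_and_pcs):
        layout, pcs = layout_and_pcs
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(layout)) + 2.0 * pcs["PC1_krig"].to_numpy()
        adj1 = pcr_adjust_continuous(y, pcs, layout)
        adj2 = pcr_adjust_continuous(adj1.frame["adjusted"].to_numpy(), pcs, layout)
        names = [c for c in pcs.columns if c != "plot_id"]
        second_pass = np.array([adj2.coefficients[n] for n in names])
        assert np.abs(second_pass).max() < 0.05


class TestAdjustCounts:
    def test_identity_and_monotonicity_of_backtransform(self):
        observed = np.array([0.0, 3.0, 10.0, 250.0])
        P = np.array([[0.0], [1.0], [-1.0], [2.0]])
        assert np.array_equal(
            adjust_counts_from_coefs(observed, P, np.array([0.0])), observed
        )
        adj = adjust_counts_from_coefs(observed, P, np.array([0.5]))
        assert adj[0] == 0.0  # zeros preserved
        assert adj[1] < observed[1]  # positive predictor shrinks
        assert adj[2] > observed[2]  # negative predictor grows
        lit = adjust_counts_from_coefs(observed, P, np.array([0.5]),
                                       literal_constant=True)
        assert np.allclose(lit, observed / np.exp(0.5))

    def test_zinb_adjustment_preserves_zeros_and_positivity(self):
        coefs = np.zeros((8, 3))
        coefs[:, 0] = 1.0
        cfg = SimConfig(
            seed=29, soil_sample_step=1,
            otu=OTUSpec(n_otus=8, compartments=("soil",), coefs=coefs,
                        zero_inflation=0.3),
        )
        layout, soil, pheno, otu, truth = simulate_field_study(cfg)
        lat = truth["latent"].reset_index()
        lat.columns = ["plot_id", "L1_krig", "L2_krig", "L3_krig"]
        result = pcr_adjust_counts(otu, lat, layout)
        assert result.retention["soil"]["attempted"] >= 1
        adj = result.table.counts
        obs = otu.counts.loc[adj.index, adj.columns]
        assert ((obs.to_numpy() == 0) == (adj.to_numpy() == 0)).all()
        assert (adj.to_numpy()[obs.to_numpy() > 0] > 0).all()
        # coefficients should point in the planted direction
        assert result.coefficients["L1_krig"].median() > 0.3
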