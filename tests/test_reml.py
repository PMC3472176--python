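"""REML engine against closed-form, grid-search and invariance oracles."""

import numpy as np
import pytest

import gvarpart as gv
from gvarpart.errors import InputError
from gvarpart.relmatrix import RelationshipMatrix
from gvarpart.reml import VarianceComponentModel


def balanced_oneway(a=8, r=5, sa2=40.0, se2=10.0, seed=3):
    """Balanced one-way random-effects data: y_ij = mu + u_i + e_ij."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(a) * np.sqrt(sa2)
    e = rng.standard_normal((a, r)) * np.sqrt(se2)
    y = (10.0 + u[:, None] + e).ravel()
    groups = np.repeat(np.arange(a), r)
    return y, groups, a, r


def anova_reml(y, groups, a, r):
    """Closed-form REML for the balanced one-way layout.

    With balanced data REML equals the ANOVA estimators:
    sigma_e^2 = MSE, sigma_a^2 = (MSA - MSE) / r.
    """
    means = np.array([y[groups == i].mean() for i in range(a)])
    grand = y.mean()
    msa = r * np.sum((means - grand) ** 2) / (a - 1)
    mse = sum(np.sum((y[groups == i] - means[i]) ** 2) for i in range(a)) / (a * (r - 1))
    return (msa - mse) / r, mse


class TestRestrictedLoglik:
    def test_profile_maximum_at_anova_estimates(self):
        """The likelihood surface peaks at the closed-form balanced-ANOVA REML."""
        y, groups, a, r = balanced_oneway()
        K = RelationshipMatrix(list(range(a)), np.eye(a))
        model = VarianceComponentModel(y, {"u": K}, ids=list(groups))
        sa2_hat, se2_hat = anova_reml(y, groups, a, r)
        best = gv.restricted_loglik(model, [sa2_hat, se2_hat])
        for f1 in (0.8, 0.95, 1.05, 1.25):
            for f2 in (0.8, 0.95, 1.05, 1.25):
                if f1 == 1.0 and f2 == 1.0:
                    continue
                assert gv.restricted_loglik(model, [sa2_hat * f1, se2_hat * f2]) <= best

    def test_null_variance_reduces_to_weighted_least_squares(self):
        rng = np.random.default_rng(1)
        n = 12
        y = rng.standard_normal(n)
        w = rng.uniform(0.5, 2.0, n)
        model = VarianceComponentModel(y, {"g": np.eye(n)}, weights=w)
        ll = gv.restricted_loglik(model, [0.0, 2.0])
        # direct weighted GLS restricted likelihood with V = 2 * diag(1/w)
        V = np.diag(2.0 / w)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        XtViX = (X.T @ Vi @ X).item()
        beta = (X.T @ Vi @ y).item() / XtViX
        resid = y - beta
        expected = -0.5 * (np.log(np.linalg.det(V)) + np.log(XtViX)
                           + float(resid @ Vi @ resid))
        # contrast-space value differs only by the constant -0.5*log(X'X)
        assert ll == pytest.approx(expected + 0.5 * np.log(n), rel=1e-10)

    def test_scale_change_shifts_loglik_by_nstar_logc(self):
        rng = np.random.default_rng(4)
        n, c = 10, 3.7
        y = rng.standard_normal(n) * 2 + 5
        K = rng.standard_normal((n, n))
        K = K @ K.T / n + np.eye(n)
        m1 = VarianceComponentModel(y, {"g": K})
        m2 = VarianceComponentModel(c * y, {"g": K})
        v = np.array([1.3, 0.7])
        ll1 = m1.loglike(v)
        ll2 = m2.loglike(v * c ** 2)
        assert ll2 - ll1 == pytest.approx(-(n - 1) * np.log(c), rel=1e-9)


class TestRemlFit:
    def test_balanced_anova_equivalence(self):
        y, groups, a, r = balanced_oneway(a=10, r=6, seed=8)
        K = RelationshipMatrix(list(range(a)), np.eye(a))
        res = VarianceComponentModel(y, {"u": K}, ids=list(groups)).fit(tol=1e-12)
        sa2_hat, se2_hat = anova_reml(y, groups, a, r)
        assert res.converged
        assert res.params["u"] == pytest.approx(sa2_hat, rel=1e-6)
        assert res.params["residual"] == pytest.approx(se2_hat, rel=1e-6)

    def test_grid_search_oracle_small_instance(self):
        """Optimum agrees with a dense 200x200 grid of the restricted likelihood."""
        c = gv.SimConfig(n_founders=8, n_generations=1, sires_per_generation=2,
                         offspring_per_sire=6, phenotype_cohort="all",
                         n_chromosomes=2, markers_per_chromosome=60, n_qtl=30,
                         var_polygenic=0.0, var_genomic=10.0, var_residual=5.0,
                         weight_low=1.0, weight_high=1.0, seed=42)
        sim = gv.simulate_dataset(c)
        G = gv.build_G(sim.genotypes.select_individuals(list(sim.phenotypes["id"])))
        model = VarianceComponentModel(sim.phenotypes["y"].to_numpy(), {"g": G},
                                       ids=list(sim.phenotypes["id"]))
        res = model.fit()
        g_grid = np.linspace(0.5, 40, 200)
        e_grid = np.linspace(0.5, 40, 200)
        ll = np.array([[model.loglike([g, e]) for e in e_grid] for g in g_grid])
        gi, ei = np.unravel_index(np.argmax(ll), ll.shape)
        cell_g = g_grid[1] - g_grid[0]
        cell_e = e_grid[1] - e_grid[0]
        assert abs(res.params["g"] - g_grid[gi]) <= cell_g
        assert abs(res.params["residual"] - e_grid[ei]) <= cell_e
        assert res.llf >= ll.max() - 1e-6

    def test_pure_noise_pins_genetic_variance_at_floor(self):
        rng = np.random.default_rng(9)
        n = 80
        y = rng.standard_normal(n) * 3
        K = rng.standard_normal((n, n))
        K = K @ K.T / n
        res = VarianceComponentModel(y, {"g": K}).fit()
        assert res.at_boundary["g"]
        assert res.params["residual"] == pytest.approx(np.var(y, ddof=1), rel=0.2)

    def test_monotone_accepted_loglik_trace(self, small_sim):
        ids = list(small_sim.phenotypes["id"])
        G = gv.build_G(small_sim.genotypes.select_individuals(ids))
        A = gv.build_A(small_sim.pedigree).subset(ids)
        model = VarianceComponentModel(small_sim.phenotypes["y"].to_numpy(),
                                       {"g": G, "a": A},
                                       weights=small_sim.phenotypes["weight"].to_numpy(),
                                       ids=ids)
        res = model.fit()
        lls = [h[1] for h in res.history]
        assert all(b >= a - 1e-7 * max(1, abs(a)) for a, b in zip(lls, lls[1:]))

    def test_equivariance_to_matrix_scaling(self, small_sim):
        ids = list(small_sim.phenotypes["id"])
        y = small_sim.phenotypes["y"].to_numpy()
        G = gv.build_G(small_sim.genotypes.select_individuals(ids))
        scaled = RelationshipMatrix(G.ids, 4.0 * G.values)
        m1 = VarianceComponentModel(y, {"g": G}, ids=ids)
        m2 = VarianceComponentModel(y, {"g": scaled}, ids=ids)
        v = np.array([50.0, 20.0])
        assert m2.loglike([v[0] / 4.0, v[1]]) == pytest.approx(m1.loglike(v), rel=1e-10)
        r1, r2 = m1.fit(), m2.fit()
        assert r2.params["g"] * 4.0 == pytest.approx(r1.params["g"], rel=1e-3)
        assert r2.llf == pytest.approx(r1.llf, abs=1e-4)

    def test_parameter_recovery_single_pedigree_term(self):
        """Model with K = A recovers the simulated total additive variance."""
        hits = 0
        for seed in range(6):
            c = gv.SimConfig(n_founders=60, n_generations=3, sires_per_generation=8,
                             offspring_per_sire=15, n_chromosomes=5,
                             markers_per_chromosome=200, n_qtl=400,
                             var_polygenic=0.0, dam_policy="founder", seed=seed)
            sim = gv.simulate_dataset(c)
            ids = list(sim.phenotypes["id"])
            A = gv.build_A(sim.pedigree).subset(ids)
            res = gv.fit_model(sim.phenotypes, 1, A=A)
            dev = abs(res.params["a"] - 100.0)
            hits += dev <= 2 * res.results.bse["a"]
        assert hits >= 4

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            VarianceComponentModel([1.0, 2.0, 3.0], {})
        with pytest.raises(InputError):
            VarianceComponentModel([1.0, 2.0, 3.0], {"g": np.eye(2)})
        with pytest.raises(InputError):
            VarianceComponentModel([1.0, 2.0, 3.0], {"g": np.eye(3)},
                                   weights=[1.0, 0.0, 1.0])


class TestVarianceRatio:
    def test_noiseless_limit(self):
        import pandas as pd

        est = pd.Series({"g": 50.0, "residual": 0.0})
        assert gv.variance_ratio(est, 1.0) == 1.0

    def test_equal_parts(self):
        import pandas as pd

        est = pd.Series({"g": 30.0, "residual": 30.0})
        assert gv.variance_ratio(est, 1.0) == 0.5

    def test_weighted_example(self):
        import pandas as pd

        est = pd.Series({"g": 300.0, "residual": 100.0})
        assert gv.variance_ratio(est, 0.25) == pytest.approx(300.0 / 325.0)

    def test_zero_total_rejected(self):
        import pandas as pd

        with pytest.raises(InputError):
            gv.variance_ratio(pd.Series({"g": 0.0, "residual": 0.0}), 1.0)
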