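import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit

from ferretmeth.bmm import (
    AssociationConfig,
    fit_all_sites,
    fit_site_bmm,
    qq_diagnostics,
)
from ferretmeth.cgmap import CGMAP_COLUMNS, unite
from ferretmeth.pedigree import additive_relationship


class TestSingleSiteFits:
    def test_identical_proportions_give_zero_beta(self):
        res = fit_site_bmm([3, 3], [10, 10], [0, 1], sigma_g2=0.0, sigma_e2=0.0)
        assert res.beta == pytest.approx(0.0, abs=1e-10)

    def test_saturated_binary_predictor_closed_form(self):
        # logit(0.8) - logit(0.2) = 2 log 4
        res = fit_site_bmm([2, 8], [10, 10], [0, 1], sigma_g2=0.0, sigma_e2=0.0)
        assert res.beta == pytest.approx(2.772589, abs=1e-4)

    def test_no_random_effect_limit_matches_irls(self, rng):
        """With variances pinned to zero, PQL is exactly binomial IRLS."""
        for _ in range(10):
            n = int(rng.integers(8, 20))
            x = rng.normal(size=n)
            r = rng.integers(5, 40, size=n).astype(float)
            pi = expit(0.2 + 0.6 * x)
            y = rng.binomial(r.astype(int), pi).astype(float)
            if np.all(y == 0) or np.all(y == r):
                continue
            res = fit_site_bmm(y, r, x, sigma_g2=0.0, sigma_e2=0.0)
            glm = sm.GLM(
                np.column_stack([y, r - y]),
                sm.add_constant(x),
                family=sm.families.Binomial(),
            ).fit()
            assert res.beta == pytest.approx(glm.params[1], abs=1e-4)
            assert res.se == pytest.approx(glm.bse[1], rel=1e-3)

    def test_monomorphic_site_skipped(self):
        res = fit_site_bmm([0, 0, 0], [10, 10, 10], [0, 1, 2])
        assert res.skip_reason == "monomorphic" and res.beta is None

    def test_constant_predictor_skipped(self):
        res = fit_site_bmm([1, 2, 3], [10, 10, 10], [1, 1, 1])
        assert res.skip_reason == "constant-predictor"

    def test_beta_antisymmetric_in_predictor(self, rng):
        y = np.array([2.0, 5.0, 8.0, 3.0, 6.0, 9.0])
        r = np.full(6, 12.0)
        x = rng.normal(size=6)
        a = fit_site_bmm(y, r, x, sigma_g2=0.1, sigma_e2=0.1)
        b = fit_site_bmm(y, r, -x, sigma_g2=0.1, sigma_e2=0.1)
        assert a.beta == pytest.approx(-b.beta, abs=1e-6)

    def test_beta_rescales_under_affine_predictor(self, rng):
        y = np.array([2.0, 5.0, 8.0, 3.0, 6.0, 9.0])
        r = np.full(6, 12.0)
        x = rng.normal(size=6)
        a = fit_site_bmm(y, r, x, sigma_g2=0.0, sigma_e2=0.0)
        b = fit_site_bmm(y, r, 3.0 + 2.0 * x, sigma_g2=0.0, sigma_e2=0.0)
        assert a.beta == pytest.approx(2.0 * b.beta, abs=1e-5)

    def test_doubling_counts_does_not_increase_se(self, rng):
        y = np.array([2.0, 5.0, 8.0, 3.0])
        r = np.full(4, 12.0)
        x = np.array([0.0, 1.0, 2.0, 3.0])
        base = fit_site_bmm(y, r, x, sigma_g2=0.0, sigma_e2=0.0)
        double = fit_site_bmm(2 * y, 2 * r, x, sigma_g2=0.0, sigma_e2=0.0)
        assert double.se <= base.se + 1e-12


class TestQuadratureOracle:
    """PQL against full ML by Gauss-Hermite integration over the random
    effect (n = 6, kinship from a parent-offspring pedigree, sigmas fixed)."""

    @staticmethod
    def _ml_beta(y, r, x, Sigma):
        Lc = np.linalg.cholesky(Sigma)
        nodes, weights = hermegauss(8)
        grids = np.meshgrid(*([nodes] * 6), indexing="ij")
        T = np.stack([g.ravel() for g in grids], axis=1)
        W = np.ones(T.shape[0])
        for g in np.meshgrid(*([weights] * 6), indexing="ij"):
            W = W * g.ravel()
        W = W / W.sum()
        U = T @ Lc.T

        def nll(params):
            mu, beta = params
            eta = mu + x * beta + U
            ll = (y * np.log(expit(eta)) + (r - y) * np.log(expit(-eta))).sum(axis=1)
            m = ll.max()
            return -(m + np.log((W * np.exp(ll - m)).sum()))

        opt = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-9})
        return opt.x[1]

    @pytest.mark.parametrize("seed", [3, 11, 29])
    def test_pql_tracks_quadrature_ml(self, trio_pedigree, seed):
        K = additive_relationship(trio_pedigree).values
        sg, se = 0.5, 0.25
        Sigma = sg * K + se * np.eye(6)
        rng = np.random.default_rng(seed)
        x = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        x = (x - x.mean()) / x.std()
        r = rng.integers(10, 25, size=6).astype(float)
        u = np.linalg.cholesky(Sigma) @ rng.standard_normal(6)
        y = rng.binomial(r.astype(int), expit(0.2 + 0.8 * x + u)).astype(float)
        if np.all(y == 0) or np.all(y == r):
            pytest.skip("degenerate draw")
        pql = fit_site_bmm(y, r, x, K=K, sigma_g2=sg, sigma_e2=se)
        ml = self._ml_beta(y, r, x, Sigma)
        assert pql.beta == pytest.approx(ml, abs=0.2)


class TestScan:
    def _matrix(self, m, t, positions=None):
        rows = []
        positions = positions or range(1, m.shape[0] + 1)
        frames = {}
        for j in range(m.shape[1]):
            recs = [
                ("scaf1", "C", p, "CG", "CG", m[i, j] / t[i, j], m[i, j], t[i, j])
                for i, p in enumerate(positions)
            ]
            frames[f"s{j}"] = pd.DataFrame(recs, columns=CGMAP_COLUMNS)
        return unite(frames)

    def _phenotypes(self, n):
        return pd.DataFrame(
            {
                "sample_id": [f"s{j}" for j in range(n)],
                "avg_litter_size": np.linspace(0, 4, n),
                "age_at_sampling": np.tile([2, 3, 4], n)[:n],
            }
        )

    def test_monomorphic_site_flagged_others_fit(self, rng):
        n = 8
        t = np.full((5, n), 20)
        m = rng.binomial(20, 0.5, size=(5, n))
        m[2] = 0  # monomorphic row
        scan = fit_all_sites(self._matrix(m, t), self._phenotypes(n))
        assert (scan.table["skip_reason"] == "monomorphic").sum() == 1
        assert (scan.table["skip_reason"] == "none").sum() == 4

    def test_missing_phenotype_rejected(self, rng):
        t = np.full((2, 4), 20)
        m = rng.binomial(20, 0.5, size=(2, 4))
        pheno = self._phenotypes(3)
        with pytest.raises(ValueError, match="phenotype missing"):
            fit_all_sites(self._matrix(m, t), pheno)

    def test_beta_reported_on_standardized_scale(self, rng):
        n = 10
        t = np.full((3, n), 25)
        m = rng.binomial(25, 0.4, size=(3, n))
        scan = fit_all_sites(self._matrix(m, t), self._phenotypes(n))
        x = np.linspace(0, 4, n)
        assert scan.predictor_scale == pytest.approx(x.std())
        assert scan.predictor_center == pytest.approx(x.mean())


class TestQqDiagnostics:
    def test_uniform_grid_is_calibrated(self):
        m = 200
        p = np.arange(1, m + 1) / (m + 1.0)
        qq = qq_diagnostics(p)
        assert qq.slope == pytest.approx(1.0, abs=0.02)
        assert qq.direction == "calibrated"
        assert np.allclose(qq.expected, qq.observed, atol=0.01)

    def test_all_ones_flagged_as_deflation(self):
        qq = qq_diagnostics(np.ones(50))
        assert qq.direction == "deflation"
        assert qq.slope == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qq_diagnostics([])
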