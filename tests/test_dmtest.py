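"""Mixed-model fitting, q-values, DMC calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import kinmeth as km
from kinmeth.dmtest import SiteModelSpec, fit_site, group_meth_diff
from kinmeth.matrix import MISSING, MethylationMatrix, SampleMeta

from .oracles import betabinom_regression_beta, exact_marginal_beta


def spec_of(y, r, x, K=None, W=None):
    n = len(y)
    return SiteModelSpec(
        y=np.asarray(y, float),
        r=np.asarray(r, float),
        x=np.asarray(x, float),
        W=W if W is not None else np.ones((n, 1)),
        K=K if K is not None else np.eye(n),
    )


class TestFitSite:
    def test_symmetric_data_beta_zero_p_one(self):
        # identical group patterns, variances fixed at zero
        y = [3, 5, 7, 3, 5, 7]
        r = [10] * 6
        x = [0, 0, 0, 1, 1, 1]
        fit = fit_site(spec_of(y, r, x), fix_sigma_g2=0.0, fix_sigma_e2=0.0)
        assert fit.beta_hat == pytest.approx(0.0, abs=1e-6)
        assert fit.p_value == pytest.approx(1.0, abs=1e-5)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="inestimable"):
            fit_site(spec_of([1, 2, 3, 4], [10] * 4, [1, 1, 1, 1]))

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_site(spec_of([1, 2, 3], [10] * 3, [0, 1, 0]))

    def test_non_psd_kinship_rejected(self):
        K = np.array(
            [[1, -2, 0, 0], [-2, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]]
        )
        with pytest.raises(ValueError, match="positive semidefinite"):
            spec_of([1, 2, 3, 4], [10] * 4, [0, 0, 1, 1], K=K)

    def test_glm_reduction_matches_statsmodels(self):
        """Variances fixed at 0: plain binomial GLM."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        n = 30
        x = np.repeat([0.0, 1.0], n // 2)
        r = np.full(n, 40)
        y = rng.binomial(r, 1 / (1 + np.exp(-(-0.5 + 0.8 * x))))
        fit = fit_site(spec_of(y, r, x), fix_sigma_g2=0.0, fix_sigma_e2=0.0)
        X = np.column_stack([np.ones(n), x])
        glm = sm.GLM(np.column_stack([y, r - y]), X,
                     family=sm.families.Binomial()).fit()
        assert fit.beta_hat == pytest.approx(glm.params[1], abs=1e-6)
        assert fit.se_beta == pytest.approx(glm.bse[1], rel=1e-3)

    def test_laplace_matches_exact_quadrature_small_n(self):
        """n=6 with variances fixed at truth: Laplace beta within 0.05 of the
        exact marginal-likelihood estimate (Gauss-Hermite oracle)."""
        rng = np.random.default_rng(1)
        worst = 0.0
        for rep in range(10):
            n = 6
            x = np.array([0.0, 0, 0, 1, 1, 1])
            # two trios of full sibs
            K = np.eye(n)
            K[0, 1] = K[1, 0] = K[0, 2] = K[2, 0] = K[1, 2] = K[2, 1] = 0.5
            K[3, 4] = K[4, 3] = K[3, 5] = K[5, 3] = K[4, 5] = K[5, 4] = 0.5
            sg2, se2 = 0.3, 0.2
            Sigma = sg2 * K + se2 * np.eye(n)
            L = np.linalg.cholesky(Sigma)
            alpha, beta = rng.normal(0, 0.7, 2)
            eta = alpha + beta * x + L @ rng.standard_normal(n)
            r = np.full(n, 30.0)
            y = rng.binomial(30, 1 / (1 + np.exp(-eta))).astype(float)
            if y.min() == 0 or (y == r).any():
                continue  # avoid near-separated draws in this small check
            fit = fit_site(spec_of(y, r, x, K=K), fix_sigma_g2=sg2, fix_sigma_e2=se2)
            X = np.column_stack([np.ones(n), x])
            b_exact = exact_marginal_beta(y, r, X, Sigma, n_nodes=5)
            worst = max(worst, abs(fit.beta_hat - b_exact[1]))
        assert worst < 0.05

    def test_reduction_to_betabinomial_oracle(self):
        """sigma_g2 = 0, K = I: estimates track an independent beta-binomial
        regression on overdispersed data.

        The comparison is on the population-averaged (marginal) scale: the
        beta-binomial mean is exactly expit(Xb) while the logit-normal
        model's conditional coefficient is attenuated marginally by
        ~sqrt(1 + c^2 sigma_e^2) with c = 16 sqrt(3) / (15 pi), so the
        conditional estimate is deflated by that factor before comparing.
        """
        c2 = (16 * np.sqrt(3) / (15 * np.pi)) ** 2
        rng = np.random.default_rng(2)
        diffs = []
        for rep in range(12):
            n = 24
            x = np.repeat([0.0, 1.0], n // 2)
            eta = 0.2 + 0.8 * x + rng.normal(0, np.sqrt(0.3), n)
            r = np.full(n, 50.0)
            y = rng.binomial(50, 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_site(spec_of(y, r, x))
            X = np.column_stack([np.ones(n), x])
            b_bb = betabinom_regression_beta(y, r, X)
            marginal = fit.beta_hat / np.sqrt(1 + c2 * fit.sigma_e2_hat)
            diffs.append(marginal - b_bb[1])
        assert np.mean(np.abs(diffs)) < 0.05

    def test_effect_recovery_sampling_mean(self):
        """beta = 1, K = I: mean estimate over replicates near truth."""
        rng = np.random.default_rng(3)
        n = 20
        x = np.repeat([0.0, 1.0], n // 2)
        betas = []
        for _ in range(60):
            eta = -0.2 + 1.0 * x + rng.normal(0, np.sqrt(0.25), n)
            r = np.maximum(rng.negative_binomial(5, 5 / 35, n), 1).astype(float)
            y = rng.binomial(r.astype(int), 1 / (1 + np.exp(-eta))).astype(float)
            betas.append(fit_site(spec_of(y, r, x)).beta_hat)
        assert abs(np.mean(betas) - 1.0) < 0.15


def _matrix(meth, total, groups):
    n_sites, n_samples = np.shape(meth)
    samples = [SampleMeta(f"s{j}", group=groups[j]) for j in range(n_samples)]
    sites = pd.DataFrame({"chrom": ["chr1"] * n_sites,
                          "pos": np.arange(1, n_sites + 1) * 100,
                          "strand": ["."] * n_sites})
    return MethylationMatrix(sites, samples, np.asarray(meth), np.asarray(total))


class TestFitAll:
    def test_single_site_delegates_to_fit_site(self):
        rng = np.random.default_rng(4)
        groups = ["hatchery"] * 4 + ["stream"] * 4
        total = np.full((1, 8), 30)
        meth = rng.integers(5, 26, (1, 8))
        mat = _matrix(meth, total, groups)
        K = km.KinshipMatrix([f"s{j}" for j in range(8)], np.eye(8))
        fits = km.fit_all(mat, K, progress_every=0)
        x = mat.group_indicator("group", "hatchery")
        direct = fit_site(SiteModelSpec(meth[0], total[0], x, np.ones((8, 1)), np.eye(8)))
        assert fits.loc[0, "beta_hat"] == pytest.approx(direct.beta_hat)
        assert fits.loc[0, "p_value"] == pytest.approx(direct.p_value)

    def test_sparse_site_flagged_not_fit(self):
        groups = ["hatchery"] * 4 + ["stream"] * 4
        total = np.full((1, 8), MISSING)
        total[0, :3] = 20
        meth = np.where(total == MISSING, MISSING, 5)
        mat = _matrix(meth, total, groups)
        K = km.KinshipMatrix([f"s{j}" for j in range(8)], np.eye(8))
        fits = km.fit_all(mat, K, progress_every=0)
        assert not fits.loc[0, "converged"]
        assert np.isnan(fits.loc[0, "p_value"])


class TestQvalues:
    def test_all_ones(self):
        assert np.allclose(km.qvalues(np.ones(10)), 1.0)

    def test_bh_equivalence_when_pi0_one(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.random(200)
        q = km.qvalues(p, pi0=1.0)
        _, bh, _, _ = sm.multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh)

    def test_pi0_near_one_under_null(self):
        rng = np.random.default_rng(6)
        p = rng.random(5000)
        assert 0.85 <= km.estimate_pi0(p) <= 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            km.qvalues([0.5, 0.0])
        with pytest.raises(ValueError):
            km.qvalues([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
                 min_size=2, max_size=100)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p(self, ps):
        p = np.asarray(ps)
        q = km.qvalues(p, pi0=0.7)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallDmcs:
    def _fits(self, pvals):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * len(pvals),
                "pos": np.arange(1, len(pvals) + 1) * 100,
                "p_value": pvals,
                "beta_hat": 0.5,
                "se": 0.1,
                "sigma_g2": 0.1,
                "sigma_e2": 0.1,
                "n_used": 8,
                "converged": True,
            }
        )

    def test_boundary_q_equal_fdr_not_called(self):
        groups = ["hatchery"] * 4 + ["stream"] * 4
        total = np.full((3, 8), 20)
        meth = np.full((3, 8), 10)
        mat = _matrix(meth, total, groups)
        fits = self._fits([0.5, 0.6, 0.7])
        out = km.call_dmcs(fits, mat, fdr=0.10)
        # force the q-value column to the boundary and re-evaluate the rule
        out2 = out.copy()
        out2["q_value"] = 0.10
        called = out2["p_value"].notna() & (out2["q_value"] < 0.10)
        assert not called.any()

    def test_meth_diff_sign_and_magnitude(self):
        groups = ["hatchery"] * 4 + ["stream"] * 4
        total = np.full((1, 8), 20)
        meth = np.array([[16, 16, 16, 16, 11, 11, 11, 11]])  # 0.80 vs 0.55
        mat = _matrix(meth, total, groups)
        diff = group_meth_diff(
            mat, mat.group_indicator("group", "hatchery").astype(bool),
            mat.group_indicator("group", "stream").astype(bool),
        )
        assert diff[0] == pytest.approx(0.25)

    def test_no_calls_when_no_q_below_threshold(self):
        groups = ["hatchery"] * 4 + ["stream"] * 4
        total = np.full((3, 8), 20)
        meth = np.full((3, 8), 10)
        mat = _matrix(meth, total, groups)
        out = km.call_dmcs(self._fits([0.9, 0.8, 0.95]), mat)
        assert not out["is_dmc"].any()


class TestCompareDmcSets:
    def _df(self, sites, diffs=None):
        return pd.DataFrame(
            {
                "chrom": [c for c, _ in sites],
                "pos": [p for _, p in sites],
                "meth_diff": diffs if diffs else [0.2] * len(sites),
            }
        )

    def test_identical_single_site(self):
        a = self._df([("chr1", 500)])
        rep = km.compare_dmc_sets(a, a)
        assert rep["n_exact"] == 1 and rep["n_proximal"] == 0

    def test_proximity_boundaries(self):
        a = self._df([("chr1", 1000)])
        b = self._df([("chr1", 10999)])   # 9,999 bp apart -> proximal
        c = self._df([("chr1", 11001)])   # 10,001 bp -> neither
        assert km.compare_dmc_sets(a, b)["n_proximal"] == 1
        rep = km.compare_dmc_sets(a, c)
        assert rep["n_exact"] == 0 and rep["n_proximal"] == 0

    def test_direction_concordance(self):
        a = self._df([("chr1", 1000)], [0.3])
        b = self._df([("chr1", 1500)], [-0.3])
        rep = km.compare_dmc_sets(a, b)
        assert rep["n_pairs"] == 1 and rep["n_concordant"] == 0
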