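"""The summary-statistic association engine against individual-level oracles."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import phenotrace as pt
from phenotrace.assoc import (
    AssociationError,
    snp_trait_corr,
    subset_association,
    subset_bic,
    subset_pvalue,
    subset_r1,
    univariate_r2,
)
from phenotrace.synthetic import oracle_subset_stats
from phenotrace.traitcorr import TraitCorrelationMatrix


def _sample_corr(Y, names):
    c = np.corrcoef(Y, rowvar=False)
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    return TraitCorrelationMatrix(
        values=pd.DataFrame(c, index=names, columns=names),
        source="user_supplied",
    )


class TestUnivariateR2:
    def test_null_and_algebraic_identity(self):
        assert univariate_r2(0.0, 1000) == 0.0
        assert univariate_r2(math.sqrt(1000), 1000) == pytest.approx(0.5)
        with pytest.raises(AssociationError):
            univariate_r2(1.0, 0)

    def test_matches_ols_fit(self):
        """R^2 from the z-score reproduces the OLS R^2.

        linregress is the independent oracle.  With residual df n-2 in the
        t statistic, z^2/(z^2 + n - 2) is the exact OLS R^2; the n in place
        of n - 2 used by the summary formula is its large-n form.
        """
        rng = np.random.default_rng(5)
        n = 2045
        x = rng.binomial(2, 0.3, n).astype(float)
        y = 0.07 * x + rng.normal(size=n)
        fit = stats.linregress(x, y)
        z = fit.slope / fit.stderr
        assert univariate_r2(z, n - 2) == pytest.approx(fit.rvalue**2, abs=1e-12)
        assert univariate_r2(z, n) == pytest.approx(fit.rvalue**2, abs=2 / n)


class TestSubsetR1:
    def test_null_vector(self):
        assert subset_r1(np.zeros(4), np.eye(4)) == 0.0

    def test_identity_matrix_pythagoras(self):
        assert subset_r1([0.3, 0.4], np.eye(2)) == pytest.approx(0.5, abs=1e-12)

    def test_single_trait_absolute_value(self):
        assert subset_r1([-0.2], np.eye(1)) == pytest.approx(0.2)

    def test_singular_matrix_names_remedy(self):
        S = np.ones((2, 2))
        with pytest.raises(AssociationError, match="metacca-plus"):
            subset_r1([0.1, 0.1], S)

    def test_matches_individual_level_cca(self):
        """Summary r1 vs the first canonical correlation on raw data.

        For one variant, the first canonical correlation equals sqrt(R^2)
        of regressing genotype on the traits; oracle_subset_stats computes
        it directly from individual-level data.
        """
        rng = np.random.default_rng(17)
        n, k = 2000, 5
        corr = 0.5 * np.ones((k, k))
        np.fill_diagonal(corr, 1.0)
        L = np.linalg.cholesky(corr)
        names = [f"T{j}" for j in range(k)]
        for trial in range(5):
            g = rng.binomial(2, 0.35, n).astype(float)
            Y = rng.standard_normal((n, k)) @ L.T
            Y[:, 0] += 0.15 * g
            Y[:, 3] += 0.10 * g
            zs, ns = [], []
            for j in range(k):
                fit = stats.linregress(g, Y[:, j])
                zs.append(fit.slope / fit.stderr)
                ns.append(n)
            r = snp_trait_corr(np.array(zs), np.array(ns))
            r1 = subset_r1(r, _sample_corr(Y, names).subset(names))
            oracle = oracle_subset_stats(g, Y)
            assert abs(r1 - oracle.r1) < 0.02


class TestSubsetPvalue:
    def test_null_is_p_one(self):
        assert subset_pvalue(0.0, 3, 1000) == 0.0

    def test_k1_equals_t_test_identity(self):
        """F(1, d) = t^2(d): the one-trait P matches the two-sided t P."""
        for r1, n in [(0.05, 500), (0.12, 2045), (0.3, 150)]:
            nlp = subset_pvalue(r1, 1, n)
            F = (r1**2) * (n - 2) / (1 - r1**2)
            t = math.sqrt(F)
            nlp_t = -(stats.t.logsf(t, n - 2) + math.log(2)) / math.log(10)
            assert nlp == pytest.approx(nlp_t, rel=1e-9)

    def test_matches_independent_f_evaluation(self):
        # k = 4, n = 10,000, R^2 = 0.01; oracle: regularised incomplete beta
        k, n, r2 = 4, 10_000, 0.01
        dof2 = n - k - 1
        F = (r2 / k) / ((1 - r2) / dof2)
        sf = special.betainc(dof2 / 2, k / 2, dof2 / (dof2 + k * F))
        assert subset_pvalue(math.sqrt(r2), k, n) == pytest.approx(
            -math.log10(sf), rel=1e-9
        )

    def test_monotone_in_r1(self):
        r1s = np.linspace(0.01, 0.9, 50)
        nlps = [subset_pvalue(r, 4, 5000) for r in r1s]
        bics = [subset_bic(r, 4, 5000) for r in r1s]
        assert np.all(np.diff(nlps) > 0)
        assert np.all(np.diff(bics) < 0)

    @pytest.mark.parametrize("method", ["f", "bartlett"])
    def test_far_beyond_underflow_stays_finite(self, method):
        # P ~ 1e-300 and far smaller must stay representable on -log10 scale
        mild = subset_pvalue(0.263, 2, 20_000, method=method)  # ~1e-311
        extreme = subset_pvalue(0.9, 2, 20_000, method=method)
        assert 250 < mild < 350
        assert np.isfinite(extreme) and extreme > 1000

    def test_small_sample_errors(self):
        with pytest.raises(AssociationError, match="too small"):
            subset_pvalue(0.1, 5, 6)

    def test_bartlett_close_to_f_at_large_n(self):
        a = subset_pvalue(0.1, 3, 50_000, method="f")
        b = subset_pvalue(0.1, 3, 50_000, method="bartlett")
        assert a == pytest.approx(b, rel=0.01)


class TestSubsetBic:
    def test_null_model_is_pure_penalty(self):
        assert subset_bic(0.0, 3, 1000) == pytest.approx(3 * math.log(1000))

    def test_zero_gain_trait_costs_log_n(self):
        r1, n = 0.2, 2000
        assert subset_bic(r1, 4, n) - subset_bic(r1, 3, n) == pytest.approx(
            math.log(n)
        )

    def test_invalid_inputs(self):
        with pytest.raises(AssociationError):
            subset_bic(1.0, 2, 100)
        with pytest.raises(AssociationError):
            subset_bic(0.1, 0, 100)

    def test_matches_individual_level_bic(self):
        """Constant-aligned BIC vs the maximized-likelihood oracle."""
        rng = np.random.default_rng(23)
        n, k = 2000, 4
        names = [f"T{j}" for j in range(k)]
        g = rng.binomial(2, 0.4, n).astype(float)
        Y = rng.standard_normal((n, k))
        Y[:, 1] += 0.2 * g
        zs = []
        for j in range(k):
            fit = stats.linregress(g, Y[:, j])
            zs.append(fit.slope / fit.stderr)
        r = snp_trait_corr(np.array(zs), np.full(k, n))
        S = _sample_corr(Y, names)
        for sub in [(0,), (1,), (0, 1), (0, 1, 2, 3)]:
            idx = list(sub)
            r1 = subset_r1(r[idx], S.subset([names[j] for j in idx]))
            oracle = oracle_subset_stats(g, Y[:, idx])
            assert abs(subset_bic(r1, len(idx), n) - oracle.bic) < 0.5


class TestPanelIntegration:
    def test_monotone_nesting_of_r_squared(self, panel8, corr8):
        """R^2 of a trait superset is never (numerically) below a subset's."""
        rng = np.random.default_rng(2)
        traits = panel8.traits
        for i in rng.integers(0, panel8.n_variants, size=8):
            sub = list(rng.choice(traits, size=3, replace=False))
            sup = sub + [t for t in traits if t not in sub][:2]
            a = subset_association(panel8, int(i), sub, corr8)
            b = subset_association(panel8, int(i), sup, corr8)
            assert b.r_squared >= a.r_squared - 1e-8

    def test_n_policy(self, panel8, corr8):
        a = subset_association(panel8, 0, panel8.traits, corr8, n_policy="min")
        b = subset_association(panel8, 0, panel8.traits, corr8, n_policy="mean")
        assert a.n_used == int(panel8.n[0].min())
        assert b.n_used == int(round(panel8.n[0].mean()))
        with pytest.raises(AssociationError):
            subset_association(panel8, 0, panel8.traits, corr8, n_policy="max")
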