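"""ZINB likelihood/fitting/LRT and elastic-net sign models."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vaginome import assoc, synthetic
from vaginome.containers import CountMatrix
from vaginome.errors import DataError, ParameterError


def simulate_zinb(rng, X, beta, pi, theta):
    mu = np.exp(X @ beta)
    lam = rng.gamma(theta, mu / theta)
    y = rng.poisson(lam)
    y[rng.random(len(y)) < pi] = 0
    return y


class TestZinbLoglik:
    def test_pi_zero_reduces_to_negative_binomial(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.0, 0.3])
        y = rng.poisson(np.exp(X @ beta))
        theta = 1.7
        mu = np.exp(X @ beta)
        # scipy's NB(n=theta, p=theta/(theta+mu)) is the same distribution
        expected = stats.nbinom(theta, theta / (theta + mu)).logpmf(y).sum()
        assert assoc.zinb_loglik(beta, 0.0, theta, y, X) == pytest.approx(expected)

    def test_all_zero_counts_pi_near_one(self):
        X = np.ones((20, 1))
        y = np.zeros(20)
        ll = assoc.zinb_loglik(np.array([0.0]), 1 - 1e-12, 2.0, y, X)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_mixture_summation(self, rng):
        """Oracle: evaluate the mixture density term by term with gamma
        functions, no shared code path."""
        n = 12
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        beta = np.array([0.8, -0.4])
        pi, theta = 0.25, 1.3
        y = simulate_zinb(rng, X, beta, pi, theta).astype(float)
        direct = 0.0
        for yi, xi in zip(y, X):
            mu = math.exp(float(xi @ beta))
            nb = (
                math.gamma(yi + theta) / (math.gamma(theta) * math.factorial(int(yi)))
                * (theta / (theta + mu)) ** theta * (mu / (theta + mu)) ** yi
            )
            direct += math.log(pi * (yi == 0) + (1 - pi) * nb)
        assert assoc.zinb_loglik(beta, pi, theta, y, X) == pytest.approx(direct)

    def test_domain_errors(self):
        X, y = np.ones((10, 1)), np.zeros(10)
        with pytest.raises(ParameterError):
            assoc.zinb_loglik(np.array([0.0]), 0.2, -1.0, y, X)
        with pytest.raises(ParameterError):
            assoc.zinb_loglik(np.array([0.0]), 1.0, 2.0, y, X)


class TestFitZinb:
    def test_zero_inflation_absent_detected(self, rng):
        n = 800
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        y = simulate_zinb(rng, X, np.array([1.2, 0.4]), 0.0, 2.0)
        fit = assoc.fit_zinb(y, X)
        assert fit.converged
        assert fit.pi <= 0.05

    def test_nested_models_order_likelihoods(self, rng):
        n = 300
        race = rng.integers(0, 2, n).astype(float)
        bv = rng.integers(0, 2, n).astype(float)
        X_full = np.column_stack([np.ones(n), race, bv, race * bv])
        y = simulate_zinb(rng, X_full, np.array([1.0, 0.2, 0.6, 0.0]), 0.2, 2.0)
        full = assoc.fit_zinb(y, X_full)
        red = assoc.fit_zinb(y, X_full[:, :3])
        assert full.loglik >= red.loglik - 1e-6

    def test_too_few_observations(self):
        with pytest.raises(ParameterError):
            assoc.fit_zinb(np.array([1, 2, 3]), np.ones((3, 2)))

    def test_matches_external_zinb_implementation(self, rng):
        """statsmodels' zero-inflated NB (same parameterization) is the
        independent optimizer cross-check."""
        from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

        n = 600
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        y = simulate_zinb(rng, X, np.array([1.0, 0.5]), 0.3, 2.0)
        ours = assoc.fit_zinb(y, X)
        theirs = ZeroInflatedNegativeBinomialP(
            y, X, exog_infl=np.ones((n, 1)), p=2
        ).fit(disp=0)
        assert ours.loglik == pytest.approx(theirs.llf, abs=1e-4)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert assoc.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_step_up(self):
        q = assoc.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_at_least_p_and_monotone_in_rank(self, rng):
        p = rng.random(40)
        q = assoc.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_domain_check(self):
        with pytest.raises(ParameterError):
            assoc.bh_adjust([0.5, 1.5])


class TestElasticNet:
    def test_huge_penalty_zeroes_everything(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        y = rng.normal(size=40)
        res = assoc.elasticnet_fit(X, y, alpha=0.5, k_folds=4, seed=0,
                                   lambda_path=np.array([1e6]))
        assert (res.coefficients == 0).all()

    def test_orthonormal_soft_threshold_closed_form(self, rng):
        n, p = 64, 8
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = q * math.sqrt(n)  # columns with x_j'x_j / n = 1, orthogonal
        beta_true = np.zeros(p)
        beta_true[:3] = [2.0, -1.5, 1.0]
        y = X @ beta_true
        yc = y - y.mean()
        lam = 0.7
        b_ols = X.T @ yc / n
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
        got = assoc._coordinate_descent(X, yc, lam, 1.0, np.zeros(p))
        assert np.abs(got - expected).max() < 1e-6

    def test_matches_sklearn_solver(self, rng):
        from sklearn.linear_model import ElasticNet

        X = rng.normal(size=(100, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=100)
        lam, alpha = 0.3, 0.5
        ours = assoc._coordinate_descent(
            X - X.mean(0), y - y.mean(), lam, alpha, np.zeros(10),
            tol=1e-12, max_sweeps=10_000,
        )
        theirs = ElasticNet(alpha=lam, l1_ratio=alpha, tol=1e-12,
                            max_iter=100_000).fit(X, y)
        assert np.abs(ours - theirs.coef_).max() < 1e-8

    def test_planted_signal_recovered_by_cv(self, rng):
        n, p = 200, 50
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"t{i}" for i in range(p)])
        y = 1.2 * X["t0"] - 1.0 * X["t1"] + 0.8 * X["t2"] + rng.normal(0, 0.5, n)
        res = assoc.elasticnet_fit(X, y, alpha=0.5, k_folds=10, seed=0)
        assert {"t0", "t1", "t2"} <= set(res.nonzero.index)
        assert np.sign(res.coefficients["t1"]) == -1

    def test_k_folds_validation(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(ParameterError):
            assoc.elasticnet_fit(X, np.zeros(5), k_folds=10)


class TestInteractionLrt:
    def test_deviance_nonnegative_and_bh_applied(self, cohort):
        meta, cm = cohort
        table = assoc.interaction_lrt(cm, meta, min_nonzero=8)
        tested = table[table["reason"] == ""]
        assert len(tested) >= 3
        assert (tested["deviance"] >= 0).all()
        assert (tested["q"] >= tested["p"] - 1e-12).all()

    def test_covariate_encoding_order_invariance(self, cohort):
        meta, cm = cohort
        t1 = assoc.interaction_lrt(cm, meta, race_levels=("White", "Black"))
        flipped = meta.copy()
        t2 = assoc.interaction_lrt(cm, flipped, race_levels=("Black", "White"))
        a = t1[t1["reason"] == ""].set_index("taxon")["deviance"]
        b = t2[t2["reason"] == ""].set_index("taxon")["deviance"]
        common = a.index.intersection(b.index)
        assert len(common) >= 3
        assert np.allclose(a[common], b[common], atol=1e-3)

    def test_sparse_taxa_skipped_with_reason(self, cohort):
        meta, cm = cohort
        table = assoc.interaction_lrt(cm, meta, min_nonzero=10_000)
        assert (table["reason"] == "too_few_nonzero").all()

    def test_power_increases_with_interaction_strength(self, rng):
        """LRT power grows monotonically across three planted effect
        sizes (per-taxon simulation from the cohort count model)."""
        n = 160
        race = rng.integers(0, 2, n).astype(float)
        bv = rng.integers(0, 2, n).astype(float)
        x_full = np.column_stack([np.ones(n), race, bv, race * bv])
        power = []
        for gamma in (0.0, 0.8, 1.6):
            hits = 0
            n_sims = 120
            for _ in range(n_sims):
                mu = np.exp(1.2 + 0.3 * race + 0.5 * bv + gamma * race * bv)
                y = rng.poisson(rng.gamma(2.0, mu / 2.0))
                y[rng.random(n) < 0.12] = 0
                full = assoc.fit_zinb(y, x_full)
                red = assoc.fit_zinb(y, x_full[:, :3])
                d = max(0.0, 2.0 * (full.loglik - red.loglik))
                hits += stats.chi2.sf(d, 1) < 0.05
            power.append(hits / n_sims)
        assert power[0] < power[1] < power[2]
        assert power[0] < 0.15  # near-nominal under the null
        assert power[2] > 0.8


class TestSignAssociation:
    def test_two_driver_taxa_hit_all_four_criteria(self, world):
        """When two taxa drive every sign, both appear in all four models."""
        eff = synthetic.EffectConfig.default(world.species)
        eff.depth_mean = 400.0
        drivers = [t for t in world.species
                   if "amnionii" in t or "Eggerthella" in t]
        assert len(drivers) == 2
        for name, model in eff.sign_models.items():
            total = 2.4 if name != "ph" else 0.8
            model.coefs = {t: total / 2 for t in drivers}
        meta, cm = synthetic.simulate_cohort(160, 0.5, {"W": 1.0}, eff, seed=31)
        fits, member = assoc.sign_association_table(cm, meta, seed=31)
        for t in drivers:
            assert member.loc[t, "n_criteria"] == 4
            for sign in ("ph", "amsel_whiff", "clue_cells", "amsel_discharge"):
                assert member.loc[t, sign] > 0

    def test_independent_sign_selects_nothing_usually(self, world, rng):
        """A sign with no taxon dependence mostly yields an empty model
        under the sparsity-oriented 1-SE rule; occasional chance
        correlations with the structured taxa keep a coefficient or two."""
        eff = synthetic.EffectConfig.default(world.species)
        eff.depth_mean = 300.0
        meta, cm = synthetic.simulate_cohort(400, 0.5, {"W": 1.0}, eff, seed=32)
        logX = pd.DataFrame(
            np.log(cm.counts.to_numpy(dtype=float) + 0.5),
            index=cm.samples, columns=cm.taxa,
        )
        empty, sizes = 0, []
        n_seeds = 10
        for s in range(n_seeds):
            y = rng.normal(size=len(cm.samples))  # pure noise sign
            res = assoc.elasticnet_fit(logX, y, alpha=0.5, k_folds=5, seed=s,
                                       selection_rule="1se")
            sizes.append(int((res.coefficients != 0).sum()))
            empty += int(sizes[-1] == 0)
        assert empty >= 0.7 * n_seeds
        assert max(sizes) <= 3

    def test_missing_sign_column_is_data_error(self, cohort):
        meta, cm = cohort
        broken = meta.drop(columns=["amsel_whiff"])
        with pytest.raises((DataError, KeyError)):
            assoc.sign_association_table(cm, broken)
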