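"""Effect estimators: propensity fitting, weighting, trimming, Hájek IPW,
AIPW double robustness, bootstrap inference, and the CEVAE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalkit import (CEVAEConfig, SimulationConfig, aipw_ate,
                       bootstrap_inference, cevae_ate, estimate_propensity,
                       fit_cevae, generate_cohort, ipw_ate, ipw_weights,
                       naive_ate, trim_weights)
from causalkit.estimation import gaussian_kl
from causalkit.synthcohort import DegenerateArmError


class TestEstimatePropensity:
    def test_intercept_only_returns_marginal_rate(self):
        T = np.array([1] * 40 + [0] * 60)
        fit = estimate_propensity(np.empty((100, 0)), T)
        assert np.allclose(fit.scores, 0.4)

    def test_matches_hand_rolled_newton_raphson(self):
        """Independent IRLS oracle on a 3-covariate toy."""
        rng = np.random.default_rng(0)
        n = 800
        X = rng.standard_normal((n, 3))
        T = rng.binomial(1, 1 / (1 + np.exp(-(0.3 + X @ [1.0, -0.5, 0.2]))))
        fit = estimate_propensity(X, T)

        D = np.column_stack([np.ones(n), X])
        beta = np.zeros(4)
        for _ in range(50):
            p = 1 / (1 + np.exp(-D @ beta))
            W = p * (1 - p)
            step = np.linalg.solve(D.T @ (W[:, None] * D), D.T @ (T - p))
            beta = beta + step
            if np.max(np.abs(step)) < 1e-12:
                break
        oracle = 1 / (1 + np.exp(-D @ beta))
        assert fit.scores == pytest.approx(oracle, abs=1e-6)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 2))
        T = rng.binomial(1, 0.5, 200)
        perm = rng.permutation(200)
        s1 = estimate_propensity(X, T).scores[perm]
        s2 = estimate_propensity(X[perm], T[perm]).scores
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_perfect_separation_warns_but_returns_clipped(self):
        x = np.linspace(-2, 2, 100)
        T = (x > 0).astype(int)
        with pytest.warns(UserWarning, match="separation"):
            fit = estimate_propensity(x[:, None], T)
        assert np.all((fit.scores >= 1e-6) & (fit.scores <= 1 - 1e-6))


class TestIpwWeights:
    def test_constant_half_scores(self):
        w = ipw_weights(np.full(4, 0.5), np.array([1, 0, 1, 0]))
        assert np.all(w == 2.0)

    def test_direct_formula(self):
        w = ipw_weights(np.array([0.8, 0.8]), np.array([1, 0]))
        assert w == pytest.approx([1.25, 5.0])

    def test_elementwise_loop_oracle(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(0.05, 0.95, 50)
        T = rng.binomial(1, 0.5, 50)
        w = ipw_weights(e, T)
        expected = [1 / ei if ti == 1 else 1 / (1 - ei) for ei, ti in zip(e, T)]
        assert w == pytest.approx(expected)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            ipw_weights(np.array([0.0, 0.5]), np.array([1, 0]))


class TestTrimWeights:
    def test_equal_weights_unchanged(self):
        w = np.full(10, 3.0)
        assert np.all(trim_weights(w) == 3.0)

    def test_sort_based_percentile_oracle(self):
        w = np.arange(1.0, 101.0)
        out = trim_weights(w, 1, 99)
        lo, hi = np.percentile(w, [1, 99])
        assert out.min() == pytest.approx(lo) and out.max() == pytest.approx(hi)
        interior = (w > lo) & (w < hi)
        assert np.all(out[interior] == w[interior])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.1, 1e3), min_size=3, max_size=100))
    def test_repeated_trimming_contracts_and_preserves_interior(self, ws):
        """Re-trimming never expands the range; strictly interior values are
        untouched; constant vectors are exact fixed points."""
        w = np.asarray(ws)
        once = trim_weights(w)
        twice = trim_weights(once)
        assert once.min() - 1e-12 <= twice.min()
        assert twice.max() <= once.max() + 1e-12
        lo1, hi1 = np.percentile(once, [1, 99])
        interior = (once > lo1) & (once < hi1)
        assert twice[interior] == pytest.approx(once[interior])

    def test_constant_vector_is_fixed_point(self):
        w = np.full(17, 2.5)
        assert np.all(trim_weights(trim_weights(w)) == w)

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValueError):
            trim_weights(np.ones(5), 99, 1)


class TestIpwAte:
    def test_worked_four_row_table(self):
        T = np.array([1, 1, 0, 0])
        Y = np.array([2.0, 1.0, 1.0, 0.0])
        e = np.array([0.8, 0.5, 0.5, 0.2])
        res = ipw_ate(Y, T, ipw_weights(e, T))
        treated = (1.25 * 2 + 2 * 1) / (1.25 + 2)
        control = (2 * 1 + 1.25 * 0) / (2 + 1.25)
        assert res.ate == pytest.approx(treated - control, abs=1e-12)
        assert res.ate == pytest.approx(0.769230769230769, abs=1e-12)

    def test_constant_scores_reduce_to_difference_in_means(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal(200)
        T = rng.binomial(1, 0.5, 200)
        res = ipw_ate(Y, T, ipw_weights(np.full(200, 0.5), T))
        assert res.ate == pytest.approx(Y[T == 1].mean() - Y[T == 0].mean(),
                                        abs=1e-12)

    def test_hajek_invariance_to_weight_rescaling(self):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal(300)
        T = rng.binomial(1, 0.4, 300)
        w = rng.uniform(1, 5, 300)
        assert ipw_ate(Y, T, w).ate == pytest.approx(
            ipw_ate(Y, T, 17.3 * w).ate, abs=1e-12)

    def test_analytic_ci_brackets_estimate(self, default_cohort):
        y = default_cohort.outcomes.iloc[:, 0].to_numpy()
        T = default_cohort.treatment
        e = estimate_propensity(
            default_cohort.covariates[default_cohort.covariate_names("confounder")],
            T).scores
        res = ipw_ate(y, T, trim_weights(ipw_weights(e, T)))
        assert res.ci_low <= res.ate <= res.ci_high
        assert 0 <= res.p_value <= 1

    def test_empty_arm_raises(self):
        with pytest.raises(DegenerateArmError):
            ipw_ate(np.ones(3), np.ones(3), np.ones(3))


class TestAipw:
    def test_agrees_with_ipw_when_both_models_correct(self):
        c = generate_cohort(SimulationConfig(n_subjects=5000, seed=31))
        conf = c.covariate_names("confounder")
        y = c.outcomes.iloc[:, 0].to_numpy()
        e = estimate_propensity(c.covariates[conf], c.treatment).scores
        ipw = ipw_ate(y, c.treatment, trim_weights(ipw_weights(e, c.treatment)))
        aipw = aipw_ate(y, c.treatment, c.covariates[conf])
        assert abs(ipw.ate - aipw.ate) < 0.1  # same data, MC tolerance

    def test_robust_to_garbage_propensity(self):
        """Correct outcome model, shuffled propensity scores."""
        errs = []
        for seed in range(10):
            c = generate_cohort(SimulationConfig(n_subjects=5000, seed=seed))
            conf = c.covariate_names("confounder")
            y = c.outcomes.iloc[:, 0].to_numpy()
            rng = np.random.default_rng(seed)
            e = rng.permutation(
                estimate_propensity(c.covariates[conf], c.treatment).scores)
            res = aipw_ate(y, c.treatment, c.covariates[conf], propensity=e)
            errs.append(res.ate - 0.5)
        assert abs(np.mean(errs)) < 0.05

    def test_robust_to_garbage_outcome_model(self):
        """Correct propensity, outcome model fit on shuffled covariates."""
        errs = []
        for seed in range(10):
            c = generate_cohort(SimulationConfig(n_subjects=5000, seed=seed))
            conf = c.covariate_names("confounder")
            y = c.outcomes.iloc[:, 0].to_numpy()
            rng = np.random.default_rng(seed)
            Xg = c.covariates[conf].sample(frac=1.0, random_state=seed)
            Xg.index = range(len(Xg))
            from causalkit.estimation import _arm_linear_predictions
            m1, m0 = _arm_linear_predictions(y, c.treatment, Xg.to_numpy())
            res = aipw_ate(y, c.treatment, c.covariates[conf],
                           outcome_predictions=(m1, m0))
            errs.append(res.ate - 0.5)
        assert abs(np.mean(errs)) < 0.05


class TestBootstrapInference:
    def test_constant_estimator_zero_width(self):
        boot = bootstrap_inference(lambda y: 1.23, (np.arange(50.0),),
                                   B=100, seed=0)
        assert boot.ci_low == boot.ci_high == 1.23
        assert boot.p_value == pytest.approx(1 / 101)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(200)
        t = rng.binomial(1, 0.5, 200)
        est = lambda yy, tt: naive_ate((yy, tt))
        b1 = bootstrap_inference(est, (y, t), B=200, seed=99)
        b2 = bootstrap_inference(est, (y, t), B=200, seed=99)
        assert (b1.ci_low, b1.ci_high, b1.p_value) == (b2.ci_low, b2.ci_high,
                                                       b2.p_value)

    def test_failure_rate_above_five_percent_raises(self):
        calls = {"n": 0}

        def flaky(y):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise RuntimeError("boom")
            return float(np.mean(y))

        with pytest.raises(RuntimeError, match="replicates failed"):
            bootstrap_inference(flaky, (np.arange(30.0),), B=100, seed=1)

    def test_b_below_two_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_inference(lambda y: 0.0, (np.arange(5.0),), B=1)


@pytest.fixture(scope="module")
def small_fit():
    c = generate_cohort(SimulationConfig(
        n_subjects=800, n_confounders=0, n_instruments=0, n_noise=6,
        latent_dim=1, latent_strength=1.0, seed=41))
    y = c.outcomes.iloc[:, 0].to_numpy()
    cfg = CEVAEConfig(epochs=20, mc_samples=50, seed=41)
    model = fit_cevae(c.covariates, c.treatment, y, cfg)
    return c, y, model


class TestCevae:
    def test_kl_of_standard_normal_is_zero(self):
        mu = np.zeros((10, 2))
        logvar = np.zeros((10, 2))
        assert gaussian_kl(mu, logvar) == pytest.approx(np.zeros(10), abs=1e-14)

    def test_kl_matches_closed_form(self):
        rng = np.random.default_rng(6)
        mu = rng.standard_normal((20, 3))
        logvar = rng.uniform(-1, 1, (20, 3))
        sigma2 = np.exp(logvar)
        closed = 0.5 * np.sum(sigma2 + mu ** 2 - 1 - np.log(sigma2), axis=1)
        assert gaussian_kl(mu, logvar) == pytest.approx(closed, abs=1e-10)
        assert np.all(gaussian_kl(mu, logvar) >= 0)

    def test_reconstruction_term_matches_manual_recomputation(self, small_fit):
        """Recompute log p(X,T,Y|z) from the decoder outputs by hand on one
        batch; with beta=0 the objective is exactly this term."""
        c, y, model = small_fit
        Xs, Ts, Ys = model._standardize(c.covariates.to_numpy(), c.treatment, y)
        rng = np.random.default_rng(0)
        mu, logvar = model.encode(Xs, Ts, Ys)
        z = mu + rng.standard_normal(mu.shape) * np.exp(0.5 * logvar)
        recon = model._reconstruction(z, Xs, Ts, Ys)

        mx = model.dec_x.forward(z)
        lx = -0.5 * np.sum(np.log(2 * np.pi) + model.logvar_x
                           + (Xs - mx) ** 2 / np.exp(model.logvar_x), axis=1)
        logit = model.dec_t.forward(z)[:, 0]
        pt = 1 / (1 + np.exp(-logit))
        lt = np.log(np.where(Ts == 1, pt, 1 - pt))
        my0 = model.dec_y0.forward(z)[:, 0]
        my1 = model.dec_y1.forward(z)[:, 0]
        my = np.where(Ts == 1, my1, my0)
        ly = -0.5 * (np.log(2 * np.pi) + model.logvar_y[0]
                     + (Ys - my) ** 2 / np.exp(model.logvar_y[0]))
        assert recon == pytest.approx(lx + lt + ly, abs=1e-9)
        _, kl = model.elbo_terms(c.covariates.to_numpy(), c.treatment, y)
        assert np.all(kl >= 0)

    def test_kl_nonnegative_during_training(self, small_fit):
        _, _, model = small_fit
        assert np.all(np.asarray(model.kl_curve) >= 0)

    def test_training_loss_decreases(self, small_fit):
        _, _, model = small_fit
        first = np.mean(model.loss_curve[:3])
        last = np.mean(model.loss_curve[-3:])
        assert last < first

    def test_null_wiring_gives_exactly_zero_ate(self, small_fit):
        import copy

        _, _, model = small_fit
        tied = copy.deepcopy(model)
        tied.dec_y1.W = [w.copy() for w in tied.dec_y0.W]
        tied.dec_y1.b = [b.copy() for b in tied.dec_y0.b]
        res = tied.ate(mc_samples=20)
        assert res.ate == 0.0

    def test_mc_sample_consistency(self, small_fit):
        _, _, model = small_fit
        few = model.ate(mc_samples=5)
        many = model.ate(mc_samples=400)
        band = 4 * many.se / np.sqrt(5) + 4 * many.se / np.sqrt(400)
        assert abs(few.ate - many.ate) <= band + 1e-9

    def test_invalid_mc_samples_rejected(self, small_fit):
        _, _, model = small_fit
        with pytest.raises(ValueError):
            model.ate(mc_samples=0)
        with pytest.raises(ValueError):
            CEVAEConfig(mc_samples=0).validate()


class TestAlternativeModes:
    def test_horvitz_thompson_mode_not_rescale_invariant(self):
        rng = np.random.default_rng(8)
        Y = rng.standard_normal(300)
        T = rng.binomial(1, 0.4, 300)
        e = rng.uniform(0.2, 0.8, 300)
        w = ipw_weights(e, T)
        ht = ipw_ate(Y, T, w, normalize=False)
        # HT with true-weight structure: mean of w*y per arm over n
        n = len(Y)
        expected = (np.sum(w * Y * (T == 1)) - np.sum(w * Y * (T == 0))) / n
        assert ht.ate == pytest.approx(expected, abs=1e-12)
        # doubling the weights doubles the HT estimate (no invariance)
        assert ipw_ate(Y, T, 2 * w, normalize=False).ate == pytest.approx(
            2 * ht.ate, abs=1e-10)

    def test_exclusion_trim_mode_zeroes_tails(self):
        w = np.arange(1.0, 101.0)
        out = trim_weights(w, 5, 95, mode="exclude")
        lo, hi = np.percentile(w, [5, 95])
        assert np.all(out[(w < lo) | (w > hi)] == 0.0)
        interior = (w >= lo) & (w <= hi)
        assert np.all(out[interior] == w[interior])

    def test_unknown_trim_mode_rejected(self):
        with pytest.raises(ValueError):
            trim_weights(np.ones(5), mode="drop")
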