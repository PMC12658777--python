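"""Average treatment effect estimation: trimmed IPW, AIPW, bootstrap
inference, and a causal-effect variational autoencoder for latent
confounding.

The inverse-probability-weighted (IPW) estimator fits a logistic propensity
model e_i = P(T_i = 1 | X_i) on the selected confounders, forms weights
w_i = 1/e_i for treated and 1/(1-e_i) for untreated subjects, winsorizes
them at the 1st/99th percentiles to tame extreme scores, and compares
weight-normalized (Hájek) outcome means between arms.  The augmented IPW
(AIPW) estimator adds per-arm linear outcome regressions, yielding double
robustness: consistency if either the propensity or the outcome model is
correct.  Percentile bootstrap over row-resamples provides nonparametric
intervals and p-values.

The CEVAE posits a latent confounder z with generative structure
z ~ p(z), T ~ p(T|z), X ~ p(X|z), Y ~ p(Y|T,z); an encoder q(z|X,T,Y)
(Gaussian) and three decoder branches are trained by maximizing the
evidence lower bound with a beta-weighted KL term,

    ELBO = E_q[log p(X,T,Y|z)] - beta * KL(q(z|X,T,Y) || p(z)),

and the ATE is read from the Y-decoder as the Monte-Carlo average of
p(Y|T=1,z) - p(Y|T=0,z) with MC-dropout sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from ._nn import MLP, Adam
from .synthcohort import DegenerateArmError

__all__ = [
    "PropensityFit",
    "ATEResult",
    "CEVAEConfig",
    "CEVAE",
    "BootstrapResult",
    "TrainingFailureError",
    "estimate_propensity",
    "ipw_weights",
    "trim_weights",
    "ipw_ate",
    "aipw_ate",
    "bootstrap_inference",
    "fit_cevae",
    "cevae_ate",
    "gaussian_kl",
]

_CLIP = 1e-6


class TrainingFailureError(RuntimeError):
    """Variational training diverged (NaN loss)."""


@dataclass
class PropensityFit:
    scores: np.ndarray  # in (0,1) after clipping
    coefficients: np.ndarray  # intercept first
    covariate_names: list


@dataclass
class ATEResult:
    method: str  # {ipw, aipw, cevae, naive}
    ate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_treated: int
    n_untreated: int
    se: float = float("nan")
    boot_ci_low: float = float("nan")
    boot_ci_high: float = float("nan")
    boot_p: float = float("nan")

    def with_bootstrap(self, boot: "BootstrapResult") -> "ATEResult":
        self.boot_ci_low, self.boot_ci_high = boot.ci_low, boot.ci_high
        self.boot_p = boot.p_value
        return self


def _to_matrix(X):
    if X is None:
        return np.empty((0, 0)), []
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j + 1}" for j in range(X.shape[1])]


def estimate_propensity(X_conf, T) -> PropensityFit:
    """Logistic propensity model of T on the selected confounders.

    Scores are clipped to [1e-6, 1 - 1e-6].  Perfect separation degrades to
    a warning (ridge-regularized refit) rather than an error, since clipped
    scores remain usable for weighting.
    """
    T = np.asarray(T, dtype=float)
    Xm, names = _to_matrix(X_conf)
    if Xm.size and np.isnan(Xm).any():
        raise ValueError("confounder matrix contains missing cells")
    if Xm.size == 0 or Xm.shape[1] == 0:
        rate = float(np.clip(T.mean(), _CLIP, 1 - _CLIP))
        return PropensityFit(np.full(len(T), rate),
                             np.array([np.log(rate / (1 - rate))]), [])
    design = sm.add_constant(Xm, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(T, design).fit(disp=0, maxiter=100)
        coefs = np.asarray(fit.params)
        scores = np.asarray(fit.predict(design))
        if not np.isfinite(scores).all():
            raise ValueError("non-finite scores")
    except Exception:
        warnings.warn("propensity fit unstable (possible perfect separation); "
                      "falling back to a ridge-regularized fit", stacklevel=2)
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e4, max_iter=2000)
        lr.fit(Xm, T.astype(int))
        coefs = np.concatenate([lr.intercept_, lr.coef_[0]])
        scores = lr.predict_proba(Xm)[:, 1]
    return PropensityFit(np.clip(scores, _CLIP, 1 - _CLIP), coefs, names)


def ipw_weights(e, T) -> np.ndarray:
    """Inverse-propensity weights: 1/e for treated, 1/(1-e) for untreated."""
    e = np.asarray(e, dtype=float)
    T = np.asarray(T)
    if np.any(e <= 0) or np.any(e >= 1):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    return np.where(T == 1, 1.0 / e, 1.0 / (1.0 - e))


def trim_weights(w, lower_pct: float = 1.0, upper_pct: float = 99.0,
                 mode: str = "winsorize") -> np.ndarray:
    """Winsorize weights at the given percentiles (linear interpolation).

    Values below the lower percentile are raised to it and values above the
    upper percentile lowered to it; sample size is preserved.  Because the
    cut points are recomputed from the input, re-trimming can contract the
    range slightly further (interpolated percentiles move once the tails are
    clamped); the weight range is monotonically non-expanding under
    repeated application and constant vectors are fixed points.

    ``mode="exclude"`` instead zeroes the weights outside the percentile
    band (subject exclusion rather than clamping).
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    if mode not in ("winsorize", "exclude"):
        raise ValueError("mode must be 'winsorize' or 'exclude'")
    w = np.asarray(w, dtype=float)
    lo, hi = np.percentile(w, [lower_pct, upper_pct])
    if mode == "exclude":
        return np.where((w < lo) | (w > hi), 0.0, w)
    return np.clip(w, lo, hi)


def _check_arms(T):
    T = np.asarray(T)
    n1, n0 = int((T == 1).sum()), int((T == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateArmError("both treatment arms must be nonempty")
    return n1, n0


def ipw_ate(Y, T, w, method: str = "ipw", normalize: bool = True) -> ATEResult:
    """Hájek (weight-normalized) IPW contrast of outcome means.

    ATE = sum(w y T)/sum(w T) - sum(w y (1-T))/sum(w (1-T)).  With
    ``normalize=False`` the Horvitz-Thompson form divides by the sample
    size instead of the weight sums (not invariant to weight rescaling).
    The analytic CI uses a robust variance approximation for ratio-form
    weighted means (weights treated as fixed); p-value from a normal
    reference.
    """
    Y = np.asarray(Y, dtype=float)
    T = np.asarray(T)
    w = np.asarray(w, dtype=float)
    n1, n0 = _check_arms(T)
    t_mask, c_mask = T == 1, T == 0
    if normalize:
        sw1, sw0 = w[t_mask].sum(), w[c_mask].sum()
    else:
        sw1 = sw0 = float(len(T))
    mu1 = float(w[t_mask] @ Y[t_mask] / sw1)
    mu0 = float(w[c_mask] @ Y[c_mask] / sw0)
    ate = mu1 - mu0
    if normalize:
        var1 = float(np.sum((w[t_mask] * (Y[t_mask] - mu1)) ** 2) / sw1 ** 2)
        var0 = float(np.sum((w[c_mask] * (Y[c_mask] - mu0)) ** 2) / sw0 ** 2)
    else:
        var1 = float(np.sum((w[t_mask] * Y[t_mask] - mu1) ** 2) / sw1 ** 2)
        var0 = float(np.sum((w[c_mask] * Y[c_mask] - mu0) ** 2) / sw0 ** 2)
    se = np.sqrt(var1 + var0)
    z = ate / se if se > 0 else np.inf * np.sign(ate)
    p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return ATEResult(method, ate, ate - 1.96 * se, ate + 1.96 * se, p,
                     n1, n0, se=se)


def _arm_linear_predictions(Y, T, Xm):
    """Per-arm OLS fits; returns predicted (m1, m0) for all subjects."""
    design = np.column_stack([np.ones(len(Y)), Xm]) if Xm.size else np.ones((len(Y), 1))
    preds = {}
    for arm in (1, 0):
        mask = T == arm
        coef, *_ = np.linalg.lstsq(design[mask], Y[mask], rcond=None)
        preds[arm] = design @ coef
    return preds[1], preds[0]


def aipw_ate(Y, T, X_conf, propensity=None, outcome_predictions=None,
             trim=(1.0, 99.0)) -> ATEResult:
    """Doubly robust augmented-IPW estimator.

    Combines inverse-propensity weighting with per-arm linear outcome-model
    predictions; the influence-function form is consistent if either model
    is correctly specified.  ``propensity`` and ``outcome_predictions``
    accept externally supplied values (used e.g. in misspecification
    studies); by default both are fit internally.
    """
    Y = np.asarray(Y, dtype=float)
    T = np.asarray(T)
    Xm, _ = _to_matrix(X_conf)
    n1, n0 = _check_arms(T)
    if propensity is None:
        e = estimate_propensity(X_conf, T).scores
    else:
        e = np.clip(np.asarray(propensity, dtype=float), _CLIP, 1 - _CLIP)
    if trim is not None:
        # winsorize the implied weights, then map back to scores per arm
        w = trim_weights(ipw_weights(e, T), *trim)
        inv = 1.0 / w
        e = np.where(T == 1, inv, 1.0 - inv)
        e = np.clip(e, _CLIP, 1 - _CLIP)
    if outcome_predictions is None:
        m1, m0 = _arm_linear_predictions(Y, T, Xm)
    else:
        m1, m0 = (np.asarray(m, dtype=float) for m in outcome_predictions)
    Tf = (T == 1).astype(float)
    psi = (m1 - m0
           + Tf * (Y - m1) / e
           - (1 - Tf) * (Y - m0) / (1 - e))
    ate = float(psi.mean())
    se = float(psi.std(ddof=1) / np.sqrt(len(psi)))
    z = ate / se if se > 0 else np.inf * np.sign(ate)
    p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return ATEResult("aipw", ate, ate - 1.96 * se, ate + 1.96 * se, p,
                     n1, n0, se=se)


@dataclass
class BootstrapResult:
    ci_low: float
    ci_high: float
    p_value: float
    estimates: np.ndarray
    n_dropped: int = 0


def bootstrap_inference(estimator, data, B: int = 1000, seed: int = 0,
                        alpha: float = 0.05) -> BootstrapResult:
    """Percentile bootstrap over joint row-resamples.

    ``estimator`` maps the resampled arrays in ``data`` to a scalar.  The
    two-sided p-value against zero is 2*min(frac <= 0, frac >= 0) with a
    continuity floor of 1/(B+1).  Replicates on which the estimator raises
    are dropped and counted; more than 5% drops is a failure.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    estimates = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            estimates.append(float(estimator(*(a[idx] for a in arrays))))
        except Exception:
            dropped += 1
    if dropped > 0.05 * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates failed")
    est = np.asarray(estimates)
    lo, hi = np.percentile(est, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    frac_le = float((est <= 0).mean())
    frac_ge = float((est >= 0).mean())
    p = max(2 * min(frac_le, frac_ge), 1.0 / (B + 1))
    return BootstrapResult(float(lo), float(hi), float(min(p, 1.0)), est, dropped)


# --------------------------------------------------------------------------
# CEVAE
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CEVAEConfig:
    latent_dim: int = 1
    beta: float = 0.5
    mc_samples: int = 1000
    epochs: int = 60
    hidden_width: int = 32
    learning_rate: float = 5e-3
    dropout_rate: float = 0.1
    batch_size: int = 512
    seed: int = 20250125

    def validate(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")


def gaussian_kl(mu, logvar) -> np.ndarray:
    """KL(N(mu, exp(logvar)) || N(0, 1)), summed over latent dimensions."""
    return 0.5 * np.sum(np.exp(logvar) + mu ** 2 - 1.0 - logvar, axis=-1)


class CEVAE:
    """Causal-effect VAE with Gaussian encoder and three decoder branches.

    The outcome branch p(Y|T, z) is realized as two potential-outcome heads
    (one per treatment arm), so the treatment contrast is expressed
    structurally rather than through a single scalar input.  Inputs are
    standardized internally; the ATE is reported on the original outcome
    scale.  The outcome heads carry dropout in their hidden layers so
    Monte-Carlo dropout can express model uncertainty at inference.
    """

    def __init__(self, config: CEVAEConfig, n_features: int):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, L = config.hidden_width, config.latent_dim
        self.encoder = MLP([n_features + 2, h, h, 2 * L], rng)
        self.dec_x = MLP([L, h, n_features], rng)
        self.dec_t = MLP([L, h, 1], rng)
        # two potential-outcome heads: p(Y | T=0, z) and p(Y | T=1, z)
        self.dec_y0 = MLP([L, h, 1], rng, dropout_rate=config.dropout_rate)
        self.dec_y1 = MLP([L, h, 1], rng, dropout_rate=config.dropout_rate)
        self.logvar_x = np.zeros(n_features)
        self.logvar_y = np.zeros(1)
        self.loss_curve = []
        self.kl_curve = []
        self._rng = rng

    @property
    def params(self):
        return [*self.encoder.params, *self.dec_x.params, *self.dec_t.params,
                *self.dec_y0.params, *self.dec_y1.params,
                self.logvar_x, self.logvar_y]

    # ---- internals -------------------------------------------------------

    def _standardize(self, X, T, Y):
        Xs = (np.asarray(X, dtype=float) - self.x_mu) / self.x_sd
        Ys = (np.asarray(Y, dtype=float) - self.y_mu) / self.y_sd
        return Xs, np.asarray(T, dtype=float), Ys

    def encode(self, Xs, Ts, Ys):
        out = self.encoder.forward(np.column_stack([Xs, Ts, Ys]))
        L = self.config.latent_dim
        return out[:, :L], out[:, L:]

    def elbo_terms(self, X, T, Y, rng=None):
        """Monte-Carlo (single-sample) reconstruction and KL terms per subject."""
        rng = rng or np.random.default_rng(self.config.seed + 99)
        Xs, Ts, Ys = self._standardize(X, T, Y)
        mu, logvar = self.encode(Xs, Ts, Ys)
        eps = rng.standard_normal(mu.shape)
        z = mu + eps * np.exp(0.5 * logvar)
        recon = self._reconstruction(z, Xs, Ts, Ys)
        return recon, gaussian_kl(mu, logvar)

    def _reconstruction(self, z, Xs, Ts, Ys, dropout_rng=None):
        mx = self.dec_x.forward(z)
        lx = -0.5 * np.sum(np.log(2 * np.pi) + self.logvar_x
                           + (Xs - mx) ** 2 / np.exp(self.logvar_x), axis=1)
        logit = self.dec_t.forward(z)[:, 0]
        lt = Ts * logit - np.logaddexp(0.0, logit)
        my0 = self.dec_y0.forward(z, dropout_rng=dropout_rng)[:, 0]
        my1 = self.dec_y1.forward(z, dropout_rng=dropout_rng)[:, 0]
        my = Ts * my1 + (1.0 - Ts) * my0
        ly = -0.5 * (np.log(2 * np.pi) + self.logvar_y[0]
                     + (Ys - my) ** 2 / np.exp(self.logvar_y[0]))
        return lx + lt + ly

    def _train_step(self, Xb, Tb, Yb, opt, rng):
        """One minibatch gradient step on -ELBO; returns (loss, mean KL)."""
        B = len(Yb)
        cfg = self.config
        mu, logvar = self.encode(Xb, Tb, Yb)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + eps * std

        var_x = np.exp(self.logvar_x)
        mx = self.dec_x.forward(z)
        logit = self.dec_t.forward(z)[:, 0]
        my0 = self.dec_y0.forward(z, dropout_rng=rng)[:, 0]
        my1 = self.dec_y1.forward(z, dropout_rng=rng)[:, 0]
        my = Tb * my1 + (1.0 - Tb) * my0
        var_y = np.exp(self.logvar_y[0])

        lx = -0.5 * np.sum(np.log(2 * np.pi) + self.logvar_x
                           + (Xb - mx) ** 2 / var_x, axis=1)
        lt = Tb * logit - np.logaddexp(0.0, logit)
        ly = -0.5 * (np.log(2 * np.pi) + self.logvar_y[0] + (Yb - my) ** 2 / var_y)
        kl = gaussian_kl(mu, logvar)
        loss = float(np.mean(-(lx + lt + ly) + cfg.beta * kl))
        if not np.isfinite(loss):
            raise TrainingFailureError("CEVAE loss is not finite")

        # gradients of the mean over the batch
        d_mx = (mx - Xb) / var_x / B
        d_logit = (expit(logit) - Tb)[:, None] / B
        d_my = ((my - Yb) / var_y / B)[:, None]
        g_lvx = 0.5 * np.sum(1.0 - (Xb - mx) ** 2 / var_x, axis=0) / B
        g_lvy = np.array([0.5 * np.sum(1.0 - (Yb - my) ** 2 / var_y) / B])

        dz = self.dec_x.backward(d_mx)
        dz = dz + self.dec_t.backward(d_logit)
        dz = dz + self.dec_y0.backward(d_my * (1.0 - Tb)[:, None])
        dz = dz + self.dec_y1.backward(d_my * Tb[:, None])

        d_mu = dz + cfg.beta * mu / B
        d_logvar = dz * eps * 0.5 * std + cfg.beta * 0.5 * (np.exp(logvar) - 1.0) / B
        self.encoder.backward(np.column_stack([d_mu, d_logvar]))

        grads = [*self.encoder.grads, *self.dec_x.grads, *self.dec_t.grads,
                 *self.dec_y0.grads, *self.dec_y1.grads, g_lvx, g_lvy]
        opt.step(grads)
        return loss, float(kl.mean())

    # ---- public API ------------------------------------------------------

    def fit(self, X, T, Y):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("X contains missing cells")
        self.x_mu, self.x_sd = X.mean(axis=0), X.std(axis=0)
        self.x_sd[self.x_sd == 0] = 1.0
        Y = np.asarray(Y, dtype=float)
        self.y_mu, self.y_sd = float(Y.mean()), float(Y.std()) or 1.0
        Xs, Ts, Ys = self._standardize(X, T, Y)
        self._train_data = (Xs, Ts, Ys)

        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(self.params, lr=cfg.learning_rate)
        n = len(Ys)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, kl = self._train_step(Xs[idx], Ts[idx], Ys[idx], opt, rng)
                epoch_loss += loss
                n_batches += 1
                self.kl_curve.append(kl)
            self.loss_curve.append(epoch_loss / n_batches)
        return self

    def ate(self, X=None, T=None, Y=None, mc_samples=None) -> ATEResult:
        """Monte-Carlo ATE: average of p(Y|T=1,z) - p(Y|T=0,z).

        For each draw, z is sampled from the encoder posterior (conditioning
        on observed X, T, Y) and the dropout masks of the Y-decoder are
        resampled; the same z and masks serve both potential-outcome arms.
        The interval is the 2.5/97.5 percentile of the per-draw population
        ATEs (spread over MC samples).
        """
        cfg = self.config
        mc = cfg.mc_samples if mc_samples is None else mc_samples
        if mc < 1:
            raise ValueError("mc_samples must be >= 1")
        if X is None:
            Xs, Ts, Ys = self._train_data
        else:
            Xs, Ts, Ys = self._standardize(X, T, Y)
        mu, logvar = self.encode(Xs, Ts, Ys)
        std = np.exp(0.5 * logvar)
        rng = np.random.default_rng(cfg.seed + 7)
        draws = np.empty(mc)
        for s in range(mc):
            z = mu + rng.standard_normal(mu.shape) * std
            mask_seed = int(rng.integers(0, 2 ** 31))
            # identical dropout masks for both potential-outcome heads
            y1 = self.dec_y1.forward(z, dropout_rng=np.random.default_rng(mask_seed))[:, 0]
            y0 = self.dec_y0.forward(z, dropout_rng=np.random.default_rng(mask_seed))[:, 0]
            draws[s] = float(np.mean(y1 - y0))
        draws *= self.y_sd
        ate = float(draws.mean())
        if mc > 1:
            lo, hi = np.percentile(draws, [2.5, 97.5])
            se = float(draws.std(ddof=1))
        else:
            lo = hi = ate
            se = 0.0
        z_stat = ate / se if se > 0 else np.inf * np.sign(ate) if ate else 0.0
        p = float(2 * norm.sf(abs(z_stat))) if np.isfinite(z_stat) else 1.0
        n1 = int(np.sum(Ts == 1))
        return ATEResult("cevae", ate, float(lo), float(hi), p,
                         n1, len(Ts) - n1, se=se)


def fit_cevae(X, T, Y, config: CEVAEConfig = CEVAEConfig()) -> CEVAE:
    """Train a CEVAE on standardized (X, T, Y)."""
    Xm, _ = _to_matrix(X)
    model = CEVAE(config, Xm.shape[1])
    return model.fit(Xm, T, Y)


def cevae_ate(model: CEVAE, X=None, T=None, Y=None, mc_samples=None,
              config: CEVAEConfig | None = None) -> ATEResult:
    """Monte-Carlo ATE from a fitted CEVAE (see :meth:`CEVAE.ate`)."""
    if config is not None:
        mc_samples = mc_samples or config.mc_samples
    return model.ate(X, T, Y, mc_samples=mc_samples)
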