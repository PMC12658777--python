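"""Synthetic observational cohorts with known causal ground truth.

Generates rectangular cohorts that mimic the statistical structure of
registry data on moderate-to-severe brain injury: a mix of continuous and
binary baseline covariates, a latent severity factor influencing both
treatment assignment and outcomes, logistic treatment assignment driven by a
subset of covariates (confounding by indication), linear-plus-noise outcomes
with a known constant additive treatment effect, an optional continuous
exposure (days to rehabilitation admission) for extreme-contrast
binarization, and registry-style integer placeholder codes for missingness.

Every draw is fully reproducible from ``(config, seed)`` and the generating
coefficients are recorded in a truth ledger so downstream estimators can be
scored against the exact data-generating process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "InvalidConfigError",
    "DegenerateArmError",
    "generate_cohort",
    "inject_special_codes",
    "naive_ate",
    "write_cohort",
]


class InvalidConfigError(ValueError):
    """A simulation configuration violates its preconditions."""


class DegenerateArmError(ValueError):
    """An estimator was asked to compare arms and one arm is empty."""


# Loading of the latent factor onto continuous covariates.  Making measured
# covariates noisy proxies of the latent severity factor is what renders
# latent-confounder recovery well-posed: the latent generates X as well as
# entering T and Y.
_PROXY_LOADING = 0.8
# Lognormal parameters for days-to-rehabilitation: median ~12 days with both
# the <=4.5-day and >=45-day tails populated.
_DAYS_LOG_MEAN = 2.5
_DAYS_SEVERITY_LOADING = 0.9
_DAYS_LOG_NOISE_SD = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic data-generating process.

    ``n_confounders`` covariates affect both treatment and outcome,
    ``n_instruments`` affect treatment only, ``n_noise`` affect neither.
    ``confounding_strength`` scales the confounder coefficients in both the
    treatment and outcome models; ``latent_strength`` does the same for the
    latent factor.  ``true_ate`` is a constant additive effect in outcome
    units.
    """

    n_subjects: int = 5000
    n_confounders: int = 10
    n_instruments: int = 5
    n_noise: int = 5
    latent_dim: int = 1
    true_ate: float = 0.5
    confounding_strength: float = 1.0
    latent_strength: float = 0.0
    outcome_noise_sd: float = 1.0
    n_outcomes: int = 1
    exposure_mode: str = "binary"  # {"binary", "continuous-days"}
    missing_rate: float = 0.0
    special_codes: tuple = (999, -1)
    treated_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 20:
            raise InvalidConfigError("n_subjects must be >= 20")
        for name in ("n_confounders", "n_instruments", "n_noise", "latent_dim"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.outcome_noise_sd <= 0:
            raise InvalidConfigError("outcome_noise_sd must be > 0")
        if self.confounding_strength < 0 or self.latent_strength < 0:
            raise InvalidConfigError("strength parameters must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if self.exposure_mode not in ("binary", "continuous-days"):
            raise InvalidConfigError(f"unknown exposure_mode {self.exposure_mode!r}")
        if self.n_outcomes < 1:
            raise InvalidConfigError("n_outcomes must be >= 1")
        if not (0 < self.treated_fraction < 1):
            raise InvalidConfigError("treated_fraction must lie in (0, 1)")

    @property
    def n_covariates(self) -> int:
        return self.n_confounders + self.n_instruments + self.n_noise


@dataclass
class SyntheticCohort:
    """A generated cohort plus its complete truth ledger.

    ``latent`` and ``true_propensity`` are hidden from estimators in normal
    use; they exist so tests can score estimates against the generating
    model.
    """

    covariates: pd.DataFrame
    roles: dict  # column name -> {"confounder", "instrument", "noise"}
    latent: np.ndarray
    treatment: np.ndarray
    outcomes: pd.DataFrame
    true_propensity: np.ndarray
    true_ate: float
    exposure_days: np.ndarray | None
    truth: dict
    config: SimulationConfig

    @property
    def n(self) -> int:
        return len(self.treatment)

    def covariate_names(self, role: str | None = None) -> list:
        if role is None:
            return list(self.covariates.columns)
        return [c for c, r in self.roles.items() if r == role]

    def to_frame(self, include_truth: bool = False) -> pd.DataFrame:
        """Rectangular table: treatment, outcomes, covariates (and optionally
        the truth columns)."""
        parts = [pd.Series(self.treatment, name="treatment"), self.outcomes,
                 self.covariates]
        if self.exposure_days is not None:
            parts.insert(1, pd.Series(self.exposure_days, name="exposure_days"))
        if include_truth:
            parts.append(pd.Series(self.true_propensity, name="true_propensity"))
            for j in range(self.latent.shape[1]):
                parts.append(pd.Series(self.latent[:, j], name=f"latent_{j + 1}"))
        return pd.concat(parts, axis=1)


def _column_spec(config: SimulationConfig):
    """Names, roles and types (continuous/binary) for every covariate.

    Within each role block columns alternate continuous and binary,
    mirroring a registry's mix of scales and binary imaging findings.
    """
    names, roles, is_binary = [], {}, {}
    for role, count, prefix in (
        ("confounder", config.n_confounders, "conf"),
        ("instrument", config.n_instruments, "inst"),
        ("noise", config.n_noise, "noise"),
    ):
        for i in range(count):
            name = f"{prefix}_{i + 1:02d}"
            names.append(name)
            roles[name] = role
            is_binary[name] = i % 2 == 1
    return names, roles, is_binary


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort from the configured generating model.

    Treatment is Bernoulli(expit(intercept + confounder score + instrument
    score + latent score)); each outcome is linear in the confounders plus a
    latent term, the constant treatment effect and Gaussian noise.  The
    intercept is solved so that the mean true propensity equals
    ``config.treated_fraction``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n, p = config.n_subjects, config.n_covariates
    names, roles, is_binary = _column_spec(config)

    latent = rng.standard_normal((n, config.latent_dim))

    X = np.empty((n, p))
    for j, name in enumerate(names):
        if is_binary[name]:
            X[:, j] = rng.binomial(1, 0.5, size=n).astype(float)
        else:
            X[:, j] = rng.standard_normal(n)
            if config.latent_dim > 0:
                # continuous covariates are noisy proxies of the latent factor
                X[:, j] += _PROXY_LOADING * latent[:, 0]

    # Generating coefficients: positive, so confounding bias grows
    # monotonically with confounding_strength.  Blocks are normalized by the
    # square root of their size so that the total confounding signal (and
    # hence overlap) is governed by the strength parameters, not by how many
    # covariates carry them.
    # At strength 1 the base draw U(0.15, 0.35) yields moderate confounding:
    # a naive-estimator bias of roughly 0.3 outcome units with propensities
    # staying inside ~(0.01, 0.98), i.e. confounding by indication without a
    # positivity violation.
    nc, ni = config.n_confounders, config.n_instruments
    alpha_conf = (config.confounding_strength / np.sqrt(max(nc, 1))
                  * rng.uniform(0.15, 0.35, size=nc))
    # instruments share the treatment-model scale so that zero strength
    # means a treatment assignment independent of every covariate
    alpha_inst = (config.confounding_strength / np.sqrt(max(ni, 1))
                  * rng.uniform(0.4, 0.8, size=ni))
    u_latent = rng.uniform(0.5, 1.0, size=config.latent_dim)

    Xc = X.copy()
    for j, name in enumerate(names):  # center binaries so prevalence is stable
        if is_binary[name]:
            Xc[:, j] -= 0.5

    score = np.zeros(n)
    if nc:
        score += Xc[:, :nc] @ alpha_conf
    if ni:
        score += Xc[:, nc:nc + ni] @ alpha_inst
    if config.latent_dim:
        score += config.latent_strength * (latent @ u_latent)

    def _prevalence(a0):
        return expit(a0 + score).mean() - config.treated_fraction

    intercept = brentq(_prevalence, -30.0, 30.0)
    propensity = expit(intercept + score)
    treatment = rng.binomial(1, propensity).astype(int)

    beta_conf = np.empty((config.n_outcomes, nc))
    v_latent = np.empty((config.n_outcomes, config.latent_dim))
    outcomes = {}
    for k in range(config.n_outcomes):
        beta_conf[k] = (config.confounding_strength / np.sqrt(max(nc, 1))
                        * rng.uniform(0.15, 0.35, size=nc))
        v_latent[k] = rng.uniform(0.5, 1.0, size=config.latent_dim)
        y = config.true_ate * treatment + config.outcome_noise_sd * rng.standard_normal(n)
        if nc:
            y += Xc[:, :nc] @ beta_conf[k]
        if config.latent_dim:
            y += config.latent_strength * (latent @ v_latent[k])
        outcomes[f"outcome_{k + 1}"] = y

    exposure_days = None
    if config.exposure_mode == "continuous-days":
        severity = latent[:, 0] if config.latent_dim else rng.standard_normal(n)
        log_days = (_DAYS_LOG_MEAN + _DAYS_SEVERITY_LOADING * severity
                    + _DAYS_LOG_NOISE_SD * rng.standard_normal(n))
        exposure_days = np.exp(log_days)

    truth = {
        "seed": config.seed,
        "true_ate": config.true_ate,
        "intercept_treatment": float(intercept),
        "alpha_confounders": alpha_conf.tolist(),
        "alpha_instruments": alpha_inst.tolist(),
        "latent_loading_treatment": u_latent.tolist(),
        "beta_confounders": beta_conf.tolist(),
        "latent_loading_outcome": v_latent.tolist(),
        "proxy_loading": _PROXY_LOADING if config.latent_dim else 0.0,
        "binary_columns": [c for c in names if is_binary[c]],
    }

    return SyntheticCohort(
        covariates=pd.DataFrame(X, columns=names),
        roles=roles,
        latent=latent,
        treatment=treatment,
        outcomes=pd.DataFrame(outcomes),
        true_propensity=propensity,
        true_ate=config.true_ate,
        exposure_days=exposure_days,
        truth=truth,
        config=config,
    )


def inject_special_codes(cohort: SyntheticCohort, config: SimulationConfig | None = None):
    """Replace a fraction of covariate cells (completely at random) with
    registry-style placeholder codes, returning a raw :class:`CohortTable`
    that carries no truth columns.
    """
    from .cohort import CohortTable  # local import to avoid a cycle

    config = config or cohort.config
    rate = config.missing_rate
    if rate > 0 and not config.special_codes:
        raise InvalidConfigError("special_codes must be nonempty when missing_rate > 0")

    frame = cohort.to_frame(include_truth=False)
    if rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0DE5]))
        cov_cols = list(cohort.covariates.columns)
        block = frame[cov_cols].to_numpy(copy=True)
        mask = rng.random(block.shape) < rate
        codes = np.asarray(config.special_codes, dtype=float)
        fills = codes[rng.integers(0, len(codes), size=block.shape)]
        block[mask] = fills[mask]
        frame[cov_cols] = block
    return CohortTable(frame=frame)


def naive_ate(cohort) -> float:
    """Unadjusted difference in outcome means between arms.

    Accepts a :class:`SyntheticCohort` (first outcome) or a ``(Y, T)`` pair.
    """
    if isinstance(cohort, SyntheticCohort):
        y = cohort.outcomes.iloc[:, 0].to_numpy()
        t = cohort.treatment
    else:
        y, t = (np.asarray(a, dtype=float) for a in cohort)
    t = np.asarray(t)
    if not (t == 1).any() or not (t == 0).any():
        raise DegenerateArmError("both treatment arms must be nonempty")
    return float(y[t == 1].mean() - y[t == 0].mean())


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write the cohort table as CSV and the truth ledger as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "cohort.csv"
    cohort.to_frame().to_csv(csv_path, index=False, encoding="utf-8")
    ledger_path = out / "truth_ledger.json"
    ledger = dict(cohort.truth)
    ledger["config"] = asdict(cohort.config)
    ledger["config"]["special_codes"] = list(ledger["config"]["special_codes"])
    ledger_path.write_text(json.dumps(ledger, indent=2))
    return {"cohort": str(csv_path), "truth_ledger": str(ledger_path)}
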