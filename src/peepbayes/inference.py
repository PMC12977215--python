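"""Hierarchical Bayesian models for the three trial outcomes.

Three likelihoods share one structure — a fixed treatment effect theta, a
hospital random intercept b_h ~ Normal(0, tau^2) with tau ~ Half-Normal,
and outcome-specific nuisance parameters:

* VFD (ordinal 0-28): proportional-odds cumulative logistic,
  ``P(Y >= k) = expit(theta * I(lower) + b_h - alpha_k)`` with strictly
  increasing cut-points alpha_1 < ... < alpha_28.  theta > 0 (OR > 1)
  means higher cumulative odds of more ventilator-free days, i.e. benefit.
* 28-day mortality (binary): hierarchical logistic regression; OR < 1 is
  benefit.
* Ventilation duration among survivors (continuous, days): hierarchical
  linear regression with Normal residuals; MD < 0 is benefit.

Sampling uses an ensemble MCMC (differential-evolution and stretch moves)
over an unconstrained parameterization: hospital effects are non-centred
(b = tau * z); tau is sampled through an unconstrained u with tau = |u|
and u ~ Normal(0, s), whose absolute value is exactly Half-Normal(s) and
avoids both the hard boundary at zero and the log-scale tail; the residual
SD is sampled on the log scale with its Half-Normal prior plus Jacobian;
ordinal cut-points are a free first cut-point plus log-gaps.  Each fit runs
``n_chains`` fully independent ensembles; split-R-hat compares the
ensembles and bulk ESS comes from per-walker autocorrelation (arviz).
Fits failing the convergence gate (R-hat <= 1.01, ESS >= 400 on theta and
tau) are flagged with a warning, never silently returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .priors import HeterogeneityPrior, PriorSpec
from .trial_data import Arm, TrialDataset

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: Weakly informative scales for nuisance parameters, deliberately much wider
#: than any registry treatment prior so the registry priors dominate theta.
INTERCEPT_PRIOR_SD = 5.0
CUTPOINT_PRIOR_SD = 5.0
RESIDUAL_SD_PRIOR_SCALE = 5.0

#: Protocol subgroup dichotomizations for interaction models.
SUBGROUP_DEFINITIONS = {
    "cardiac_arrest": ("cardiac_arrest", None),
    "surgical_admission": ("surgical_admission", None),
    "primary_respiratory_failure": ("primary_respiratory_failure", None),
    "bmi": ("bmi", lambda x: x > 30.0),
    "pf_ratio": ("pf_ratio", lambda x: x <= 200.0),
    "lips": ("lips", lambda x: x >= 4.0),
    "apache": ("apache", lambda x: x >= 86.0),
}


class ConvergenceWarning(UserWarning):
    pass


class ModelError(ValueError):
    pass


@dataclass
class HierarchicalModelSpec:
    outcome: str  # "vfd" | "mortality_28d" | "duration"
    treatment_prior: PriorSpec
    heterogeneity_prior: HeterogeneityPrior = field(default_factory=HeterogeneityPrior)
    n_chains: int = 4
    n_warmup: int = 1500
    n_draws: int = 1000
    seed: int = 0
    thin: int = 10
    tau_fixed: Optional[float] = None  # fix tau (0 removes the hierarchy); None = sample
    interaction_covariate: Optional[str] = None
    interaction_prior: Optional[PriorSpec] = None

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ModelError("n_chains must be >= 2")
        if self.n_draws < 1 or self.n_warmup < 0:
            raise ModelError("invalid sampler settings")


@dataclass
class PosteriorDraws:
    """Flattened posterior draws (length n_chains * n_draws) plus diagnostics."""

    outcome: str
    effect_scale: str
    theta: np.ndarray
    tau: np.ndarray
    nuisance: dict[str, np.ndarray]
    diagnostics: dict[str, float | bool]
    seed: int
    n_chains: int
    n_draws: int

    @property
    def interaction(self) -> Optional[np.ndarray]:
        return self.nuisance.get("interaction")


# --------------------------------------------------------------------------
# numerically stable logistic helpers (vectorized over walker x group arrays)

def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _log_expit_diff(a: np.ndarray, b: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """log(expit(a) - expit(b)) for a > b with delta = a - b > 0."""
    return _log_sigmoid(a) + _log_sigmoid(-b) + np.log(-np.expm1(-np.maximum(delta, 1e-300)))


# --------------------------------------------------------------------------
# model builders: each produces a vectorized unnormalized log posterior


def _design_arrays(data: TrialDataset):
    low = np.array([r.arm == Arm.LOWER_PEEP for r in data.records], dtype=float)
    hosp = np.array([r.hospital_id - 1 for r in data.records], dtype=int)
    return low, hosp


class _BaseModel:
    """Shared parameter layout: [theta, (tau_raw), (z_1..z_H), *nuisance]."""

    def __init__(self, spec: HierarchicalModelSpec, n_hospitals: int):
        self.spec = spec
        self.H = n_hospitals
        self.sample_tau = spec.tau_fixed is None
        self.has_z = self.sample_tau or (spec.tau_fixed is not None and spec.tau_fixed > 0)
        self.i_theta = 0
        idx = 1
        if self.sample_tau:
            self.i_tau_raw = idx
            idx += 1
        if self.has_z:
            self.sl_z = slice(idx, idx + self.H)
            idx += self.H
        self.i_nuisance0 = idx

    def _unpack_common(self, x: np.ndarray):
        theta = x[:, self.i_theta]
        if self.sample_tau:
            tau = np.abs(x[:, self.i_tau_raw])
        else:
            tau = np.full(x.shape[0], float(self.spec.tau_fixed))
        if self.has_z:
            z = x[:, self.sl_z]
            b = tau[:, None] * z
        else:
            z = np.zeros((x.shape[0], self.H))
            b = np.zeros((x.shape[0], self.H))
        return theta, tau, z, b

    def _log_prior_common(self, x: np.ndarray, theta, tau, z) -> np.ndarray:
        p = self.spec.treatment_prior
        lp = -0.5 * ((theta - p.mu) / p.sigma) ** 2
        if self.sample_tau:
            s = self.spec.heterogeneity_prior.sigma
            # u ~ Normal(0, s); tau = |u| is Half-Normal(s) exactly.
            lp = lp - 0.5 * (tau / s) ** 2
        if self.has_z:
            lp = lp - 0.5 * np.sum(z**2, axis=1)
        return lp

    def log_posterior(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        theta, tau, z, b = self._unpack_common(x)
        lp = self._log_prior_common(x, theta, tau, z) + self._log_prior_extra(x)
        ll = self._log_likelihood(x, theta, b)
        out = lp + ll
        out = np.where(np.isfinite(out), out, -np.inf)
        return out if out.shape[0] > 1 else float(out[0])

    # subclasses implement:
    def _log_prior_extra(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def _log_likelihood(self, x, theta, b):  # pragma: no cover - abstract
        raise NotImplementedError


class CumulativeLogisticModel(_BaseModel):
    """Proportional-odds model over the full 29-category VFD scale."""

    K = 29  # categories 0..28 -> 28 cut-points

    def __init__(self, data: TrialDataset, spec: HierarchicalModelSpec):
        super().__init__(spec, data.n_hospitals)
        low, hosp = _design_arrays(data)
        y = np.array([r.vfd for r in data.records], dtype=int)
        if len(np.unique(y)) < 2:
            raise ModelError("degenerate ordinal outcome: a single VFD category")
        # Group identical (arm, hospital, category) cells; the likelihood is a
        # count-weighted sum over at most 2 * H * 29 cells.
        key = (low.astype(int) * self.H + hosp) * self.K + y
        uniq, counts = np.unique(key, return_counts=True)
        self.g_y = (uniq % self.K).astype(int)
        self.g_h = ((uniq // self.K) % self.H).astype(int)
        self.g_low = (uniq // (self.K * self.H)).astype(float)
        self.g_n = counts.astype(float)
        self.ncut = self.K - 1
        self.ndim = self.i_nuisance0 + self.ncut
        self._y_obs = y

    def _alpha(self, x: np.ndarray) -> np.ndarray:
        a1 = x[:, self.i_nuisance0]
        lam = x[:, self.i_nuisance0 + 1 : self.ndim]
        gaps = np.exp(lam)
        return np.concatenate(
            [a1[:, None], a1[:, None] + np.cumsum(gaps, axis=1)], axis=1
        )

    def _log_prior_extra(self, x: np.ndarray) -> np.ndarray:
        alpha = self._alpha(x)
        lam = x[:, self.i_nuisance0 + 1 : self.ndim]
        # iid Normal(0, s) on the ordered cut-points + log-gap Jacobian.
        return (
            -0.5 * np.sum((alpha / CUTPOINT_PRIOR_SD) ** 2, axis=1)
            + np.sum(lam, axis=1)
        )

    def _log_likelihood(self, x, theta, b) -> np.ndarray:
        alpha = self._alpha(x)  # (W, 28)
        eta = theta[:, None] * self.g_low[None, :] + np.take(b, self.g_h, axis=1)
        logp = np.empty_like(eta)
        y = self.g_y
        is0 = y == 0
        isK = y == self.K - 1
        mid = ~(is0 | isK)
        if is0.any():
            logp[:, is0] = _log_sigmoid(alpha[:, 0][:, None] - eta[:, is0])
        if isK.any():
            logp[:, isK] = _log_sigmoid(eta[:, isK] - alpha[:, -1][:, None])
        if mid.any():
            ym = y[mid]
            a_hi = eta[:, mid] - alpha[:, ym - 1]
            a_lo = eta[:, mid] - alpha[:, ym]
            delta = alpha[:, ym] - alpha[:, ym - 1]
            logp[:, mid] = _log_expit_diff(a_hi, a_lo, delta)
        return logp @ self.g_n

    def initial_point(self) -> np.ndarray:
        counts = np.bincount(self._y_obs, minlength=self.K).astype(float) + 0.2
        p_ge = 1.0 - np.cumsum(counts / counts.sum())[:-1]
        p_ge = np.clip(p_ge, 1e-4, 1 - 1e-4)
        alpha0 = np.log((1.0 - p_ge) / p_ge)
        alpha0 = np.maximum.accumulate(alpha0 + 1e-3 * np.arange(self.ncut))
        gaps = np.maximum(np.diff(alpha0), 1e-3)
        x0 = np.zeros(self.ndim)
        x0[self.i_theta] = self.spec.treatment_prior.mu
        if self.sample_tau:
            x0[self.i_tau_raw] = 0.1
        x0[self.i_nuisance0] = alpha0[0]
        x0[self.i_nuisance0 + 1 :] = np.log(gaps)
        return x0

    def nuisance_names(self):
        return {"cutpoints": slice(self.i_nuisance0, self.ndim)}


class LogisticModel(_BaseModel):
    """Hierarchical logistic regression for 28-day mortality, optionally with a
    subgroup main effect and a treatment-by-subgroup interaction."""

    def __init__(
        self,
        data: TrialDataset,
        spec: HierarchicalModelSpec,
        subgroup: Optional[np.ndarray] = None,
    ):
        super().__init__(spec, data.n_hospitals)
        low, hosp = _design_arrays(data)
        y = np.array([r.died_by_day28 for r in data.records], dtype=float)
        if y.min() == y.max():
            raise ModelError("degenerate binary outcome: a single class present")
        self.with_interaction = subgroup is not None
        if self.with_interaction:
            subgroup = np.asarray(subgroup, dtype=float)
            if subgroup.min() == subgroup.max():
                raise ModelError("subgroup indicator is constant: degenerate design")
            for lo_v in (0.0, 1.0):
                for sg_v in (0.0, 1.0):
                    if not np.any((low == lo_v) & (subgroup == sg_v)):
                        raise ModelError(
                            f"empty subgroup cell: arm={'lower' if lo_v else 'higher'}, "
                            f"subgroup={'yes' if sg_v else 'no'}"
                        )
            if spec.interaction_prior is None:
                raise ModelError("interaction model requires an interaction_prior")
        else:
            subgroup = np.zeros_like(low)
        for arm_v in (0.0, 1.0):
            sel = low == arm_v
            if sel.any() and y[sel].min() == y[sel].max():
                warnings.warn(
                    "complete separation in one arm: the prior dominates the "
                    "treatment effect",
                    ConvergenceWarning,
                    stacklevel=3,
                )
        sg = subgroup
        key = ((low.astype(int) * 2 + sg.astype(int)) * self.H + hosp)
        uniq, inv = np.unique(key, return_inverse=True)
        G = len(uniq)
        self.g_h = (uniq % self.H).astype(int)
        self.g_sg = ((uniq // self.H) % 2).astype(float)
        self.g_low = (uniq // (2 * self.H)).astype(float)
        self.g_n = np.bincount(inv, minlength=G).astype(float)
        self.g_dead = np.bincount(inv, weights=y, minlength=G)
        self.i_intercept = self.i_nuisance0
        self.ndim = self.i_nuisance0 + 1 + (2 if self.with_interaction else 0)
        if self.with_interaction:
            self.i_sub = self.i_intercept + 1
            self.i_int = self.i_intercept + 2
        self._p_hat = float(y.mean())

    def _log_prior_extra(self, x: np.ndarray) -> np.ndarray:
        lp = -0.5 * (x[:, self.i_intercept] / INTERCEPT_PRIOR_SD) ** 2
        if self.with_interaction:
            lp = lp - 0.5 * (x[:, self.i_sub] / INTERCEPT_PRIOR_SD) ** 2
            ip = self.spec.interaction_prior
            lp = lp - 0.5 * ((x[:, self.i_int] - ip.mu) / ip.sigma) ** 2
        return lp

    def _log_likelihood(self, x, theta, b) -> np.ndarray:
        eta = (
            x[:, self.i_intercept][:, None]
            + theta[:, None] * self.g_low[None, :]
            + np.take(b, self.g_h, axis=1)
        )
        if self.with_interaction:
            eta = eta + (
                x[:, self.i_sub][:, None] * self.g_sg[None, :]
                + x[:, self.i_int][:, None] * (self.g_sg * self.g_low)[None, :]
            )
        return (_log_sigmoid(eta) * self.g_dead[None, :]).sum(axis=1) + (
            _log_sigmoid(-eta) * (self.g_n - self.g_dead)[None, :]
        ).sum(axis=1)

    def initial_point(self) -> np.ndarray:
        x0 = np.zeros(self.ndim)
        x0[self.i_theta] = self.spec.treatment_prior.mu
        if self.sample_tau:
            x0[self.i_tau_raw] = 0.1
        p = min(max(self._p_hat, 1e-3), 1 - 1e-3)
        x0[self.i_intercept] = np.log(p / (1 - p))
        return x0

    def nuisance_names(self):
        names = {"intercept": self.i_intercept}
        if self.with_interaction:
            names["subgroup_effect"] = self.i_sub
            names["interaction"] = self.i_int
        return names


class LinearModel(_BaseModel):
    """Hierarchical Gaussian regression for ventilation duration among survivors."""

    def __init__(self, data: TrialDataset, spec: HierarchicalModelSpec):
        super().__init__(spec, data.n_hospitals)
        survivors = [r for r in data.records if not r.died_by_day28]
        low = np.array([r.arm == Arm.LOWER_PEEP for r in survivors], dtype=float)
        hosp = np.array([r.hospital_id - 1 for r in survivors], dtype=int)
        y = np.array([r.vent_duration_days for r in survivors], dtype=float)
        if np.any(np.isnan(y)):
            raise ModelError("survivor with missing ventilation duration")
        if len(y) < 2:
            raise ModelError("need at least 2 survivors")
        for arm_v in set(low):
            if (low == arm_v).sum() < 2:
                raise ModelError("need at least 2 survivors per (present) arm")
        key = low.astype(int) * self.H + hosp
        uniq, inv = np.unique(key, return_inverse=True)
        G = len(uniq)
        self.g_h = (uniq % self.H).astype(int)
        self.g_low = (uniq // self.H).astype(float)
        self.g_n = np.bincount(inv, minlength=G).astype(float)
        self.g_sum = np.bincount(inv, weights=y, minlength=G)
        self.g_sumsq = np.bincount(inv, weights=y**2, minlength=G)
        self.n_obs = float(len(y))
        self._ybar, self._ysd = float(y.mean()), float(y.std() + 1e-6)
        self.i_intercept = self.i_nuisance0
        self.i_logsig = self.i_nuisance0 + 1
        self.ndim = self.i_nuisance0 + 2

    def _log_prior_extra(self, x: np.ndarray) -> np.ndarray:
        sig = np.exp(x[:, self.i_logsig])
        return (
            -0.5 * (x[:, self.i_intercept] / INTERCEPT_PRIOR_SD) ** 2
            - 0.5 * (sig / RESIDUAL_SD_PRIOR_SCALE) ** 2
            + x[:, self.i_logsig]
        )

    def _log_likelihood(self, x, theta, b) -> np.ndarray:
        sig = np.exp(x[:, self.i_logsig])
        m = (
            x[:, self.i_intercept][:, None]
            + theta[:, None] * self.g_low[None, :]
            + np.take(b, self.g_h, axis=1)
        )
        ss = (
            self.g_sumsq[None, :]
            - 2.0 * m * self.g_sum[None, :]
            + (m**2) * self.g_n[None, :]
        ).sum(axis=1)
        return -self.n_obs * (np.log(sig) + _LOG_SQRT_2PI) - ss / (2.0 * sig**2)

    def initial_point(self) -> np.ndarray:
        x0 = np.zeros(self.ndim)
        x0[self.i_theta] = self.spec.treatment_prior.mu
        if self.sample_tau:
            x0[self.i_tau_raw] = 0.1
        x0[self.i_intercept] = self._ybar
        x0[self.i_logsig] = np.log(self._ysd)
        return x0

    def nuisance_names(self):
        return {"intercept": self.i_intercept, "residual_sd": self.i_logsig}


# --------------------------------------------------------------------------
# sampling


def _diagnose(chains: tuple[np.ndarray, np.ndarray]) -> tuple[float, float]:
    """Split-R-hat across independent ensembles; bulk ESS from walker chains."""
    import arviz as az

    rhat_arr, ess_arr = chains
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(rhat_arr)), float(az.ess(ess_arr))


def _run_sampler(model: _BaseModel, spec: HierarchicalModelSpec) -> PosteriorDraws:
    """Run ``spec.n_chains`` independent ensembles and pool their draws.

    Split-R-hat is computed across the independent ensembles (not across
    interacting walkers); ESS is computed from per-walker autocorrelation
    with walkers of every ensemble stacked as chains.
    """
    import emcee

    d = model.ndim
    nwalkers = 2 * d + 6
    nwalkers += nwalkers % 2
    x0 = model.initial_point()
    # Over-dispersed initialization: walkers start at roughly the prior scale
    # for theta, tau and the standardized hospital effects, so the ensemble
    # contracts onto the posterior (DE ensembles contract much faster than
    # they expand from a tight ball).
    jitter = np.full(d, 0.1)
    jitter[model.i_theta] = spec.treatment_prior.sigma
    if model.sample_tau:
        jitter[model.i_tau_raw] = 0.5 * spec.heterogeneity_prior.sigma
    if model.has_z:
        jitter[model.sl_z] = 1.0

    # Post-warmup raw steps per ensemble: enough thinned steps for a usable
    # per-walker autocorrelation estimate, and enough flattened draws.
    need = max(
        spec.thin * ((spec.n_draws + nwalkers - 1) // nwalkers),
        spec.thin * 150,
    )

    chain_flat = []  # per ensemble: (flat_len, d), step-major (early -> late)
    walker_chains = []  # per ensemble: (walkers, steps, d), thinned
    seed_root = np.random.SeedSequence(spec.seed)
    for c, child in enumerate(seed_root.spawn(spec.n_chains)):
        rs = np.random.RandomState(int(child.generate_state(1)[0] & 0x7FFFFFFF))
        p0 = x0[None, :] + jitter[None, :] * rs.randn(nwalkers, d)
        sampler = emcee.EnsembleSampler(
            nwalkers,
            d,
            model.log_posterior,
            vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.9), (emcee.moves.StretchMove(), 0.1)],
        )
        sampler.random_state = rs.get_state()
        state = sampler.run_mcmc(p0, spec.n_warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, need, progress=False)
        chain = sampler.get_chain(thin=spec.thin)  # (steps, walkers, dim)
        walker_chains.append(chain.transpose(1, 0, 2))
        chain_flat.append(chain.reshape(-1, d))
        if c == 0:
            accept = float(np.mean(sampler.acceptance_fraction))

    avail = min(cf.shape[0] for cf in chain_flat)
    flat_len = min(avail, spec.n_draws)
    # Evenly strided subsample over the whole post-warmup window: a tail
    # window alone is coherent with the ensemble's slow spread mode and
    # would under-represent posterior dispersion.
    idx = np.linspace(0, avail - 1, flat_len).round().astype(int)
    kept = np.stack([cf[idx] for cf in chain_flat])  # (n_chains, flat_len, d)
    wstack = np.concatenate(walker_chains, axis=0)  # (n_chains*walkers, steps, d)

    def flat(idx) -> np.ndarray:
        return kept[:, :, idx].reshape(spec.n_chains * flat_len, -1).squeeze()

    theta = np.asarray(flat(model.i_theta), float)
    theta_chains = (kept[:, :, model.i_theta], wstack[:, :, model.i_theta])
    if model.sample_tau:
        tau = np.abs(np.asarray(flat(model.i_tau_raw), float))
        tau_chains = (
            np.abs(kept[:, :, model.i_tau_raw]),
            np.abs(wstack[:, :, model.i_tau_raw]),
        )
    else:
        tau = np.full_like(theta, float(spec.tau_fixed))
        tau_chains = None

    rhat_t, ess_t = _diagnose(theta_chains)
    diagnostics: dict[str, float | bool] = {
        "rhat_theta": rhat_t,
        "ess_theta": ess_t,
        "mean_acceptance": accept,
    }
    if tau_chains is not None:
        rhat_tau, ess_tau = _diagnose(tau_chains)
        diagnostics["rhat_tau"] = rhat_tau
        diagnostics["ess_tau"] = ess_tau
    converged = diagnostics["rhat_theta"] <= 1.01 and diagnostics["ess_theta"] >= 400
    if tau_chains is not None:
        converged = converged and diagnostics["rhat_tau"] <= 1.01 and diagnostics["ess_tau"] >= 400
    diagnostics["converged"] = bool(converged)
    if not converged:
        warnings.warn(
            f"sampler convergence gate not met for outcome {spec.outcome!r}: "
            f"{ {k: round(v, 3) if isinstance(v, float) else v for k, v in diagnostics.items()} }",
            ConvergenceWarning,
            stacklevel=3,
        )

    nuisance: dict[str, np.ndarray] = {}
    for name, idx in model.nuisance_names().items():
        vals = np.asarray(flat(idx), float)
        if name == "residual_sd":
            vals = np.exp(vals)
        if name == "cutpoints":
            # stored as (draws, 28) on the alpha scale
            raw = kept[:, :, idx].reshape(spec.n_chains * flat_len, -1)
            a1 = raw[:, :1]
            vals = np.concatenate(
                [a1, a1 + np.cumsum(np.exp(raw[:, 1:]), axis=1)], axis=1
            )
        nuisance[name] = vals

    return PosteriorDraws(
        outcome=spec.outcome,
        effect_scale=spec.treatment_prior.effect_scale,
        theta=theta,
        tau=tau,
        nuisance=nuisance,
        diagnostics=diagnostics,
        seed=spec.seed,
        n_chains=spec.n_chains,
        n_draws=flat_len,
    )


# --------------------------------------------------------------------------
# public fitting API


def build_model(
    data: TrialDataset,
    spec: HierarchicalModelSpec,
    subgroup: Optional[np.ndarray] = None,
) -> _BaseModel:
    """Construct the model object (exposes the exact unnormalized log posterior)."""
    if spec.outcome == "vfd":
        return CumulativeLogisticModel(data, spec)
    if spec.outcome == "mortality_28d":
        return LogisticModel(data, spec, subgroup=subgroup)
    if spec.outcome == "duration":
        return LinearModel(data, spec)
    raise ModelError(f"unknown outcome {spec.outcome!r}")


def fit_vfd_model(data: TrialDataset, spec: HierarchicalModelSpec) -> PosteriorDraws:
    if spec.outcome != "vfd":
        raise ModelError("spec.outcome must be 'vfd'")
    return _run_sampler(CumulativeLogisticModel(data, spec), spec)


def fit_mortality_model(data: TrialDataset, spec: HierarchicalModelSpec) -> PosteriorDraws:
    if spec.outcome != "mortality_28d":
        raise ModelError("spec.outcome must be 'mortality_28d'")
    return _run_sampler(LogisticModel(data, spec), spec)


def fit_duration_model(data: TrialDataset, spec: HierarchicalModelSpec) -> PosteriorDraws:
    if spec.outcome != "duration":
        raise ModelError("spec.outcome must be 'duration'")
    return _run_sampler(LinearModel(data, spec), spec)


def subgroup_indicator(data: TrialDataset, covariate: str) -> tuple[np.ndarray, np.ndarray]:
    """Dichotomize a subgroup covariate per the protocol cut-offs.

    Returns ``(indicator, complete)`` where ``complete`` marks rows with a
    non-missing covariate (interaction fits are complete-case).
    """
    if covariate not in SUBGROUP_DEFINITIONS:
        raise ModelError(
            f"unknown subgroup {covariate!r}; expected one of {sorted(SUBGROUP_DEFINITIONS)}"
        )
    fieldname, rule = SUBGROUP_DEFINITIONS[covariate]
    raw = [getattr(r, fieldname) for r in data.records]
    complete = np.array([v is not None for v in raw])
    vals = np.array([0.0 if v is None else float(rule(v) if rule else v) for v in raw])
    return vals, complete


def fit_subgroup_interaction(
    data: TrialDataset, spec: HierarchicalModelSpec
) -> PosteriorDraws:
    """Hierarchical logistic model with subgroup main effect and
    treatment-by-subgroup interaction (dichotomous 28-day mortality outcome)."""
    if spec.interaction_covariate is None:
        raise ModelError("spec.interaction_covariate must be set")
    if spec.outcome != "mortality_28d":
        raise ModelError("interaction models are fitted on the dichotomous outcome")
    sg, complete = subgroup_indicator(data, spec.interaction_covariate)
    if not complete.all():
        n_drop = int((~complete).sum())
        warnings.warn(
            f"dropping {n_drop} record(s) with missing {spec.interaction_covariate!r} "
            "(complete-case)",
            UserWarning,
            stacklevel=2,
        )
        records = [r for r, ok in zip(data.records, complete) if ok]
        data = TrialDataset(records, data.n_hospitals, data.provenance, data.seed)
        sg = sg[complete]
    model = LogisticModel(data, spec, subgroup=sg)
    return _run_sampler(model, spec)
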