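"""Independent brute-force reference implementations used only by tests.

Deliberately naive: per-patient loops, scipy distribution objects, hourly
day-marking grids — no code shared with the package's vectorized paths.
The log posteriors are normalized densities; comparisons against the
package's unnormalized kernels are made on *differences* between parameter
points, where additive constants cancel.
"""

import numpy as np
from scipy import stats
from scipy.special import expit


def vfd_day_marking(course, horizon=28, count_mid_course=True, min_window_days=1.0):
    """Hour-resolution day-marking oracle for ventilator-free days."""
    t0 = course.randomization_day
    if course.death_day is not None and course.death_day <= t0 + horizon:
        return 0
    hours = horizon * 24
    ventilated = np.zeros(hours, dtype=bool)
    for start, end in course.ventilation_episodes:
        if end - t0 >= horizon and start - t0 < horizon:
            return 0  # still on the ventilator at the horizon
        lo = int(np.ceil((start - t0) * 24 - 1e-9))
        hi = int(np.ceil((end - t0) * 24 - 1e-9))
        ventilated[max(lo, 0) : min(hi, hours)] = True
    # maximal unassisted runs of hours
    free_days = 0
    runs = []
    i = 0
    while i < hours:
        if not ventilated[i]:
            j = i
            while j < hours and not ventilated[j]:
                j += 1
            runs.append((i, j, j == hours))
            i = j
        else:
            i += 1
    for lo, hi, terminal in runs:
        if hi - lo < min_window_days * 24:
            continue
        if not terminal and not count_mid_course:
            continue
        for day in range(horizon):
            if lo <= day * 24 and (day + 1) * 24 <= hi:
                free_days += 1
    return free_days


def _ordinal_logpmf(y, eta, alpha):
    """P(Y = y) under P(Y >= k) = expit(eta - alpha_k), naive arithmetic."""
    p_ge = np.concatenate([[1.0], expit(eta - np.asarray(alpha)), [0.0]])
    return np.log(p_ge[y] - p_ge[y + 1])


def _common_log_prior(spec, theta, tau_raw, z):
    p = spec.treatment_prior
    lp = stats.norm.logpdf(theta, p.mu, p.sigma)
    lp += stats.norm.logpdf(tau_raw, 0.0, spec.heterogeneity_prior.sigma)
    lp += stats.norm.logpdf(z, 0.0, 1.0).sum()
    return lp


def vfd_log_posterior(data, spec, params):
    """Brute-force log posterior of the proportional-odds model.

    ``params`` uses the sampler's layout: theta, tau_raw, z_1..z_H, alpha_1,
    27 log-gaps.
    """
    H = data.n_hospitals
    theta, tau_raw = params[0], params[1]
    z = np.asarray(params[2 : 2 + H])
    a1 = params[2 + H]
    lam = np.asarray(params[3 + H :])
    alpha = np.concatenate([[a1], a1 + np.cumsum(np.exp(lam))])
    b = abs(tau_raw) * z

    lp = _common_log_prior(spec, theta, tau_raw, z)
    lp += stats.norm.logpdf(alpha, 0.0, 5.0).sum() + lam.sum()
    for r in data.records:
        eta = theta * (r.arm.value == "lower_peep") + b[r.hospital_id - 1]
        lp += _ordinal_logpmf(r.vfd, eta, alpha)
    return lp


def mortality_log_posterior(data, spec, params, subgroup=None):
    """Brute-force log posterior of the hierarchical logistic model."""
    H = data.n_hospitals
    theta, tau_raw = params[0], params[1]
    z = np.asarray(params[2 : 2 + H])
    gamma = params[2 + H]
    b = abs(tau_raw) * z

    lp = _common_log_prior(spec, theta, tau_raw, z)
    lp += stats.norm.logpdf(gamma, 0.0, 5.0)
    if subgroup is not None:
        beta_s, beta_i = params[3 + H], params[4 + H]
        ip = spec.interaction_prior
        lp += stats.norm.logpdf(beta_s, 0.0, 5.0)
        lp += stats.norm.logpdf(beta_i, ip.mu, ip.sigma)
    for i, r in enumerate(data.records):
        low = float(r.arm.value == "lower_peep")
        eta = gamma + theta * low + b[r.hospital_id - 1]
        if subgroup is not None:
            eta += beta_s * subgroup[i] + beta_i * subgroup[i] * low
        pr = expit(eta)
        lp += np.log(pr) if r.died_by_day28 else np.log(1.0 - pr)
    return lp


def duration_log_posterior(data, spec, params):
    """Brute-force log posterior of the hierarchical linear model (survivors)."""
    H = data.n_hospitals
    theta, tau_raw = params[0], params[1]
    z = np.asarray(params[2 : 2 + H])
    gamma, log_sig = params[2 + H], params[3 + H]
    sig = np.exp(log_sig)
    b = abs(tau_raw) * z

    lp = _common_log_prior(spec, theta, tau_raw, z)
    lp += stats.norm.logpdf(gamma, 0.0, 5.0)
    lp += stats.halfnorm.logpdf(sig, scale=5.0) + log_sig
    for r in data.records:
        if r.died_by_day28:
            continue
        mu = gamma + theta * (r.arm.value == "lower_peep") + b[r.hospital_id - 1]
        lp += stats.norm.logpdf(r.vent_duration_days, mu, sig)
    return lp
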