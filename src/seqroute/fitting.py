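"""Parameter-estimation procedures that constrain the network model.

Covers the two-stage passive-membrane fit (leak from the steady state,
capacitance from the onset transient), EPSP-amplitude-to-conductance
inversion, maximum-likelihood fitting of the truncated lognormal
conductance distribution, moment matching of that distribution, and the
bootstrap of the probability that a neuron owns at least one strong
connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .neuron import VoltageTrace, psp_amplitude
from .params import DEFAULT_PARAMS, NeuronParameters

__all__ = [
    "MembraneFit",
    "LognormalFit",
    "BootstrapResult",
    "fit_membrane",
    "epsp_to_conductance",
    "fit_truncated_lognormal",
    "match_truncated_moments",
    "truncated_lognormal_moments",
    "truncated_lognormal_ppf",
    "bootstrap_strong_probability",
]


class FitError(RuntimeError):
    """Raised when a fit cannot be performed or fails a quality check."""


@dataclass
class MembraneFit:
    g_L_hat: float       # nS
    C_hat: float         # pF
    residual_ss: float   # mV, residual slope proxy of the steady-state stage
    residual_onset: float  # mV, RMS residual of the transient stage

    def __post_init__(self) -> None:
        if self.g_L_hat <= 0 or self.C_hat <= 0:
            raise FitError("fitted g_L and C must be positive")


def fit_membrane(
    trace: VoltageTrace,
    injected_current: float,
    t_on: float,
    onset_window: float = 100.0,
    steady_fraction: float = 0.2,
    slope_tol: float = 0.005,
) -> MembraneFit:
    """Two-stage passive-membrane fit on a current-step voltage trace.

    Stage 1 estimates the leak conductance from the steady-state
    deflection, g_L = I / dV_ss.  Stage 2 fixes g_L and fits the membrane
    capacitance by least squares on the onset transient
    V(t) = V0 + dV_ss (1 - exp(-t g_L / C)).

    ``slope_tol`` (mV/ms) bounds the drift of the tail used as steady
    state; a larger drift raises :class:`FitError`.
    """
    if injected_current == 0:
        raise FitError("zero injected current: membrane parameters unidentifiable")
    t = np.asarray(trace.times, dtype=float)
    V = np.asarray(trace.V, dtype=float)
    pre = t < t_on
    if pre.sum() < 2 or (~pre).sum() < 10:
        raise FitError("trace must span a pre-onset baseline and a post-onset response")
    V0 = V[pre].mean()
    # steady state: last `steady_fraction` of the post-onset span
    post_t = t[~pre]
    tail = t >= post_t[0] + (1 - steady_fraction) * (post_t[-1] - post_t[0])
    slope = np.polyfit(t[tail], V[tail], 1)[0]
    if abs(slope) > slope_tol:
        raise FitError(f"steady state not reached: tail slope {slope:.4f} mV/ms")
    dV_ss = V[tail].mean() - V0
    if dV_ss == 0:
        raise FitError("no steady-state deflection")
    g_L = injected_current / dV_ss
    if g_L <= 0:
        raise FitError("negative fitted leak conductance")
    # onset transient
    onset = (t >= t_on) & (t <= t_on + onset_window)
    ts = t[onset] - t_on
    Vs = V[onset]

    def model(ts, tau):
        return V0 + dV_ss * (1.0 - np.exp(-ts / tau))

    tau0 = max(onset_window / 4.0, 1.0)
    popt, _ = optimize.curve_fit(model, ts, Vs, p0=[tau0],
                                 bounds=(1e-3, np.inf), maxfev=10000)
    tau = float(popt[0])
    rms = float(np.sqrt(np.mean((model(ts, tau) - Vs) ** 2)))
    return MembraneFit(g_L_hat=float(g_L), C_hat=float(g_L * tau),
                       residual_ss=float(abs(slope)), residual_onset=rms)


def epsp_to_conductance(
    amplitude: float,
    params: NeuronParameters = DEFAULT_PARAMS,
    tol: float = 1e-3,
) -> float:
    """Invert the model's EPSP amplitude (mV, at rest) to a conductance (nS).

    Monotone bisection on :func:`seqroute.neuron.psp_amplitude`.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return 0.0

    def probe(g):
        amp, spiked = psp_amplitude(params, g, "excitatory", return_flag=True)
        return np.inf if spiked else amp  # a spiking response exceeds any target

    g_hi = 8.0
    while probe(g_hi) < amplitude:
        g_hi *= 2.0
        if g_hi > 4096.0:
            raise ValueError(f"amplitude {amplitude} mV outside the invertible range")
    g_lo = 0.0
    while g_hi - g_lo > tol:
        mid = 0.5 * (g_lo + g_hi)
        if probe(mid) < amplitude:
            g_lo = mid
        else:
            g_hi = mid
    g = 0.5 * (g_lo + g_hi)
    _, spiked = psp_amplitude(params, g, "excitatory", return_flag=True)
    if spiked:
        raise ValueError(f"amplitude {amplitude} mV drives the neuron to spike")
    return g


# --- truncated lognormal -------------------------------------------------

def truncated_lognormal_moments(mu: float, sigma: float, truncation: float):
    """(mean, std) of a lognormal(mu, sigma) right-truncated at ``truncation``."""
    lnT = np.log(truncation)
    Z = stats.norm.cdf((lnT - mu) / sigma)
    m1 = np.exp(mu + sigma**2 / 2) * stats.norm.cdf((lnT - mu - sigma**2) / sigma) / Z
    m2 = np.exp(2 * mu + 2 * sigma**2) * stats.norm.cdf((lnT - mu - 2 * sigma**2) / sigma) / Z
    return float(m1), float(np.sqrt(m2 - m1**2))


def match_truncated_moments(mean: float, std: float, truncation: float):
    """Underlying (mu, sigma) whose right-truncated lognormal has the given
    mean and standard deviation."""

    def eqs(p):
        m, s = truncated_lognormal_moments(p[0], p[1], truncation)
        return [m - mean, s - std]

    sol = optimize.root(eqs, [np.log(mean), 1.0])
    if not sol.success:
        raise FitError(f"moment matching failed: {sol.message}")
    mu, sigma = sol.x
    if sigma <= 0:
        raise FitError("moment matching produced non-positive sigma")
    return float(mu), float(sigma)


def truncated_lognormal_ppf(q, mu: float, sigma: float, truncation: float):
    """Quantile of the right-truncated lognormal."""
    Z = stats.norm.cdf((np.log(truncation) - mu) / sigma)
    return np.exp(mu + sigma * stats.norm.ppf(np.asarray(q) * Z))


@dataclass
class LognormalFit:
    underlying_mu: float
    underlying_sigma: float
    truncation: float
    implied_mean: float
    implied_std: float
    log_likelihood: float

    def ppf(self, q):
        return truncated_lognormal_ppf(q, self.underlying_mu,
                                       self.underlying_sigma, self.truncation)

    def prob_range(self, lo: float, hi: float) -> float:
        """P(lo <= X <= hi) under the truncated distribution."""
        mu, s, T = self.underlying_mu, self.underlying_sigma, self.truncation
        Z = stats.norm.cdf((np.log(T) - mu) / s)
        hi = min(hi, T)
        p = (stats.norm.cdf((np.log(hi) - mu) / s)
             - stats.norm.cdf((np.log(lo) - mu) / s)) / Z
        return float(max(p, 0.0))


def fit_truncated_lognormal(
    samples,
    truncation: float,
    account_truncation: bool = True,
) -> LognormalFit:
    """Maximum-likelihood lognormal fit to right-truncated samples.

    With ``account_truncation`` the likelihood is normalized by the
    lognormal CDF at the truncation point (standard truncated MLE);
    without it a plain lognormal MLE is performed (closed form).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise FitError("need at least 10 samples")
    if np.any(x <= 0):
        raise FitError("samples must be positive")
    if np.any(x > truncation * (1 + 1e-12)):
        raise FitError("samples exceed the truncation point")
    lx = np.log(x)
    if np.std(lx) < 1e-12:
        raise FitError("degenerate (constant) sample")
    mu0, s0 = float(np.mean(lx)), float(np.std(lx))
    if account_truncation:
        lnT = np.log(truncation)

        def nll(p):
            mu, ls = p
            s = np.exp(ls)
            z = (lx - mu) / s
            logZ = stats.norm.logcdf((lnT - mu) / s)
            return np.sum(0.5 * z**2 + np.log(s)) + x.size * logZ

        res = optimize.minimize(nll, [mu0, np.log(s0)], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
        ll = -float(res.fun) - x.size * 0.5 * np.log(2 * np.pi) - float(np.sum(lx))
    else:
        mu, sigma = mu0, s0
        z = (lx - mu) / sigma
        ll = float(-np.sum(0.5 * z**2) - x.size * (np.log(sigma) + 0.5 * np.log(2 * np.pi))
                   - np.sum(lx))
    m, s = truncated_lognormal_moments(mu, sigma, truncation)
    return LognormalFit(mu, sigma, float(truncation), m, s, ll)


@dataclass
class BootstrapResult:
    p_strong: np.ndarray          # per-rep probability a connection is strong
    p_at_least_one: np.ndarray    # per-rep estimate of P(>=1 strong connection)
    strong_range: tuple
    degree_mu: float
    degree_sigma: float
    n_degree_draws: int
    reps: int = field(init=False)

    def __post_init__(self) -> None:
        self.reps = int(self.p_strong.size)


def bootstrap_strong_probability(
    conductance_samples,
    reps: int = 50_000,
    strong_range: tuple = (50.6, 67.8),
    truncation: float = 67.8,
    degree_mu: float = 745.0,
    degree_sigma: float = 27.0,
    n_degree_draws: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the probability that a neuron has >=1 strong connection.

    Per replicate: resample the conductance set with replacement, refit the
    truncated lognormal, compute p_j = P(strong range), draw
    ``n_degree_draws`` connection counts n_i from a discretized Gaussian
    (truncated at >=1), sample s_ij ~ Binomial(n_i, p_j) and record the
    fraction of s_ij >= 1.
    """
    x = np.asarray(conductance_samples, dtype=float)
    if x.size == 0:
        raise ValueError("conductance_samples must be non-empty")
    rng = np.random.default_rng(seed)
    p_strong = np.empty(reps)
    p_any = np.empty(reps)
    lo, hi = strong_range
    for j in range(reps):
        boot = rng.choice(x, size=x.size, replace=True)
        try:
            fit = fit_truncated_lognormal(boot, truncation)
            pj = fit.prob_range(lo, hi)
        except FitError:
            pj = 0.0
        n_i = np.maximum(np.rint(rng.normal(degree_mu, degree_sigma,
                                            n_degree_draws)), 1).astype(int)
        s_ij = rng.binomial(n_i, pj)
        p_strong[j] = pj
        p_any[j] = np.mean(s_ij >= 1)
    return BootstrapResult(p_strong, p_any, (float(lo), float(hi)),
                           degree_mu, degree_sigma, n_degree_draws)
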