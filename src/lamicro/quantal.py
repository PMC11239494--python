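"""Maximum-likelihood quantal analysis under the simple binomial release model.

The response amplitude v is modelled as a Gaussian mixture over the
number of released quanta m ~ Binomial(n, p):

    f(v) = p_stim * sum_{m=0}^{n} C(n, m) p^m (1-p)^(n-m)
                 * N(v; v0 + m*q, sigma_m)
         + (1 - p_stim) * N(v; v0, sigma_noise)

with sigma_m^2 = sigma_noise^2 + m*sigma_q^2 for type-I quantal variance,
or sigma_noise^2 + sigma_q^2 for every m > 0 under the "flat" model.
The closed-form release moments are mean = n*p*q and
s.d. = q*sqrt(n*p*(1-p)).

Fitting scans the candidate site count n from a data-driven lower bound
up to 14 (fits that select the 14-site cap are discarded as unresolved),
maximizing the likelihood over (p, q, v0[, sigma_q]) by Nelder-Mead
simplex from ten starting points per n, with the recording noise s.d.
fixed at its measured value.  Goodness of fit is a Monte-Carlo chi^2
test against datasets simulated from the fitted parameters, and a
stability filter excludes run-down/run-up recordings before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .types import ParameterError, QuantalParams

__all__ = [
    "QuantalFit",
    "StabilityResult",
    "binomial_density",
    "log_likelihood",
    "moments",
    "fit_quantal",
    "gof_monte_carlo",
    "stability_filter",
]

N_MAX = 14  # cap on candidate release-site counts; boundary fits are discarded


@dataclass
class QuantalFit:
    """Result of the binomial-model maximum-likelihood fit."""

    params: QuantalParams | None
    log_likelihood: float
    n_scan: list[tuple[int, float]]
    gof_p: float | None = None
    converged: bool = True
    excluded: bool = False
    excluded_reason: str | None = None
    n_amplitudes: int = 0


@dataclass
class StabilityResult:
    """Outcome of the recording-stability filter."""

    keep: bool
    drift: float  # |reference - mean(last 10)| / reference
    evaluable: bool = True
    reason: str | None = None


def moments(params: QuantalParams) -> tuple[float, float]:
    """Closed-form release mean n*p*q and s.d. q*sqrt(n*p*(1-p))."""
    n, p, q = params.n_sites, params.p_release, params.q_size
    return n * p * q, q * np.sqrt(n * p * (1.0 - p))


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _log_density(v: np.ndarray, params: QuantalParams) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ParameterError("amplitudes must be finite")
    n, p = params.n_sites, params.p_release
    m = np.arange(n + 1)
    with np.errstate(divide="ignore"):
        log_w = (
            gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
            + m * np.log(p if p > 0 else 1e-300)
            + (n - m) * np.log1p(-min(p, 1 - 1e-300))
        )
    sigma = params.sigma_m(m)
    if np.any(sigma <= 0):
        raise ParameterError("mixture component s.d. must be positive")
    mu = params.v0 + m * params.q_size
    # (len(v), n+1) component log densities
    z = (v[:, None] - mu[None, :]) / sigma[None, :]
    comp = -0.5 * z**2 - np.log(sigma)[None, :] - _LOG_SQRT_2PI
    log_release = logsumexp(comp + log_w[None, :], axis=1)
    if params.p_stim >= 1.0:
        return log_release
    if params.sigma_noise <= 0:
        raise ParameterError("p_stim < 1 requires sigma_noise > 0")
    zf = (v - params.v0) / params.sigma_noise
    log_fail = -0.5 * zf**2 - np.log(params.sigma_noise) - _LOG_SQRT_2PI
    return np.logaddexp(
        np.log(params.p_stim) + log_release, np.log1p(-params.p_stim) + log_fail
    )


def binomial_density(v: np.ndarray | float, params: QuantalParams) -> np.ndarray:
    """Model density f(v) of observing amplitude(s) v."""
    scalar = np.isscalar(v)
    out = np.exp(_log_density(np.atleast_1d(np.asarray(v, dtype=float)), params))
    return float(out[0]) if scalar else out


def log_likelihood(amplitudes: np.ndarray, params: QuantalParams) -> float:
    return float(_log_density(np.asarray(amplitudes, dtype=float), params).sum())


# ------------------------------------------------------------------ fitting


def _pack(p: float, q: float, v0: float, sigma_q: float, fit_sigma_q: bool) -> np.ndarray:
    theta = [np.log(p / (1 - p)), np.log(q), v0]
    if fit_sigma_q:
        theta.append(np.log(max(sigma_q, 1e-6)))
    return np.asarray(theta)


def _unpack(
    theta: np.ndarray, n: int, noise_sd: float, variance_model: str,
    p_stim: float, fit_sigma_q: bool,
) -> QuantalParams:
    p = 1.0 / (1.0 + np.exp(-theta[0]))
    q = float(np.exp(theta[1]))
    v0 = float(theta[2])
    sigma_q = float(np.exp(theta[3])) if fit_sigma_q else 0.0
    return QuantalParams(
        n_sites=n,
        p_release=min(max(p, 1e-9), 1 - 1e-9),
        q_size=q,
        v0=v0,
        sigma_noise=noise_sd,
        sigma_q=sigma_q,
        p_stim=p_stim,
        variance_model=variance_model,
    )


def _starting_points(
    amps: np.ndarray, n: int, noise_sd: float, n_starts: int,
    rng: np.random.Generator, fit_sigma_q: bool,
) -> list[np.ndarray]:
    """Moment-based starts jittered across the (p, q) plane."""
    mean = float(amps.mean())
    spread = float(amps.std())
    starts = []
    p_grid = np.linspace(0.15, 0.85, n_starts)
    for i in range(n_starts):
        p0 = p_grid[i]
        q0 = abs(mean) / (n * p0) if mean != 0 else max(spread, noise_sd)
        q0 = max(q0, noise_sd / 2, 1e-3)
        q0 *= np.exp(rng.normal(0.0, 0.2))
        v0 = float(rng.normal(0.0, noise_sd / 4)) if noise_sd > 0 else 0.0
        sq0 = max(noise_sd / 2, 1e-3)
        starts.append(_pack(p0, q0, v0, sq0, fit_sigma_q))
    return starts


def _make_nll(
    amps: np.ndarray, n: int, noise_sd: float, variance_model: str,
    p_stim: float, fit_sigma_q: bool,
):
    """Negative log-likelihood over the unconstrained parameter vector.

    Equivalent to -log_likelihood(amps, _unpack(theta, ...)) but without
    per-call parameter-object construction — this sits inside the
    Nelder-Mead inner loop.
    """
    m = np.arange(n + 1, dtype=float)
    log_choose = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    v = amps[:, None]
    noise_var = noise_sd**2
    flat = variance_model == "flat"
    m_pos = (m > 0).astype(float)

    def nll(theta: np.ndarray) -> float:
        p = 1.0 / (1.0 + np.exp(-theta[0]))
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        q = np.exp(theta[1])
        v0 = theta[2]
        sq2 = np.exp(2.0 * theta[3]) if fit_sigma_q else 0.0
        if not np.isfinite(q) or q <= 0:
            return np.inf
        var = noise_var + (m_pos * sq2 if flat else m * sq2)
        sigma = np.sqrt(var)
        log_w = log_choose + m * np.log(p) + (n - m) * np.log1p(-p)
        z = (v - (v0 + m * q)[None, :]) / sigma[None, :]
        a = -0.5 * z * z - (np.log(sigma) + _LOG_SQRT_2PI - log_w)[None, :]
        # inline log-sum-exp over mixture components (hot loop)
        amax = a.max(axis=1)
        ll = np.log(np.exp(a - amax[:, None]).sum(axis=1)) + amax
        if p_stim < 1.0:
            zf = (amps - v0) / noise_sd
            log_fail = -0.5 * zf**2 - np.log(noise_sd) - _LOG_SQRT_2PI
            ll = np.logaddexp(np.log(p_stim) + ll, np.log1p(-p_stim) + log_fail)
        total = ll.sum()
        return -total if np.isfinite(total) else np.inf

    return nll


def _lowest_n(amps: np.ndarray, noise_sd: float) -> int:
    """Data-driven lower bound: quanta needed to span the amplitude range.

    With one release site the largest response is one quantal size above
    the offset; the observed range divided by a rough quantal-size guess
    (the smallest well-separated positive amplitude) bounds n from below.
    Conservative failure modes fall back to 1.
    """
    positive = amps[amps > 3 * noise_sd]
    if positive.size == 0:
        return 1
    q_guess = np.percentile(positive, 10)
    if q_guess <= 0:
        return 1
    n_lo = int(np.ceil(positive.max() / q_guess - 0.25))
    return min(max(n_lo, 1), N_MAX)


def fit_quantal(
    amplitudes: np.ndarray,
    noise_sd: float,
    variance_model: str = "type1",
    p_stim: float = 1.0,
    fit_sigma_q: bool = True,
    n_starts: int = 10,
    n_min: int | None = None,
    seed: int = 0,
    selection_margin: float = 2.0,
) -> QuantalFit:
    """Maximum-likelihood binomial-model fit of an amplitude sample.

    ``noise_sd`` is the recording noise s.d. measured independently (RMS
    of the baseline) and is held fixed.  For each candidate n from the
    lowest data-driven estimate up to 14, the likelihood is maximized by
    Nelder-Mead from ``n_starts`` starting points; the selected n is the
    smallest whose log-likelihood lies within ``selection_margin`` of the
    best (parsimony tie-break).  A fit that selects the 14-site cap is
    discarded; a sample indistinguishable from pure noise is flagged as
    unidentifiable.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 30:
        warnings.warn(f"only {amps.size} amplitudes (< 30); fit may be unstable")
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    lo = n_min if n_min is not None else _lowest_n(amps, noise_sd)

    n_scan: list[tuple[int, float]] = []
    best_by_n: dict[int, tuple[float, QuantalParams]] = {}
    for n in range(lo, N_MAX + 1):
        nll = _make_nll(amps, n, noise_sd, variance_model, p_stim, fit_sigma_q)
        best_ll = -np.inf
        best_theta: np.ndarray | None = None
        for theta0 in _starting_points(amps, n, noise_sd, n_starts, rng, fit_sigma_q):
            res = optimize.minimize(
                nll, theta0, method="Nelder-Mead",
                options={"maxiter": 200 * theta0.size, "xatol": 1e-3, "fatol": 1e-5},
            )
            if np.isfinite(res.fun) and -res.fun > best_ll:
                best_ll = -res.fun
                best_theta = res.x
        n_scan.append((n, best_ll))
        if best_theta is not None:
            best_by_n[n] = (
                best_ll,
                _unpack(best_theta, n, noise_sd, variance_model, p_stim, fit_sigma_q),
            )

    if not best_by_n:
        return QuantalFit(
            params=None, log_likelihood=-np.inf, n_scan=n_scan,
            converged=False, n_amplitudes=amps.size,
        )

    top_ll = max(ll for ll, _ in best_by_n.values())
    selected_n = min(n for n, (ll, _) in best_by_n.items() if ll >= top_ll - selection_margin)
    ll, params = best_by_n[selected_n]
    fit = QuantalFit(
        params=params, log_likelihood=ll, n_scan=n_scan, n_amplitudes=amps.size
    )
    if selected_n == N_MAX:
        fit.excluded = True
        fit.excluded_reason = "n at 14-site cap; fit discarded"
    release_mean, _ = moments(params)
    if abs(release_mean) < noise_sd / 2:
        fit.excluded = True
        fit.excluded_reason = (fit.excluded_reason or "") + " release unidentifiable (p~0)"
        fit.excluded_reason = fit.excluded_reason.strip()
    return fit


# ------------------------------------------------------------------ GoF


def _model_quantiles(params: QuantalParams, probs: np.ndarray) -> np.ndarray:
    """Quantiles of the fitted mixture via CDF inversion on a grid."""
    _, release_sd = moments(params)
    span = abs(params.q_size) * params.n_sites + 6 * (
        params.sigma_noise + params.sigma_q + release_sd / max(params.n_sites, 1)
    )
    lo = params.v0 - 6 * params.sigma_noise - abs(params.q_size)
    hi = params.v0 + span
    grid = np.linspace(lo, hi, 4001)
    pdf = binomial_density(grid, params)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    return np.interp(probs, cdf, grid)


def _chi2_stat(amps: np.ndarray, edges: np.ndarray, expected: np.ndarray) -> float:
    obs, _ = np.histogram(amps, bins=edges)
    return float(((obs - expected) ** 2 / expected).sum())


def gof_monte_carlo(
    fit: QuantalFit,
    amplitudes: np.ndarray,
    n_sims: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo chi^2 goodness-of-fit p-value for a converged fit.

    Observations are binned into equal-probability bins under the fitted
    model (>= 5 expected per bin, adaptively re-binned when the sample is
    small); the p-value is the fraction of simulated datasets (drawn from
    the fitted parameters) whose chi^2 meets or exceeds the observed one.
    """
    from .synthetic import simulate_quantal_amplitudes

    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    if not fit.converged or fit.params is None:
        raise ParameterError("goodness of fit requires a converged fit")
    amps = np.asarray(amplitudes, dtype=float)
    n_obs = amps.size
    n_bins = min(10, n_obs // 5)
    if n_bins < 3:
        warnings.warn("fewer than 3 bins with expected >= 5; re-binning to 3")
        n_bins = 3
    inner = _model_quantiles(fit.params, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.concatenate([[-np.inf], inner, [np.inf]])
    expected = np.full(n_bins, n_obs / n_bins)

    observed_stat = _chi2_stat(amps, edges, expected)
    rng = np.random.default_rng(seed)
    sim_stats = np.empty(n_sims)
    for s in range(n_sims):
        sim = simulate_quantal_amplitudes(fit.params, n_obs, rng)
        sim_stats[s] = _chi2_stat(sim, edges, expected)
    p = float((sim_stats >= observed_stat).mean())
    fit.gof_p = p
    return p


# ------------------------------------------------------------------ stability


def stability_filter(
    trial_amplitudes: np.ndarray,
    threshold: float = 0.30,
    reference: str = "first10",
) -> StabilityResult:
    """Exclude recordings whose response drifts by more than 30%.

    Compares an early reference — the mean of the first ten trials by
    default (``reference="first"`` uses the literal first trial) — with
    the mean of the last ten trials; drift strictly above ``threshold``
    excludes the recording.  Fewer than 11 trials is not evaluable.
    """
    amps = np.asarray(trial_amplitudes, dtype=float)
    if amps.size < 11:
        return StabilityResult(
            keep=True, drift=np.nan, evaluable=False,
            reason=f"{amps.size} trials (< 11): stability not evaluable",
        )
    ref = amps[0] if reference == "first" else amps[:10].mean()
    last = amps[-10:].mean()
    if ref == 0:
        return StabilityResult(
            keep=False, drift=np.inf, reason="zero reference amplitude"
        )
    drift = abs(ref - last) / abs(ref)
    return StabilityResult(keep=not drift > threshold, drift=float(drift))
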