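"""In-vivo stage: stimulus z-scoring, optogenetic light locking,
conditional Granger-causality connectivity and freezing quantification.

Spike trains are converted to continuous signals by 1-ms binning and
convolution with a causal half-Gaussian kernel (5-ms width).  A vector
autoregressive (VAR) model with BIC-selected order is fitted to all
units jointly (rejected if the companion-matrix spectral radius reaches
1); the time-domain conditional Granger causality of i onto j is the log
ratio of unit j's residual variance between the model omitting unit i's
lags and the full model, with an asymptotic chi^2 likelihood-ratio test
per ordered pair at P < 0.001.  The model sees only firing increases, so
it infers excitatory but not inhibitory connections.  Causal density is
the mean pairwise-conditional causality, normalized across the dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import ParameterError, SpikeTrainSet

__all__ = [
    "ZScoreResult",
    "GCResult",
    "bin_and_zscore",
    "classify_responsive",
    "classify_light_locked",
    "spikes_to_signal",
    "half_gaussian_kernel",
    "fit_var_and_gc",
    "connectivity_fraction_in_vivo",
    "normalize_causal_density",
    "percent_overlap",
    "freezing_percentage",
]


# ---------------------------------------------------------------- z-scoring


@dataclass
class ZScoreResult:
    """Stimulus-locked z-scores for one unit.

    ``z`` covers baseline + poststimulus bins (``n_baseline_bins`` of
    them precede the stimulus); ``bin_centers_ms`` is relative to onset.
    """

    z: np.ndarray
    bin_centers_ms: np.ndarray
    n_baseline_bins: int
    baseline_mean: float
    baseline_sd: float
    flags: list[str] = field(default_factory=list)

    @property
    def z_post(self) -> np.ndarray:
        return self.z[self.n_baseline_bins :]


def bin_and_zscore(
    timestamps_ms: np.ndarray,
    stimulus_onsets_ms: np.ndarray,
    bin_ms: float = 50.0,
    baseline_ms: float = 500.0,
    response_ms: float = 500.0,
) -> ZScoreResult:
    """Peristimulus z-score series against the prestimulus baseline.

    Counts are binned per stimulus repetition and averaged across
    repetitions; z(t) = (count(t) - baseline mean) / baseline s.d.  The
    baseline moments are estimated from the per-repetition baseline bin
    counts (not the handful of averaged bins) and the s.d. is scaled by
    1/sqrt(n_repetitions) to refer to the trial-averaged counts, which
    keeps the 3-s.d. criterion calibrated.
    """
    ts = np.asarray(timestamps_ms, dtype=float)
    onsets = np.asarray(stimulus_onsets_ms, dtype=float)
    if onsets.size < 1:
        raise ParameterError("need at least one stimulus onset")
    if baseline_ms <= 0:
        raise ParameterError("baseline must precede the stimulus (baseline_ms > 0)")
    edges = np.arange(-baseline_ms, response_ms + bin_ms / 2, bin_ms)
    per_rep = np.stack(
        [np.histogram(ts - onset, bins=edges)[0] for onset in onsets]
    ).astype(float)
    counts = per_rep.mean(axis=0)
    n_base = int(round(baseline_ms / bin_ms))
    base_samples = per_rep[:, :n_base].ravel()
    mu = float(base_samples.mean())
    sd = (
        float(base_samples.std(ddof=1)) / np.sqrt(onsets.size)
        if base_samples.size > 1
        else 0.0
    )
    flags = []
    if ts.size == 0:
        flags.append("empty_train")
    if sd == 0:
        flags.append("zero_baseline_sd")
        z = np.full_like(counts, np.nan)
    else:
        z = (counts - mu) / sd
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ZScoreResult(
        z=z, bin_centers_ms=centers, n_baseline_bins=n_base,
        baseline_mean=mu, baseline_sd=sd, flags=flags,
    )


def classify_responsive(result: ZScoreResult, threshold: float = 3.0) -> bool:
    """Responsive iff any poststimulus bin exceeds 3 baseline s.d."""
    if result.flags:
        return False
    return bool(np.any(result.z_post > threshold))


def classify_light_locked(
    timestamps_ms: np.ndarray,
    pulse_times_ms: np.ndarray,
    max_latency_ms: float = 5.0,
    max_jitter_ms: float = 5.0,
    min_reliability: float = 0.5,
    search_ms: float = 20.0,
) -> tuple[bool, dict[str, float]]:
    """Light-locked iff first-spike latencies are millisecond precise.

    Locked when the median first-spike latency and its s.d. across
    pulses are both below 5 ms, and a spike follows within 5 ms of at
    least half the pulses (reliability floor above chance).
    """
    ts = np.asarray(timestamps_ms, dtype=float)
    pulses = np.asarray(pulse_times_ms, dtype=float)
    if pulses.size < 10:
        raise ParameterError("need >= 10 light pulses")
    latencies = []
    hits = 0
    for p in pulses:
        after = ts[(ts >= p) & (ts < p + search_ms)]
        if after.size:
            lat = after[0] - p
            latencies.append(lat)
            if lat < max_latency_ms:
                hits += 1
    stats_out = {
        "median_latency_ms": float(np.median(latencies)) if latencies else np.inf,
        "latency_sd_ms": float(np.std(latencies)) if len(latencies) > 1 else np.inf,
        "reliability": hits / pulses.size,
        "n_pulses": float(pulses.size),
    }
    locked = (
        stats_out["median_latency_ms"] < max_latency_ms
        and stats_out["latency_sd_ms"] < max_jitter_ms
        and stats_out["reliability"] >= min_reliability
    )
    return bool(locked), stats_out


# ---------------------------------------------------------------- signals


def half_gaussian_kernel(width_ms: float = 5.0, bin_ms: float = 1.0) -> np.ndarray:
    """Causal half-Gaussian kernel, unit sum, mass at/after the spike.

    The kernel spans lags 0..width; sigma = width/3 so the support holds
    ~3 sigma of the half-Gaussian.
    """
    lags = np.arange(0.0, width_ms + bin_ms / 2, bin_ms)
    sigma = width_ms / 3.0
    k = np.exp(-0.5 * (lags / sigma) ** 2)
    return k / k.sum()


def spikes_to_signal(
    timestamps_ms: np.ndarray, duration_ms: float, width_ms: float = 5.0
) -> np.ndarray:
    """Continuous-rate signal: 1-ms binary bins * causal half-Gaussian."""
    n_bins = int(round(duration_ms))
    ts = np.asarray(timestamps_ms, dtype=float)
    if ts.size and (ts.min() < 0 or ts.max() >= duration_ms):
        raise ParameterError("duration must cover all timestamps")
    binned = np.zeros(n_bins)
    idx = np.floor(ts).astype(int)
    np.add.at(binned, idx, 1.0)
    kernel = half_gaussian_kernel(width_ms)
    return np.convolve(binned, kernel)[:n_bins]


# ---------------------------------------------------------------- Granger


@dataclass
class GCResult:
    """Conditional Granger-causality connectivity for one recording."""

    gc_matrix: np.ndarray  # (N, N), gc[i, j] = causality of i onto j
    p_matrix: np.ndarray
    order: int
    spectral_radius: float
    causal_density: float  # mean pairwise-conditional causality (raw)
    edges: list[tuple[int, int]]
    alpha: float
    unit_ids: list[str] = field(default_factory=list)
    causal_density_normalized: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.gc_matrix.shape[0]


def _lag_matrix(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Design (T-p, N*p) of stacked lags and targets (T-p, N)."""
    n, t = x.shape
    rows = t - order
    design = np.empty((rows, n * order))
    for lag in range(1, order + 1):
        design[:, (lag - 1) * n : lag * n] = x[:, order - lag : t - lag].T
    return design, x[:, order:].T


def _fit_var(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS VAR fit: coefficients (N*p, N), residuals, residual covariance."""
    design, target = _lag_matrix(x, order)
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    sigma = resid.T @ resid / resid.shape[0]
    return coef, resid, sigma


def _bic(x: np.ndarray, order: int) -> float:
    _, resid, sigma = _fit_var(x, order)
    t_eff = resid.shape[0]
    n = x.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return float(logdet + (n * n * order) * np.log(t_eff) / t_eff)


def _spectral_radius(coef: np.ndarray, n: int, order: int) -> float:
    """Spectral radius of the VAR companion matrix."""
    companion = np.zeros((n * order, n * order))
    for lag in range(order):
        companion[:n, lag * n : (lag + 1) * n] = coef[lag * n : (lag + 1) * n].T
    if order > 1:
        companion[n:, :-n] = np.eye(n * (order - 1))
    return float(np.abs(np.linalg.eigvals(companion)).max())


def fit_var_and_gc(
    signals: np.ndarray,
    max_order: int = 15,
    alpha: float = 0.001,
    unit_ids: list[str] | None = None,
    min_duration_ms: float = 60_000.0,
) -> GCResult:
    """Conditional Granger causality between all ordered unit pairs.

    ``signals`` is (N, T) at 1-ms resolution.  The VAR order is selected
    by BIC on the full model; nonstationary models (spectral radius
    >= 1) are rejected.  GC(i->j) = ln(sigma2_j[reduced] /
    sigma2_j[full]) where the reduced model omits unit i's lags from
    unit j's equation; significance is the asymptotic chi^2(order)
    likelihood-ratio test at ``alpha`` (per-pair, uncorrected).
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    n, t = x.shape
    if n < 2:
        raise ParameterError("need >= 2 units for causality analysis")
    if t < min_duration_ms:
        warnings.warn(
            f"signal duration {t} ms is below the configured minimum "
            f"({min_duration_ms:.0f} ms); estimates may be unstable"
        )
    x = x - x.mean(axis=1, keepdims=True)
    sds = x.std(axis=1)
    flags: list[str] = []
    if np.any(sds == 0):
        raise ParameterError("constant (silent) signal: unit has no variance")
    corr = np.corrcoef(x)
    if np.any(np.abs(corr[~np.eye(n, dtype=bool)]) > 0.999):
        flags.append("collinear_signals")
        warnings.warn("near-duplicate signals detected; model is degenerate")

    bics = {p: _bic(x, p) for p in range(1, max_order + 1)}
    order = min(bics, key=bics.get)
    coef, resid, sigma = _fit_var(x, order)
    radius = _spectral_radius(coef, n, order)
    if radius >= 1.0:
        raise ParameterError(
            f"nonstationary VAR model (spectral radius {radius:.3f} >= 1)"
        )

    t_eff = resid.shape[0]
    full_var = np.diag(sigma)
    design, target = _lag_matrix(x, order)
    gc = np.zeros((n, n))
    pvals = np.ones((n, n))
    lag_cols = np.arange(order) * n  # offsets of each lag block
    for i in range(n):
        keep = np.ones(n * order, dtype=bool)
        keep[lag_cols + i] = False  # drop unit i's lags
        design_red = design[:, keep]
        coef_red, *_ = np.linalg.lstsq(design_red, target, rcond=None)
        resid_red = target - design_red @ coef_red
        red_var = (resid_red**2).mean(axis=0)
        for j in range(n):
            if i == j:
                continue
            if full_var[j] <= 0:
                flags.append("degenerate_residual")
                continue
            val = float(np.log(red_var[j] / full_var[j]))
            gc[i, j] = max(val, 0.0)
            lr = t_eff * val
            pvals[i, j] = float(stats.chi2.sf(max(lr, 0.0), df=order))

    off = ~np.eye(n, dtype=bool)
    edges = [tuple(e) for e in np.argwhere((pvals < alpha) & off)]
    density = float(gc[off].mean())
    return GCResult(
        gc_matrix=gc,
        p_matrix=pvals,
        order=order,
        spectral_radius=radius,
        causal_density=density,
        edges=edges,  # type: ignore[arg-type]
        alpha=alpha,
        unit_ids=unit_ids or [f"u{i:02d}" for i in range(n)],
        flags=flags,
    )


def connectivity_fraction_in_vivo(
    results: GCResult | list[GCResult],
) -> dict[str, float]:
    """Significant ordered pairs as % of possible pairs, per animal.

    Aggregates a list of per-animal results as mean +/- s.d.
    """
    if isinstance(results, GCResult):
        results = [results]
    fracs = []
    for r in results:
        n = r.n_units
        possible = n * (n - 1)
        fracs.append(100.0 * len(r.edges) / possible if possible else np.nan)
    fr = np.asarray(fracs, dtype=float)
    return {
        "per_animal_pct": fr,  # type: ignore[dict-item]
        "mean_pct": float(np.nanmean(fr)),
        "sd_pct": float(np.nanstd(fr, ddof=1)) if fr.size > 1 else 0.0,
    }


def normalize_causal_density(results: list[GCResult]) -> list[float]:
    """Normalize causal densities to the dataset-wide maximum (AU)."""
    raw = np.array([r.causal_density for r in results], dtype=float)
    top = raw.max()
    if top <= 0:
        return [0.0] * len(results)
    normed = raw / top
    for r, v in zip(results, normed):
        r.causal_density_normalized = float(v)
    return list(normed)


def percent_overlap(n_overlap: int, n_total: int) -> float:
    """Overlap percentage, e.g. CS+-responsive units also light responsive."""
    if n_total <= 0:
        raise ParameterError("n_total must be > 0")
    if n_overlap > n_total:
        raise ParameterError("overlap cannot exceed the total")
    return 100.0 * n_overlap / n_total


# ---------------------------------------------------------------- behavior


def freezing_percentage(
    movement: np.ndarray,
    fs_hz: float,
    window_s: tuple[float, float],
    min_bout_s: float = 2.0,
) -> float:
    """Freezing time as % of the stimulus window.

    ``movement`` is a boolean series (True = moving) sampled at
    ``fs_hz``; only no-movement bouts lasting at least ``min_bout_s``
    (clipped to the window) count as freezing.
    """
    mv = np.asarray(movement, dtype=bool)
    start, end = window_s
    if not end > start:
        raise ParameterError("window end must exceed start")
    i0, i1 = int(round(start * fs_hz)), int(round(end * fs_hz))
    if i1 > mv.size:
        raise ParameterError("movement series does not cover the window")
    still = ~mv[i0:i1]
    # run-length encode the stillness bouts
    padded = np.concatenate([[False], still, [False]])
    changes = np.flatnonzero(np.diff(padded.astype(int)))
    bout_starts, bout_ends = changes[::2], changes[1::2]
    durations = (bout_ends - bout_starts) / fs_hz
    frozen_s = float(durations[durations >= min_bout_s].sum())
    return 100.0 * frozen_s / (end - start)
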