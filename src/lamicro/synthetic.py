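"""Synthetic generators emulating the statistical structure of the recordings.

Every downstream stage — EPSP detection, quantal fitting, motif
statistics, Granger causality, stimulus-response z-scoring — can be
exercised on data with planted ground truth:

* amplitude samples from the binomial release model with Gaussian noise
  and quantal variance;
* spatially embedded directed networks with distance-dependent
  connection probability;
* multi-trial sweep sets containing stimulus-locked EPSP transients with
  failures and short-term dynamics;
* discrete-time coupled spike trains with known directed causal edges;
* stimulus-evoked rasters with controlled evoked-rate changes.

All generators accept a single integer seed and split it deterministically
per cell/trial, so identical seeds give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import (
    CellRecord,
    CircuitGraph,
    DistanceProfile,
    NetworkSpec,
    ParameterError,
    ProtocolSpec,
    QuantalParams,
    SpikeTrainSet,
    SweepSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConnection",
    "simulate_quantal_amplitudes",
    "simulate_network",
    "simulate_sweep_set",
    "simulate_coupled_spikes",
    "simulate_response_raster",
    "epsp_kernel",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ------------------------------------------------------------ quantal samples


def simulate_quantal_amplitudes(
    params: QuantalParams, n_trials: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw response amplitudes from the binomial release model.

    Each amplitude is ``v0 + m*q + noise`` with ``m ~ Binomial(n, p)``
    when stimulation reaches the release sites (probability ``p_stim``),
    and ``v0 + noise`` otherwise.  The noise s.d. follows the chosen
    quantal-variance model (``sigma_m``).
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    rng = _rng(seed)
    reached = rng.random(n_trials) < params.p_stim
    m = np.where(
        reached, rng.binomial(params.n_sites, params.p_release, size=n_trials), 0
    )
    sigma = params.sigma_m(m)
    # failed stimulation carries recording noise only
    sigma = np.where(reached, sigma, params.sigma_noise)
    return params.v0 + m * params.q_size + rng.normal(0.0, 1.0, n_trials) * sigma


# ------------------------------------------------------------ spatial network


def simulate_network(spec: NetworkSpec) -> CircuitGraph:
    """Draw a directed graph with distance-dependent edge probabilities.

    Each ordered pair (i, j), i != j, is connected independently with
    probability ``profile(distance(i, j))``; self-edges never occur.
    Distances beyond the profile support get probability 0.
    """
    rng = _rng(spec.seed)
    pos = spec.positions
    n = pos.shape[0]
    cells = [
        CellRecord(cell_id=f"c{i:03d}", position=(pos[i, 0], pos[i, 1]))
        for i in range(n)
    ]
    if n == 1:
        return CircuitGraph(cells=cells, adjacency=np.zeros((1, 1), dtype=bool))
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    if np.any(dist[~np.eye(n, dtype=bool)] > spec.profile.max_radius):
        logger.info("distances beyond the profile support use probability 0")
    prob = spec.profile(dist)
    np.fill_diagonal(prob, 0.0)
    adjacency = rng.random((n, n)) < prob
    return CircuitGraph(cells=cells, adjacency=adjacency)


# ------------------------------------------------------------ sweep sets


def epsp_kernel(
    t_ms: np.ndarray, rise_ms: float = 1.0, decay_ms: float = 10.0
) -> np.ndarray:
    """Difference-of-exponentials EPSP shape, peak-normalized to 1."""
    t = np.asarray(t_ms, dtype=float)
    tt = np.maximum(t, 0.0)
    shape = np.where(t >= 0, np.exp(-tt / decay_ms) - np.exp(-tt / rise_ms), 0.0)
    t_peak = rise_ms * decay_ms / (decay_ms - rise_ms) * np.log(decay_ms / rise_ms)
    peak = np.exp(-t_peak / decay_ms) - np.exp(-t_peak / rise_ms)
    return shape / peak


@dataclass(frozen=True)
class SyntheticConnection:
    """Planted ground truth for one probed pair.

    ``amplitude_uv`` is the single-pulse EPSP peak (µV); ``scale`` (length
    n_pulses + 1) multiplies it per stimulus index to emulate short-term
    facilitation/depression; ``failure_p`` is the per-pulse probability
    that release fails entirely.
    """

    latency_ms: float = 2.0
    amplitude_uv: float = 800.0
    scale: tuple[float, ...] | None = None
    failure_p: float = 0.0
    rise_ms: float = 1.0
    decay_ms: float = 10.0

    def scales(self, n_stimuli: int) -> np.ndarray:
        if self.scale is None:
            return np.ones(n_stimuli)
        s = np.asarray(self.scale, dtype=float)
        if s.size != n_stimuli:
            raise ParameterError(
                f"scale must have {n_stimuli} entries (train + recovery), got {s.size}"
            )
        return s


_AP_HALF_WIDTH_MS = 0.5
_BASELINE_MV = -65.0


def simulate_sweep_set(
    connection: SyntheticConnection | None,
    protocol: ProtocolSpec = ProtocolSpec(),
    noise_sd_uv: float = 20.0,
    seed: int | np.random.Generator = 0,
    sampling_rate: float = 10_000.0,
    ap_delay_ms: float = 1.0,
) -> SweepSet:
    """Simulate a probed pair: presynaptic APs plus a postsynaptic trace.

    The presynaptic trace ("pre") carries a stereotyped AP at each pulse
    (peaking ``ap_delay_ms`` after pulse onset); the postsynaptic trace
    ("post") carries, per pulse, an EPSP transient of the planted latency
    and per-stimulus amplitude, stochastically omitted with ``failure_p``,
    plus white Gaussian noise.  ``connection=None`` yields noise only.
    """
    if noise_sd_uv < 0:
        raise ParameterError("noise_sd_uv must be >= 0")
    rng = _rng(seed)
    pulse_times = protocol.pulse_times()
    dt_ms = 1000.0 / sampling_rate
    n_samples = int(round((pulse_times[-1] + 90.0) / dt_ms))
    t = np.arange(n_samples) * dt_ms
    n_stim = pulse_times.size

    ap_peaks = pulse_times + ap_delay_ms
    pre_single = np.full(n_samples, _BASELINE_MV)
    for peak in ap_peaks:
        # triangular AP waveform, 100 mV tall, ~1 ms wide
        ap = 100.0 * np.clip(1.0 - np.abs(t - peak) / _AP_HALF_WIDTH_MS, 0.0, None)
        pre_single = pre_single + ap

    noise_sd_mv = noise_sd_uv / 1000.0
    pre = np.tile(pre_single, (protocol.n_trials, 1))
    pre += rng.normal(0.0, noise_sd_mv, pre.shape)

    post = np.full((protocol.n_trials, n_samples), _BASELINE_MV)
    if connection is not None:
        scales = connection.scales(n_stim)
        amp_mv = connection.amplitude_uv / 1000.0
        for trial in range(protocol.n_trials):
            for k, peak in enumerate(ap_peaks):
                if rng.random() < connection.failure_p:
                    continue
                onset = peak + connection.latency_ms
                post[trial] += (
                    amp_mv
                    * scales[k]
                    * epsp_kernel(t - onset, connection.rise_ms, connection.decay_ms)
                )
    post += rng.normal(0.0, noise_sd_mv, post.shape)

    return SweepSet(
        traces={"pre": pre, "post": post},
        sampling_rate=sampling_rate,
        pulse_times=pulse_times,
        stimulated_cell="pre",
        units="mV",
    )


# ------------------------------------------------------------ coupled spikes


def _topological_order(coupling: np.ndarray) -> list[int] | None:
    """Kahn topological order of the nonzero-coupling graph, None if cyclic."""
    n = coupling.shape[0]
    adj = coupling != 0
    indeg = adj.sum(axis=0)
    queue = [i for i in range(n) if indeg[i] == 0]
    order: list[int] = []
    indeg = indeg.copy()
    while queue:
        i = queue.pop()
        order.append(i)
        for j in np.flatnonzero(adj[i]):
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    return order if len(order) == n else None


def _recent_spike(spikes: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Indicator that a spike occurred within [t-hi, t-lo] of each bin t."""
    w = hi - lo + 1
    counts = np.convolve(spikes.astype(float), np.ones(w))[: spikes.size]
    shifted = np.concatenate([np.zeros(lo), counts])[: spikes.size]
    return (shifted > 0).astype(float)


def simulate_coupled_spikes(
    coupling: np.ndarray,
    base_rates: np.ndarray | float,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    lag_window_ms: tuple[int, int] = (1, 5),
) -> SpikeTrainSet:
    """Discrete-time (1-ms) Bernoulli spike trains with directed coupling.

    Unit j's per-bin spike probability is its base rate plus, for every
    spike of unit i within the preceding ``lag_window_ms`` (default
    1-5 ms, the monosynaptic latency range), an additive kick of
    ``coupling[i, j]``.  A zero matrix yields independent trains.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be > 0")
    coupling = np.atleast_2d(np.asarray(coupling, dtype=float))
    n = coupling.shape[0]
    if coupling.shape != (n, n):
        raise ParameterError("coupling must be a square matrix")
    rates = np.broadcast_to(np.asarray(base_rates, dtype=float), (n,))
    if np.any(rates < 0):
        raise ParameterError("rates must be >= 0")
    rng = _rng(seed)
    n_bins = int(round(duration_s * 1000.0))
    p_base = rates / 1000.0
    lo, hi = lag_window_ms
    spikes = np.zeros((n, n_bins), dtype=bool)
    u = rng.random((n, n_bins))
    order = _topological_order(coupling)
    if order is not None:
        # acyclic coupling: simulate units in topological order, vectorized
        for j in order:
            p = np.full(n_bins, p_base[j])
            for i in np.flatnonzero(coupling[:, j]):
                p = p + coupling[i, j] * _recent_spike(spikes[i], lo, hi)
            spikes[j] = u[j] < np.clip(p, 0.0, 1.0)
    else:
        # recurrent coupling: step through time
        for t in range(n_bins):
            p = p_base.copy()
            t0, t1 = max(0, t - hi), max(0, t - lo + 1)
            if t1 > t0:
                recent = spikes[:, t0:t1].any(axis=1).astype(float)
                p = p + recent @ coupling
            spikes[:, t] = u[:, t] < np.clip(p, 0.0, 1.0)
    units = {
        f"u{i:02d}": np.flatnonzero(spikes[i]).astype(float) + 0.5 for i in range(n)
    }
    return SpikeTrainSet(units=units, epoch=(0.0, float(n_bins)))


# ------------------------------------------------------------ evoked rasters


def simulate_response_raster(
    baseline_rate: float,
    evoked_rate: float,
    n_trials: int,
    stimulus_window_s: float = 0.5,
    jitter_ms: float = 0.0,
    seed: int | np.random.Generator = 0,
    pre_s: float = 1.0,
    post_s: float = 1.0,
    locked_pulses_ms: np.ndarray | None = None,
) -> SpikeTrainSet:
    """One unit's stimulus-locked raster with a controlled evoked rate.

    Each of ``n_trials`` repetitions is a Poisson train at
    ``baseline_rate`` except inside the stimulus window, where the rate is
    ``evoked_rate``.  ``locked_pulses_ms`` optionally plants one
    millisecond-jittered spike per listed pulse offset (for light-locking
    analyses).  Events are stored under ``"stim"`` at trial onsets.
    """
    if baseline_rate < 0 or evoked_rate < 0:
        raise ParameterError("rates must be >= 0")
    rng = _rng(seed)
    trial_len = pre_s + stimulus_window_s + post_s
    onsets = pre_s + np.arange(n_trials) * trial_len  # stimulus onset per trial
    ts: list[float] = []
    for k in range(n_trials):
        t0 = k * trial_len
        for seg_start, seg_len, rate in (
            (t0, pre_s, baseline_rate),
            (t0 + pre_s, stimulus_window_s, evoked_rate),
            (t0 + pre_s + stimulus_window_s, post_s, baseline_rate),
        ):
            n_sp = rng.poisson(rate * seg_len)
            ts.extend(seg_start + rng.random(n_sp) * seg_len)
        if locked_pulses_ms is not None:
            for pulse in np.asarray(locked_pulses_ms, dtype=float):
                ts.append(
                    t0
                    + pre_s
                    + pulse / 1000.0
                    + abs(rng.normal(0.0, jitter_ms)) / 1000.0
                )
    ts_ms = np.sort(np.asarray(ts)) * 1000.0
    epoch = (0.0, n_trials * trial_len * 1000.0)
    return SpikeTrainSet(
        units={"u00": ts_ms},
        epoch=epoch,
        events={"stim": onsets * 1000.0},
    )
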