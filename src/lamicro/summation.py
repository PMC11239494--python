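"""AP threshold, spatial-summation regression and temporal-summation factor.

Spike threshold is read from a current-ramp response as the voltage at
the apex of the second time-derivative preceding the AP peak (after
polynomial smoothing; raw second differences at 10 kHz are noise
dominated).  Spatial summation is an ordinary least-squares line through
summed convergent-motif uEPSP amplitudes versus input count, run
separately for first-pulse and recovery-pulse amplitudes.  Dividing the
threshold depolarization by the per-input slope yields the distribution
of synaptic inputs required to trigger a postsynaptic AP; temporal
summation during a 20-Hz train rescales that requirement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .types import ParameterError

__all__ = [
    "ApThreshold",
    "SummationFit",
    "ap_threshold_from_ramp",
    "spatial_summation_fit",
    "required_inputs",
    "temporal_summation_factor",
]


@dataclass
class ApThreshold:
    threshold_mv: float
    initiation_time_ms: float
    peak_time_ms: float


@dataclass
class SummationFit:
    slope: float  # mV per input
    intercept: float  # mV
    r_value: float
    stderr: float
    intercept_stderr: float


def ap_threshold_from_ramp(
    trace_mv: np.ndarray,
    sampling_rate: float,
    smooth_ms: float = 1.0,
    min_peak_mv: float = 0.0,
    search_back_ms: float = 5.0,
) -> ApThreshold:
    """AP threshold and initiation time from a ramp-protocol trace.

    Initiation time is the apex (maximum) of the smoothed second time
    derivative within ``search_back_ms`` before the first AP peak; the
    threshold is the membrane voltage at that instant.  Raises when the
    trace contains no AP (no sample above ``min_peak_mv``).
    """
    v = np.asarray(trace_mv, dtype=float)
    fs = sampling_rate
    dt = 1000.0 / fs
    peaks, _ = signal.find_peaks(v, height=min_peak_mv)
    if peaks.size == 0:
        raise ParameterError("trace contains no action potential")
    peak = int(peaks[0])

    window = max(5, int(round(smooth_ms * fs / 1000.0)) | 1)  # odd length
    d2 = signal.savgol_filter(v, window, polyorder=3, deriv=2, delta=dt)
    i0 = max(0, peak - int(round(search_back_ms / dt)))
    if peak <= i0:
        raise ParameterError("AP peak too close to trace start")
    apex = i0 + int(np.argmax(d2[i0:peak]))
    return ApThreshold(
        threshold_mv=float(v[apex]),
        initiation_time_ms=apex * dt,
        peak_time_ms=peak * dt,
    )


def spatial_summation_fit(
    n_inputs: np.ndarray, summed_amplitudes_mv: np.ndarray
) -> SummationFit:
    """OLS line through summed convergent uEPSP amplitude vs input count."""
    x = np.asarray(n_inputs, dtype=float)
    y = np.asarray(summed_amplitudes_mv, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ParameterError("need >= 2 (input count, amplitude) points")
    if np.unique(x).size < 2:
        raise ParameterError("need >= 2 distinct input counts for a regression")
    res = stats.linregress(x, y)
    return SummationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )


def required_inputs(
    thresholds_mv: np.ndarray,
    slope: float,
    intercept: float = 0.0,
    summation_gain: float = 1.0,
) -> dict[str, float | np.ndarray]:
    """Distribution of synaptic inputs needed to reach AP threshold.

    Per threshold sample (depolarization from rest, mV), inputs =
    (threshold - intercept) / (slope * summation_gain).  A gain > 1
    models temporal summation, shrinking the requirement by exactly
    1/gain.  Requires a positive slope.
    """
    if not slope > 0:
        raise ParameterError("slope must be > 0")
    if not summation_gain > 0:
        raise ParameterError("summation_gain must be > 0")
    th = np.asarray(thresholds_mv, dtype=float)
    inputs = (th - intercept) / (slope * summation_gain)
    return {
        "inputs": inputs,
        "mean": float(inputs.mean()),
        "sd": float(inputs.std(ddof=1)) if inputs.size > 1 else 0.0,
    }


def temporal_summation_factor(
    amplitudes: np.ndarray,
    pulse_times_ms: np.ndarray,
    decay_ms: float = 10.0,
) -> float:
    """Effective per-input depolarization under train accumulation, in %.

    Per-pulse responses are superposed with exponential decay of the
    membrane response: the residual depolarization carried into pulse k
    is sum_{j<k} amp_j * exp(-(t_k - t_j)/decay).  The factor is the
    mean over pulses 2..end of (residual + evoked peak), referenced to
    the first-pulse amplitude, x100.  With no overlap and a flat train
    this is exactly 100%.
    """
    amps = np.asarray(amplitudes, dtype=float)
    times = np.asarray(pulse_times_ms, dtype=float)
    if amps.size != times.size or amps.size < 2:
        raise ParameterError("need per-pulse amplitudes and matching pulse times (>= 2)")
    if amps[0] == 0:
        raise ParameterError("first-pulse amplitude is zero; factor undefined")
    if decay_ms < 0:
        raise ParameterError("decay must be >= 0")
    effective = np.empty(amps.size)
    for k in range(amps.size):
        if decay_ms == 0:
            residual = 0.0
        else:
            residual = float(
                np.sum(amps[:k] * np.exp(-(times[k] - times[:k]) / decay_ms))
            )
        effective[k] = residual + amps[k]
    return float(100.0 * effective[1:].mean() / amps[0])
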