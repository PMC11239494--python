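"""Unitary-connection detection and characterization from multi-patch sweeps.

A connection is called on the 15-trial average of the postsynaptic trace:
a stimulus-locked EPSP is accepted when its onset falls within 5 ms of
the presynaptic AP peak, its across-trial onset jitter is below 2.5 ms,
its amplitude reaches 100 µV (5 pA for EPSC mode) and its area reaches
the minimal-area criterion (1 mV·ms by default).  Accepted connections
are then measured per stimulus across the 8-pulse 20-Hz train plus the
recovery pulse, failures separated from successes, short-term dynamics
classified, and Hebbian potentiation quantified as post/baseline ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import (
    CellRecord,
    CircuitGraph,
    ConnectionRecord,
    ParameterError,
    SweepSet,
    possible_pairs,
)

__all__ = [
    "DetectionCriteria",
    "EpspCall",
    "TrainMeasurement",
    "rms_noise",
    "find_ap_peaks",
    "detect_epsp",
    "measure_train",
    "analyze_pair",
    "assess_connectivity",
    "connectivity_fraction",
    "classify_dynamics",
    "classify_excitability",
    "quantify_potentiation",
    "class_proportions",
]


@dataclass(frozen=True)
class DetectionCriteria:
    """Acceptance criteria for a unitary response.

    Defaults are the EPSP criteria (trace in mV): minimal amplitude
    100 µV, minimal area 1 mV·ms, onset latency < 5 ms after the
    presynaptic AP peak, across-trial jitter < 2.5 ms.  EPSC mode uses a
    5-pA minimal amplitude on pA traces.
    """

    min_amplitude: float = 0.1  # trace units (mV for EPSP)
    min_area: float = 1.0  # trace units x ms
    max_latency_ms: float = 5.0
    max_jitter_ms: float = 2.5
    peak_window_ms: tuple[float, float] = (1.0, 20.0)
    baseline_lead_ms: float = 20.0  # baseline sampled this far before the peak
    baseline_width_ms: float = 5.0
    onset_fraction: float = 0.10  # onset = first crossing of this fraction of peak
    min_trials: int = 15

    @classmethod
    def epsc(cls) -> "DetectionCriteria":
        # pA traces: 5-pA minimal amplitude, area criterion scaled alike
        return cls(min_amplitude=5.0, min_area=5.0)


@dataclass
class EpspCall:
    """An accepted stimulus-locked event on the averaged trace."""

    latency_ms: float
    amplitude: float  # trace units (mV), peak minus baseline
    area: float  # trace units x ms
    jitter_ms: float
    baseline: float
    peak_time_ms: float
    n_trials: int
    flags: list[str] = field(default_factory=list)


@dataclass
class TrainMeasurement:
    """Per-stimulus amplitudes of an accepted connection.

    ``trial_amplitudes`` is (n_trials, n_stimuli) in trace units;
    ``success`` marks trials whose peak clears the failure threshold.
    Mean amplitudes are reported both including failures (failures count
    as their measured residual amplitude) and excluding them.
    """

    trial_amplitudes: np.ndarray
    success: np.ndarray
    amplitudes_incl: np.ndarray
    amplitudes_excl: np.ndarray
    failure_rates: np.ndarray
    failure_threshold: float


def rms_noise(
    trace: np.ndarray,
    sampling_rate: float,
    window_ms: float = 0.5,
    start_ms: float = 0.0,
    pulse_times: np.ndarray | None = None,
) -> float:
    """RMS of the baseline-subtracted trace over a window at trial start.

    The window must sit outside stimulus responses; if any pulse onset
    falls inside it, an error is raised.
    """
    n = int(round(window_ms * sampling_rate / 1000.0))
    if n < 1:
        raise ParameterError("window too short for the sampling rate")
    i0 = int(round(start_ms * sampling_rate / 1000.0))
    if i0 + n > np.asarray(trace).size:
        raise ParameterError("noise window extends past the end of the trace")
    if pulse_times is not None:
        end_ms = start_ms + window_ms
        for p in np.asarray(pulse_times, dtype=float):
            if start_ms <= p < end_ms:
                raise ParameterError(f"noise window overlaps stimulus pulse at {p} ms")
    seg = np.asarray(trace, dtype=float)[i0 : i0 + n]
    seg = seg - seg.mean()
    return float(np.sqrt(np.mean(seg**2)))


def find_ap_peaks(
    pre_trace: np.ndarray,
    pulse_times: np.ndarray,
    sampling_rate: float,
    search_ms: float = 5.0,
) -> np.ndarray:
    """AP peak time (ms) after each stimulus pulse, by local maximum."""
    dt = 1000.0 / sampling_rate
    trace = np.asarray(pre_trace, dtype=float)
    peaks = []
    for p in np.asarray(pulse_times, dtype=float):
        i0 = int(round(p / dt))
        i1 = min(int(round((p + search_ms) / dt)), trace.size)
        if i1 <= i0:
            raise ParameterError(f"pulse at {p} ms is outside the trace")
        peaks.append((i0 + int(np.argmax(trace[i0:i1]))) * dt)
    return np.asarray(peaks)


def _segment(trace: np.ndarray, t0_ms: float, t1_ms: float, fs: float) -> np.ndarray:
    i0 = max(0, int(round(t0_ms * fs / 1000.0)))
    i1 = min(trace.size, max(i0 + 1, int(round(t1_ms * fs / 1000.0))))
    return trace[i0:i1]


def _baseline(
    trace: np.ndarray, peak_time_ms: float, fs: float, crit: DetectionCriteria
) -> float:
    """Mean over a 5-ms window sampled 20 ms before the response peak."""
    t0 = peak_time_ms - crit.baseline_lead_ms
    return float(np.mean(_segment(trace, t0, t0 + crit.baseline_width_ms, fs)))


def _onset_time(
    trace: np.ndarray,
    ap_peak_ms: float,
    peak_idx: int,
    baseline: float,
    amplitude: float,
    fs: float,
    crit: DetectionCriteria,
) -> float | None:
    """First crossing of ``onset_fraction * amplitude`` above baseline."""
    dt = 1000.0 / fs
    i_start = int(round(ap_peak_ms / dt))
    thresh = baseline + crit.onset_fraction * amplitude
    seg = trace[i_start : peak_idx + 1]
    above = np.flatnonzero(seg >= thresh)
    if above.size == 0:
        return None
    return (i_start + above[0]) * dt


def detect_epsp(
    avg_post_trace: np.ndarray,
    ap_peak_time_ms: float,
    per_trial_traces: np.ndarray,
    sampling_rate: float,
    criteria: DetectionCriteria = DetectionCriteria(),
    noise_sd: float | None = None,
) -> EpspCall | None:
    """Call a stimulus-locked event on the averaged postsynaptic trace.

    Returns the accepted event or None.  The peak is searched 1-20 ms
    after the presynaptic AP peak; baseline is the 5-ms mean sampled
    20 ms before the peak; latency runs from the AP peak to the onset
    (first crossing of 10% of the peak above baseline); jitter is the
    s.d. of per-trial onset latencies over success trials.
    """
    avg = np.asarray(avg_post_trace, dtype=float)
    trials = np.atleast_2d(np.asarray(per_trial_traces, dtype=float))
    fs = sampling_rate
    dt = 1000.0 / fs
    flags: list[str] = []
    if trials.shape[0] < criteria.min_trials:
        warnings.warn(
            f"averaged over {trials.shape[0]} trials "
            f"(< {criteria.min_trials}); proceeding with flag"
        )
        flags.append("few_trials")

    w0, w1 = criteria.peak_window_ms
    i0 = int(round((ap_peak_time_ms + w0) / dt))
    i1 = min(int(round((ap_peak_time_ms + w1) / dt)), avg.size)
    if i1 <= i0:
        raise ParameterError("peak search window is outside the trace")
    peak_idx = i0 + int(np.argmax(avg[i0:i1]))
    peak_time = peak_idx * dt
    baseline = _baseline(avg, peak_time, fs, criteria)
    amplitude = float(avg[peak_idx] - baseline)
    if amplitude < criteria.min_amplitude:
        return None

    onset = _onset_time(avg, ap_peak_time_ms, peak_idx, baseline, amplitude, fs, criteria)
    if onset is None:
        return None
    latency = onset - ap_peak_time_ms
    if not (0 < latency < criteria.max_latency_ms):
        return None

    # area above baseline from onset over the EPSP body
    seg = _segment(avg, onset, peak_time + 30.0, fs) - baseline
    area = float(np.clip(seg, 0.0, None).sum() * dt)
    if area < criteria.min_area:
        return None

    if noise_sd is None:
        noise_sd = rms_noise(avg, fs)
    fail_thresh = _failure_threshold(noise_sd, criteria)
    onsets = []
    for trial in trials:
        b = _baseline(trial, peak_time, fs, criteria)
        j0 = int(round((ap_peak_time_ms + w0) / dt))
        j1 = min(int(round((ap_peak_time_ms + w1) / dt)), trial.size)
        p_idx = j0 + int(np.argmax(trial[j0:j1]))
        amp_t = trial[p_idx] - b
        if amp_t < fail_thresh:  # failure trial: no onset to measure
            continue
        o = _onset_time(trial, ap_peak_time_ms, p_idx, b, amp_t, fs, criteria)
        if o is not None:
            onsets.append(o - ap_peak_time_ms)
    jitter = float(np.std(onsets)) if len(onsets) >= 2 else 0.0
    if jitter >= criteria.max_jitter_ms:
        return None

    return EpspCall(
        latency_ms=float(latency),
        amplitude=amplitude,
        area=area,
        jitter_ms=jitter,
        baseline=baseline,
        peak_time_ms=float(peak_time),
        n_trials=trials.shape[0],
        flags=flags,
    )


def _failure_threshold(noise_sd: float, criteria: DetectionCriteria) -> float:
    """Per-trial success cut: max(2x RMS noise, half the minimal amplitude)."""
    return max(2.0 * noise_sd, 0.5 * criteria.min_amplitude)


def measure_train(
    sweeps: SweepSet,
    pre_id: str = "pre",
    post_id: str = "post",
    criteria: DetectionCriteria = DetectionCriteria(),
) -> TrainMeasurement:
    """Per-stimulus amplitudes across the train plus recovery pulse.

    For each pulse, the response peak time is located on the averaged
    trace (1-20 ms post-AP window) and the per-trial amplitude is the
    1-ms mean around that time minus the pulse's own baseline — reading
    each trial at the average-peak time avoids the upward bias a
    per-trial window maximum takes from noise.  Within the 20-Hz train
    the baseline is a 2-ms mean immediately before each AP (20 ms before
    the peak would sit in the previous response's decay tail).  A trial
    counts as a failure when its amplitude stays below
    max(2x RMS noise, 50 µV).
    """
    fs = sweeps.sampling_rate
    dt = 1000.0 / fs
    pre_avg = sweeps.traces[pre_id].mean(axis=0)
    ap_peaks = find_ap_peaks(pre_avg, sweeps.pulse_times, fs)
    post = sweeps.traces[post_id]
    n_trials, _ = post.shape
    n_stim = ap_peaks.size
    noise = float(np.median([rms_noise(tr, fs) for tr in post]))
    fail_thresh = _failure_threshold(noise, criteria)

    avg_post = post.mean(axis=0)
    amps = np.zeros((n_trials, n_stim))
    w0, w1 = criteria.peak_window_ms
    half = max(1, int(round(0.5 / dt)))  # +/- 0.5 ms around the average peak
    for k, ap in enumerate(ap_peaks):
        i0 = int(round((ap + w0) / dt))
        i1 = min(int(round((ap + w1) / dt)), post.shape[1])
        pk = i0 + int(np.argmax(avg_post[i0:i1]))
        window = post[:, max(0, pk - half) : pk + half + 1]
        peaks = window.mean(axis=1)
        j0 = max(0, int(round((ap - 2.5) / dt)))
        j1 = max(j0 + 1, int(round((ap - 0.5) / dt)))
        base = post[:, j0:j1].mean(axis=1)
        amps[:, k] = peaks - base

    success = amps >= fail_thresh
    incl = amps.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        excl = np.where(
            success.any(axis=0),
            np.array(
                [amps[success[:, k], k].mean() if success[:, k].any() else np.nan
                 for k in range(n_stim)]
            ),
            np.nan,
        )
    failure_rates = 1.0 - success.mean(axis=0)
    return TrainMeasurement(
        trial_amplitudes=amps,
        success=success,
        amplitudes_incl=incl,
        amplitudes_excl=excl,
        failure_rates=failure_rates,
        failure_threshold=fail_thresh,
    )


def analyze_pair(
    sweeps: SweepSet,
    pre_id: str = "pre",
    post_id: str = "post",
    criteria: DetectionCriteria = DetectionCriteria(),
    classify: bool = True,
    seed: int = 0,
) -> ConnectionRecord | None:
    """Full per-pair pipeline: detect on pulse 1, then measure the train.

    Returns a ConnectionRecord (amplitudes in µV for mV traces) or None
    when no connection is accepted.
    """
    fs = sweeps.sampling_rate
    pre_avg = sweeps.traces[pre_id].mean(axis=0)
    post_avg = sweeps.traces[post_id].mean(axis=0)
    ap_peaks = find_ap_peaks(pre_avg, sweeps.pulse_times, fs)
    noise = float(np.median([rms_noise(tr, fs) for tr in sweeps.traces[post_id]]))
    call = detect_epsp(
        post_avg, ap_peaks[0], sweeps.traces[post_id], fs, criteria, noise_sd=noise
    )
    if call is None:
        return None
    train = measure_train(sweeps, pre_id, post_id, criteria)
    dyn = classify_dynamics(train, seed=seed) if classify else "uncategorized"
    scale = 1000.0 if sweeps.units == "mV" else 1.0  # report EPSPs in µV
    return ConnectionRecord(
        pre_id=pre_id,
        post_id=post_id,
        delay=call.latency_ms,
        jitter=call.jitter_ms,
        amplitudes=train.amplitudes_incl * scale,
        amplitudes_excl_failures=train.amplitudes_excl * scale,
        failure_rates=train.failure_rates,
        dynamics_class=dyn,
    )


def connectivity_fraction(
    n_detected: int,
    n_patched_per_slice: int | list[int] | None = None,
    n_possible: int | None = None,
) -> float:
    """Detected connections as % of all probed ordered pairs.

    The denominator is n(n-1) per slice, summed over slices, or a probed
    ordered-pair count given directly via ``n_possible`` (recordings may
    exclude individual pairs, so the tally need not be a clean sum).
    """
    if n_possible is None:
        if n_patched_per_slice is None:
            raise ParameterError("give n_patched_per_slice or n_possible")
        n_possible = possible_pairs(n_patched_per_slice)
    if n_possible == 0:
        raise ParameterError("no probed pairs")
    return 100.0 * n_detected / n_possible


def assess_connectivity(
    cells: list[CellRecord],
    calls: dict[tuple[str, str], ConnectionRecord | bool | None],
) -> tuple[CircuitGraph, float]:
    """Assemble a CircuitGraph from per-pair calls and the connectivity %.

    Every ordered pair is expected in ``calls``; unprobed pairs are
    excluded from the denominator with a warning.
    """
    ids = [c.cell_id for c in cells]
    index = {cid: i for i, cid in enumerate(ids)}
    n = len(cells)
    adj = np.zeros((n, n), dtype=bool)
    edges = []
    probed = 0
    for i in ids:
        for j in ids:
            if i == j:
                continue
            if (i, j) not in calls:
                warnings.warn(f"pair ({i}, {j}) was not probed; excluded from denominator")
                continue
            probed += 1
            call = calls[(i, j)]
            if call:
                adj[index[i], index[j]] = True
                if isinstance(call, ConnectionRecord):
                    edges.append(call)
    if probed == 0:
        raise ParameterError("no probed pairs")
    graph = CircuitGraph(cells=cells, adjacency=adj, edges=edges)
    return graph, 100.0 * graph.n_edges / probed


def classify_dynamics(
    train: TrainMeasurement | np.ndarray,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    stable_effect: float = 0.20,
    seed: int = 0,
    late_pulses: tuple[int, int] = (6, 7),
) -> str:
    """Classify short-term dynamics from trial-wise train amplitudes.

    A paired sign-flip permutation test compares the pulse-1 amplitude
    with the mean of pulses 7-8 per trial (including failures).
    Facilitating/depressing when significant at ``alpha``; stable when
    not significant and the relative change is below ``stable_effect``;
    uncategorized otherwise (including all-failure trains).
    """
    if isinstance(train, TrainMeasurement):
        amps = train.trial_amplitudes
        if not train.success.any():
            return "uncategorized"
    else:
        amps = np.atleast_2d(np.asarray(train, dtype=float))
    n_trials = amps.shape[0]
    if n_trials < 10:
        warnings.warn(f"classifying dynamics from only {n_trials} trials")
    first = amps[:, 0]
    late = amps[:, late_pulses[0] : late_pulses[1] + 1].mean(axis=1)
    diffs = late - first
    mean_first = first.mean()
    if mean_first == 0 and diffs.mean() == 0:
        return "stable" if np.allclose(amps, amps[0, 0]) else "uncategorized"
    obs = diffs.mean()
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_trials))
        null = (signs * diffs).mean(axis=1)
        p = (np.sum(np.abs(null) >= abs(obs)) + 1) / (n_permutations + 1)
    if p < alpha:
        return "facilitating" if obs > 0 else "depressing"
    if mean_first != 0 and abs(obs / mean_first) < stable_effect:
        return "stable"
    return "uncategorized"


def classify_excitability(
    step_spike_times: list[np.ndarray],
    step_duration_ms: float = 400.0,
    interneuron_rate_hz: float = 30.0,
    nonaccommodating_tts_ms: float = 100.0,
) -> tuple[str, float | None]:
    """Excitability class from current-step responses.

    Interneurons fire sustained at > 30 Hz; otherwise the time-to-spike
    under minimal stimulation separates nonaccommodating (> 100 ms) from
    accommodating cells.  Returns (class, time_to_spike_ms).
    """
    steps = [np.asarray(s, dtype=float) for s in step_spike_times]
    rates = [s.size / (step_duration_ms / 1000.0) for s in steps]
    if not any(s.size for s in steps):
        return "unknown", None
    tts = next(float(s[0]) for s in steps if s.size)
    if max(rates) > interneuron_rate_hz:
        return "interneuron", tts
    if tts > nonaccommodating_tts_ms:
        return "nonaccommodating", tts
    return "accommodating", tts


_GROUPS = {"1": (0, 1), "2-8": (1, 8), "R": (8, 9)}


def _group_means(trains: list[TrainMeasurement], excl: bool) -> dict[str, float]:
    out = {}
    for name, (a, b) in _GROUPS.items():
        vals = []
        for t in trains:
            if excl:
                # pool success-trial amplitudes across the group's pulses
                for k in range(a, min(b, t.trial_amplitudes.shape[1])):
                    vals.extend(t.trial_amplitudes[t.success[:, k], k])
            else:
                for k in range(a, min(b, t.trial_amplitudes.shape[1])):
                    vals.extend(t.trial_amplitudes[:, k])
        out[name] = float(np.mean(vals)) if vals else np.nan
    return out


def quantify_potentiation(
    baseline_trains: list[TrainMeasurement],
    post_trains: list[TrainMeasurement],
    exclude_failures: bool = True,
) -> dict[str, float | dict[str, float]]:
    """Normalized post/baseline amplitudes per stimulus group {1, 2-8, R}.

    Returns each group's mean amplitude after induction as % of its
    baseline (failures excluded by default), plus the per-group change in
    success probability — the presynaptic efficacy-redistribution
    readout (a drop in failures at pulse 1 with unchanged success
    amplitude raises the including-failures ratio but not this one).
    """
    base = _group_means(baseline_trains, exclude_failures)
    post = _group_means(post_trains, exclude_failures)
    ratios: dict[str, float] = {}
    for name in _GROUPS:
        if not np.isfinite(base[name]) or base[name] == 0:
            warnings.warn(f"group {name}: zero/undefined baseline amplitude")
            ratios[name] = np.nan
        else:
            ratios[name] = 100.0 * post[name] / base[name]

    def success_rate(trains: list[TrainMeasurement], a: int, b: int) -> float:
        rates = [t.success[:, a:b].mean() for t in trains]
        return float(np.mean(rates))

    dsucc = {
        name: success_rate(post_trains, a, b) - success_rate(baseline_trains, a, b)
        for name, (a, b) in _GROUPS.items()
    }
    return {"ratios_pct": ratios, "delta_success_prob": dsucc}


def class_proportions(counts: dict[str, int]) -> dict[str, float]:
    """Per-class percentages of the total connection count."""
    total = sum(counts.values())
    if total == 0:
        raise ParameterError("no connections to classify")
    return {k: 100.0 * v / total for k, v in counts.items()}
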