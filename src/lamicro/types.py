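"""Shared data model for multi-patch and in-vivo microcircuit analyses.

Conventions
-----------
* Voltage traces are stored in mV, currents in pA; sweep time is relative
  to trial start in ms; sampling rate in Hz (10 kHz by default).
* Unitary-response amplitudes are reported in µV for EPSPs and pA for
  EPSCs (the quantal model is unit-agnostic; it sees whatever units the
  amplitude samples carry).
* Cell positions are planar (x, y) coordinates in µm in the slice plane.
* Spike timestamps and event times are absolute ms from recording start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "QuantalParams",
    "DistanceProfile",
    "NetworkSpec",
    "ProtocolSpec",
    "SweepSet",
    "CellRecord",
    "ConnectionRecord",
    "CircuitGraph",
    "SpikeTrainSet",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a model/protocol parameter violates its constraints."""


@dataclass(frozen=True)
class QuantalParams:
    """Parameters of the simple binomial release model.

    The model assumes ``n_sites`` independent release sites sharing a
    common release probability ``p_release``; each released quantum adds
    ``q_size`` to the response on top of the offset ``v0``.  Gaussian
    recording noise has s.d. ``sigma_noise``; quantal variability adds
    ``sigma_q`` per quantum ("type1") or once for any release ("flat").
    ``p_stim`` is the probability that stimulation reaches the release
    sites at all (1 for direct somatic stimulation).
    """

    n_sites: int
    p_release: float
    q_size: float
    v0: float = 0.0
    sigma_noise: float = 0.0
    sigma_q: float = 0.0
    p_stim: float = 1.0
    variance_model: str = "type1"

    def __post_init__(self) -> None:
        if not (1 <= int(self.n_sites) <= 14):
            raise ParameterError(f"n_sites must be in [1, 14], got {self.n_sites}")
        if not (0.0 <= self.p_release <= 1.0):
            raise ParameterError(f"p_release must be in [0, 1], got {self.p_release}")
        if not self.q_size > 0:
            raise ParameterError(f"q_size must be > 0, got {self.q_size}")
        if self.sigma_noise < 0 or self.sigma_q < 0:
            raise ParameterError("sigma_noise and sigma_q must be >= 0")
        if not (0.0 <= self.p_stim <= 1.0):
            raise ParameterError(f"p_stim must be in [0, 1], got {self.p_stim}")
        if self.variance_model not in ("type1", "flat"):
            raise ParameterError(
                f"variance_model must be 'type1' or 'flat', got {self.variance_model!r}"
            )
        for name in ("p_release", "q_size", "v0", "sigma_noise", "sigma_q", "p_stim"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")

    def sigma_m(self, m: np.ndarray | int) -> np.ndarray:
        """S.d. of the mixture component with ``m`` released quanta."""
        m = np.asarray(m)
        if self.variance_model == "type1":
            var = self.sigma_noise**2 + m * self.sigma_q**2
        else:  # flat: quantal variance added once for any release
            var = np.where(
                m > 0, self.sigma_noise**2 + self.sigma_q**2, self.sigma_noise**2
            )
        return np.sqrt(var)


@dataclass(frozen=True)
class DistanceProfile:
    """Connection probability as a step function of intersomatic distance.

    ``bin_edges`` are strictly increasing (µm, length k+1); ``probs`` holds
    one probability per bin.  Distances outside the support map to 0.
    """

    bin_edges: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if edges.ndim != 1 or len(edges) != len(probs) + 1:
            raise ParameterError("bin_edges must have len(probs) + 1 entries")
        if np.any(np.diff(edges) <= 0):
            raise ParameterError("distance bins must be increasing and non-overlapping")
        if np.any((probs < 0) | (probs > 1)):
            raise ParameterError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "bin_edges", tuple(edges))
        object.__setattr__(self, "probs", tuple(probs))

    @classmethod
    def from_mapping(cls, profile: Mapping[tuple[float, float], float]) -> "DistanceProfile":
        """Build from {(lo, hi): p} bins; bins must tile contiguously."""
        items = sorted(profile.items())
        edges = [items[0][0][0]]
        probs = []
        for (lo, hi), p in items:
            if lo != edges[-1]:
                raise ParameterError("distance bins must be contiguous")
            edges.append(hi)
            probs.append(p)
        return cls(tuple(edges), tuple(probs))

    @property
    def max_radius(self) -> float:
        return self.bin_edges[-1]

    def __call__(self, distance: np.ndarray | float) -> np.ndarray:
        """Probability at each distance; 0 outside the profile support."""
        d = np.asarray(distance, dtype=float)
        edges = np.asarray(self.bin_edges)
        probs = np.asarray(self.probs)
        idx = np.searchsorted(edges, d, side="right") - 1
        inside = (idx >= 0) & (idx < len(probs)) & (d < edges[-1])
        # right edge belongs to the last bin
        inside |= d == edges[-1]
        out = np.zeros_like(d, dtype=float)
        out[inside] = probs[np.clip(idx[inside], 0, len(probs) - 1)]
        return out


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for a spatially embedded random directed network."""

    positions: np.ndarray  # (N, 2) µm
    profile: DistanceProfile
    seed: int = 0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[0] < 1 or pos.shape[1] != 2:
            raise ParameterError("positions must be an (N, 2) array with N >= 1")
        if not np.all(np.isfinite(pos)):
            raise ParameterError("positions must be finite")
        object.__setattr__(self, "positions", pos)


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation protocol: a pulse train plus a delayed recovery pulse.

    Defaults encode the connectivity-assessment protocol: eight 3-ms
    suprathreshold pulses at 20 Hz, a recovery pulse 550 ms after the last
    train pulse, repeated over 15 trials.
    """

    n_pulses: int = 8
    train_rate: float = 20.0  # Hz
    recovery_delay: float = 550.0  # ms after last train pulse
    n_trials: int = 15
    pulse_width: float = 3.0  # ms
    pulse_amplitude: float = 2.0  # nA

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ParameterError("n_pulses must be >= 1")
        if self.train_rate <= 0:
            raise ParameterError("train_rate must be > 0")
        if self.recovery_delay < 0:
            raise ParameterError("recovery_delay must be >= 0")
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")

    def pulse_times(self, t0: float = 30.0) -> np.ndarray:
        """Pulse onset times (ms): train pulses then the recovery pulse."""
        interval = 1000.0 / self.train_rate
        train = t0 + interval * np.arange(self.n_pulses)
        recovery = train[-1] + self.recovery_delay
        return np.append(train, recovery)


@dataclass
class SweepSet:
    """Repeated-trial traces for a group of simultaneously patched cells.

    ``traces`` maps cell id -> (n_trials, n_samples) array in mV (current
    clamp) or pA (voltage clamp).  ``pulse_times`` are the stimulus pulse
    onsets (ms from trial start) delivered to ``stimulated_cell``.
    """

    traces: dict[str, np.ndarray]
    sampling_rate: float  # Hz
    pulse_times: np.ndarray  # ms
    stimulated_cell: str
    units: str = "mV"

    def __post_init__(self) -> None:
        if not self.traces:
            raise ParameterError("SweepSet needs at least one cell trace")
        shapes = {np.asarray(t).shape for t in self.traces.values()}
        if len(shapes) != 1:
            raise ParameterError("all traces must share the same (trials, samples) shape")
        shape = shapes.pop()
        if len(shape) != 2 or shape[0] < 1:
            raise ParameterError("traces must be (n_trials, n_samples) with >= 1 trial")
        self.traces = {k: np.asarray(v, dtype=float) for k, v in self.traces.items()}
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.pulse_times.size and np.any(np.diff(self.pulse_times) <= 0):
            raise ParameterError("pulse_times must be strictly increasing")
        if self.stimulated_cell not in self.traces:
            raise ParameterError(f"stimulated_cell {self.stimulated_cell!r} has no trace")

    @property
    def trial_count(self) -> int:
        return next(iter(self.traces.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.traces.values())).shape[1]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.traces)

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate


@dataclass
class CellRecord:
    """One patched/recorded cell: identity, position and excitability."""

    cell_id: str
    position: tuple[float, float]  # µm
    excitability_class: str = "unknown"
    time_to_spike: float | None = None  # ms
    tag: str = "none"

    _CLASSES = ("nonaccommodating", "accommodating", "interneuron", "unknown")
    _TAGS = ("GFP+", "GFP-", "none")

    def __post_init__(self) -> None:
        x, y = self.position
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ParameterError("cell position must be finite")
        if self.excitability_class not in self._CLASSES:
            raise ParameterError(f"unknown excitability class {self.excitability_class!r}")
        if self.time_to_spike is not None and not self.time_to_spike > 0:
            raise ParameterError("time_to_spike must be > 0 when present")
        if self.tag not in self._TAGS:
            raise ParameterError(f"unknown tag {self.tag!r}")


@dataclass
class ConnectionRecord:
    """A detected directed unitary connection and its train response.

    ``amplitudes`` holds the per-stimulus mean amplitude including
    failures (µV for EPSPs), length n_pulses + 1 (train plus recovery);
    ``amplitudes_excl_failures`` excludes failure trials; ``failure_rates``
    is the per-stimulus failure fraction.
    """

    pre_id: str
    post_id: str
    delay: float  # ms, AP peak -> response onset
    jitter: float  # ms, s.d. of per-trial onset latencies
    amplitudes: np.ndarray
    amplitudes_excl_failures: np.ndarray
    failure_rates: np.ndarray
    dynamics_class: str = "uncategorized"

    _DYNAMICS = ("facilitating", "depressing", "stable", "uncategorized")

    def __post_init__(self) -> None:
        if self.pre_id == self.post_id:
            raise ParameterError("self-connections are excluded (pre_id == post_id)")
        if not (0 < self.delay < 5):
            raise ParameterError(f"delay must lie in (0, 5) ms, got {self.delay}")
        if not self.jitter < 2.5:
            raise ParameterError(f"jitter must be < 2.5 ms, got {self.jitter}")
        if self.dynamics_class not in self._DYNAMICS:
            raise ParameterError(f"unknown dynamics class {self.dynamics_class!r}")
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.amplitudes_excl_failures = np.asarray(
            self.amplitudes_excl_failures, dtype=float
        )
        self.failure_rates = np.asarray(self.failure_rates, dtype=float)
        n = self.amplitudes.size
        if self.amplitudes_excl_failures.size != n or self.failure_rates.size != n:
            raise ParameterError("per-stimulus arrays must share one length")
        if np.any((self.failure_rates < 0) | (self.failure_rates > 1)):
            raise ParameterError("failure rates must lie in [0, 1]")


@dataclass
class CircuitGraph:
    """Cells with planar positions plus a directed adjacency.

    ``adjacency[i, j]`` is True when cell i connects onto cell j (ordered
    by ``cells``).  ``edges`` optionally carries full ConnectionRecords.
    """

    cells: list[CellRecord]
    adjacency: np.ndarray
    edges: list[ConnectionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.cells)
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (n, n):
            raise ParameterError(f"adjacency must be ({n}, {n})")
        if np.any(np.diag(adj)):
            raise ParameterError("self-edges are not allowed")
        self.adjacency = adj
        ids = {c.cell_id for c in self.cells}
        for e in self.edges:
            if e.pre_id not in ids or e.post_id not in ids:
                raise ParameterError(f"edge {e.pre_id}->{e.post_id} references unknown cell")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.cells], dtype=float)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean intersomatic distances (µm)."""
        pos = self.positions()
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class SpikeTrainSet:
    """Sorted-unit spike timestamps with recording epoch and events.

    ``units`` maps unit id -> sorted timestamps (ms); ``events`` maps a
    stimulus name -> onset times (ms); ``labels`` carries per-unit flags
    such as ``recruited``, ``light_locked`` or ``responsive``.
    """

    units: dict[str, np.ndarray]
    epoch: tuple[float, float]
    events: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, dict[str, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        start, end = self.epoch
        if not end > start:
            raise ParameterError("epoch end must exceed epoch start")
        clean: dict[str, np.ndarray] = {}
        for uid, ts in self.units.items():
            ts = np.asarray(ts, dtype=float)
            if np.any(np.diff(ts) < 0):
                raise ParameterError(f"unit {uid!r} timestamps are not sorted")
            if ts.size and (ts[0] < start or ts[-1] > end):
                raise ParameterError(f"unit {uid!r} has timestamps outside the epoch")
            clean[uid] = ts
        self.units = clean
        self.events = {k: np.asarray(v, dtype=float) for k, v in self.events.items()}

    @property
    def duration_ms(self) -> float:
        return self.epoch[1] - self.epoch[0]

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units)


def possible_pairs(n_cells: int | Sequence[int]) -> int:
    """Number of probed ordered pairs, n(n-1), summed over slices."""
    if np.isscalar(n_cells):
        n_cells = [int(n_cells)]  # type: ignore[list-item]
    return int(sum(n * (n - 1) for n in n_cells))
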