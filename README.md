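# lamicro

Analysis pipeline for local microcircuits of the lateral amygdala (LA),
built around multi-patch-clamp and chronic multi-electrode recordings:

* **Unitary-connection detection** — stimulus-locked EPSPs on 15-trial
  averaged sweeps, accepted when onset latency < 5 ms after the
  presynaptic AP peak, across-trial jitter < 2.5 ms, amplitude ≥ 100 µV
  (≥ 5 pA for EPSCs) and area ≥ 1 mV·ms; per-stimulus train measurement
  (8 pulses at 20 Hz + recovery pulse 550 ms later), failure separation,
  facilitating/depressing/stable classification and Hebbian-potentiation
  readouts.
* **Quantal analysis** — maximum-likelihood fitting of the simple
  binomial release model. The amplitude density is a Gaussian mixture
  over released quanta m ~ Binomial(n, p):

  f(v) = p_stim · Σₘ C(n,m) pᵐ(1−p)ⁿ⁻ᵐ · N(v; v₀ + m·q, σₘ)
       + (1 − p_stim) · N(v; v₀, σ_noise),

  with σₘ² = σ_noise² + m·σ_q² (type-I quantal variance) or
  σ_noise² + σ_q² for m > 0 ("flat"). Release moments are mean = npq and
  s.d. = q√(np(1−p)). The site count n is scanned up to 14 (boundary
  fits discarded), each candidate maximized by Nelder–Mead from ten
  starting points; Monte-Carlo χ² goodness of fit and a 30%-drift
  stability filter complete the procedure.
* **Network motifs** — census of reciprocal, convergent, divergent and
  feed-forward motifs against a position-preserving Monte-Carlo null
  with distance-dependent connection probability and empirical
  95/99/99.9% bands; expected local in-degree from the distance profile
  and planar cell density.
* **Summation model** — AP threshold from the apex of the second
  derivative on ramp responses, OLS spatial-summation regression over
  convergent inputs, temporal-summation factor, and the distribution of
  inputs required to trigger a postsynaptic spike.
* **In-vivo stage** — peristimulus z-scoring (3-s.d. responsiveness),
  optogenetic light-locking (< 5-ms precision), conditional Granger
  causality on spike trains (1-ms bins, causal half-Gaussian kernel,
  BIC-selected VAR order, spectral-radius stationarity check, per-pair
  χ² test at P < 0.001), causal density, and freezing quantification.
* **Synthetic generators** for all of the above, with planted ground
  truth, so every stage is testable without recordings.

## Worked example

```python
import numpy as np
from lamicro import detection, quantal, synthetic
from lamicro.types import QuantalParams

# a probed pair with a planted 800-µV EPSP at 2-ms latency
conn = synthetic.SyntheticConnection(latency_ms=2.0, amplitude_uv=800.0)
sweeps = synthetic.simulate_sweep_set(conn, noise_sd_uv=20.0, seed=3)
record = detection.analyze_pair(sweeps, seed=1)
print(round(record.delay, 2), round(record.jitter, 3), record.dynamics_class)
# 2.1 0.044 stable

# quantal parameters recovered from 150 amplitudes
truth = QuantalParams(n_sites=5, p_release=0.5, q_size=460.0, sigma_noise=30.0)
amps = synthetic.simulate_quantal_amplitudes(truth, 150, seed=42)
fit = quantal.fit_quantal(amps, noise_sd=30.0)
print(fit.params.n_sites, round(fit.params.q_size, 1))
# 5 459.4
```

The detected delay (2.1 ms) is the AP-peak-to-onset latency of the
planted EPSP; the fitted site count and quantal size recover the
generating parameters (n = 5, q = 460 µV) from 150 trials.

A command-line interface wraps the same functions
(`lamicro detect`, `lamicro quantal-fit`, `lamicro motifs`,
`lamicro summation`, `lamicro gc`, `lamicro respond`).

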