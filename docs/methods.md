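# Methods

This note documents the models behind each pipeline stage, the defaults
that matter, what the synthetic generators do and do not emulate, and
the numerical choices made where the procedure was genuinely open.

## Data model and units

Sweep traces are stored in mV (current clamp) or pA (voltage clamp) at
10 kHz; unitary amplitudes are reported in µV for EPSPs and pA for
EPSCs; positions are planar µm in the slice plane; spike timestamps are
absolute ms from recording start, while sweep time is relative to trial
start. Sweeps round-trip through HDF5 (one group per trial, attributes
`sampling_rate_hz`, `pulse_times_ms`, `stimulated_cell`); cells, edges
and spikes through CSV; configuration and reports through JSON.

## Connection detection

A connection is called on the trial-averaged postsynaptic trace around
the first presynaptic AP of the 20-Hz train. Criteria: onset latency
< 5 ms after the AP peak, across-trial onset jitter < 2.5 ms, amplitude
≥ 100 µV (EPSP; 5 pA EPSC) and area ≥ the minimal-area criterion. The
area criterion is implemented as 1 mV·ms: a voltage–time integral is
the only dimensionally consistent reading of a minimal "area under the
EPSP", and the unit is configurable. Baseline for the averaged event is
a 5-ms mean sampled 20 ms before the peak; onset is the first crossing
of 10% of the peak above baseline (the onset definition is otherwise
unstated territory; 10% is conventional); the peak is searched 1–20 ms
after the AP peak; jitter is the s.d. of per-trial onset latencies over
success trials; the 15-trial average uses the mean.

Within the train, per-pulse baselines move to a 2-ms mean immediately
before each AP: at 50-ms inter-pulse intervals a 20-ms-lead baseline
sits in the previous response's decay tail and systematically biases
flat trains toward apparent depression. Per-trial amplitudes are read
as the 1-ms mean at the averaged-trace peak time (a per-trial window
maximum is upward-biased by noise and misclassifies failure trials). A
trial is a failure when its amplitude stays below
max(2 × RMS noise, 50 µV); the paper separates failures from successes
without stating the cut, so it is exposed as a parameter. RMS noise is
measured over 0.5 ms at trial start (exactly 5 samples at 10 kHz),
outside stimulus responses.

Short-term dynamics are classified per connection by a paired sign-flip
permutation test (pulse-1 vs mean of pulses 7–8 per trial, 10,000
permutations, two-sided α = 0.05): facilitating/depressing when
significant, stable when not significant and the relative change is
below 20%, uncategorized otherwise (including all-failure trains). The
original analysis reports only group-level RM-ANOVA; the per-connection
test is this package's choice.

Excitability: interneurons fire sustained above 30 Hz under current
steps; otherwise a time-to-spike above 100 ms under minimal stimulation
marks nonaccommodating cells, below it accommodating.

Potentiation is quantified per stimulus group {1, 2–8, R} as the
post-induction mean amplitude as % of baseline, failures excluded by
default, alongside the per-group change in success probability — the
readout that separates a presynaptic redistribution of efficacy (fewer
failures, unchanged success amplitude) from a postsynaptic gain change.

## Quantal analysis

The amplitude density is the binomial-mixture model given in the
README. The printed form of this density circulates with typographical
defects (a sum index starting at 1, a dangling comma in the exponent);
the implementation is the standard mixture summing m = 0..n with
component mean v0 + m·q — the only probabilistically coherent reading.
`p_stim` defaults to 1 (direct somatic stimulation); σ_q is fitted by
default and can be fixed.

Fitting holds the recording noise σ_noise at its measured value and
maximizes the likelihood over (p, q, v0[, σ_q]) by Nelder–Mead simplex
from ten starting points per candidate n (moment-based, jittered,
seeded). Candidates run from a data-driven lower bound (quanta needed
to span the amplitude range) to 14; a fit that selects the 14-site cap
is discarded as unresolved. Model selection across n uses maximum
likelihood with a parsimony tie-break: the smallest n within 2
log-units of the best, since the likelihood is otherwise weakly
monotone in n. Samples indistinguishable from pure noise (fitted
release mean below half the noise s.d.) are flagged unidentifiable.

Goodness of fit: equal-probability bins under the fitted model (at
least 5 expected per bin, adaptively re-binned for small samples),
χ² against the fitted expectation, and an empirical p-value from
datasets simulated at the fitted parameters.

Stability filter: the mean of the first ten trials (the symmetric
counterpart of the "last ten" reference; a literal first-trial reading
is available via `reference="first"`) is compared with the mean of the
last ten; drift strictly above 30% excludes the recording; fewer than
11 trials is not evaluable.

Operating regime: with 150 amplitudes, p near 0.5 and q/σ_noise ≈ 15,
the fit recovers q with negligible bias and n within ±1 site; at 14
sites and p = 0.5 the occupied mixture components no longer pin v0 and
(n, v0) become jointly unidentifiable — the boundary-discard rule
exists for exactly this regime.

## Network motifs

The census counts role-assigned node subsets: reciprocal pairs,
double/triple-convergent (C(indeg, 2), C(indeg, 3) summed over nodes),
double/triple-divergent (likewise on out-degrees), and feed-forward
chains as directed 2-paths A→B→C over distinct nodes — an A→C edge is
neither required nor forbidden, and motifs are not counted exclusively
(a triple-convergent node also contributes its three embedded doubles).
Both instance counts and connections-explained (instances × edges per
instance) are reported, matching the "14 × 2/89" accounting style.

The null redraws graphs on the real cell positions with connection
probability a step function of Euclidean intersomatic distance (50-µm
bins by default). The default null conditions on the profile, not the
observed edge count — the edge count varies binomially, which is what
"random distance-dependent connectivity" implies; a fixed-edge-count
mode is available. Bands are inclusive empirical 95/99/99.9% quantiles
(lower/higher interpolation, safe for discrete counts; they over-cover
slightly, by design matching how counts are flagged against confidence
intervals). Calibration, measured on 30 cells with a 3-bin profile at
10,000 simulations × 100 repeats: per-class coverage 0.97–0.99, joint
all-six-classes coverage ≈ 0.91.

Expected local in-degree integrates density × annulus area ×
p(distance) over 1-µm annuli to the profile support. Density and any
slice-geometry corrections are parameters, not constants.

## Summation model

AP initiation is the apex of the second time-derivative before the AP
peak, computed after Savitzky–Golay smoothing (1-ms window, cubic):
raw second differences at 10 kHz are noise-dominated. The threshold is
the voltage at that instant; on synthetic ramp-plus-spike traces the
estimator is unbiased and stays within 1 mV under 0.1-mV noise.

Spatial summation is strictly linear (arithmetic) superposition — an
OLS line through summed convergent-input uEPSP amplitude versus input
count, run separately for first-pulse and recovery-pulse amplitudes,
with no driving-force correction. Required inputs per threshold sample
are (threshold − intercept)/slope, homogeneous of degree −1 in the
slope, so a temporal-summation gain g shrinks the requirement by 1/g.

The temporal-summation factor is an interpretive choice (no closed
formula circulates): per-pulse responses superpose with exponential
decay of the membrane response, and the factor is the mean over pulses
2..end of (residual depolarization + evoked amplitude) referenced to
the first-pulse amplitude, ×100. With instantaneous decay and a flat
train it is exactly 100%.

## In-vivo stage

Peristimulus counts use 50-ms bins against a 500-ms baseline (0.5-s
bins against 5 s for the optogenetic configuration). Baseline moments
are estimated from the per-repetition baseline bin counts, with the
s.d. scaled by 1/√n_repetitions to refer to the trial-averaged counts:
estimating them from the ~10 averaged baseline bins leaves 9 degrees of
freedom and inflates the tail of the 3-s.d. criterion several-fold.
Even so the criterion is not exactly nominal at low rates: with 5-Hz
baseline firing the per-bin counts are Poisson with mean 0.25, and
their skewness puts the one-sided 3-s.d. exceedance near 0.4% per bin,
i.e. an ~8–10% per-sweep false-responsive rate on null data (exact
Poisson arithmetic, confirmed by simulation). Tests bound the null rate
accordingly rather than assuming normality. Units are light-locked when
the median first-spike latency and its s.d. across pulses are below
5 ms and a spike follows at least half the pulses within 5 ms.

Granger causality: timestamps are binned at 1 ms and convolved with a
causal half-Gaussian kernel (5-ms support, σ = width/3, unit sum, mass
at and after the spike — sidedness and normalization are conventions
fixed here). A joint VAR over all units is fitted by per-equation OLS;
the order minimizes BIC (default scan to 15); models whose companion
matrix has spectral radius ≥ 1 are rejected as nonstationary.
Conditional GC of i onto j is ln(σ²_j[reduced]/σ²_j[full]), the reduced
model omitting unit i's lags from every equation's predictor set while
conditioning on all remaining units; significance is the asymptotic
χ²(order) likelihood-ratio test at P < 0.001 per ordered pair, with no
multiple-comparison correction (only the per-pair threshold is
specified; the false-positive rate is verified by simulation: ≤ 3
significant pairs in 500 null pairs of 2-minute trains). The model sees
only rate increases and therefore infers excitatory, not inhibitory,
connections. Causal density is the mean pairwise-conditional causality;
normalization divides by the dataset-wide maximum (yielding
dimensionless units; min–max or z alternatives are a one-line change at
the call site). Analyses run on baseline epochs (default minimum 60 s;
20-minute epochs are the reference condition) outside stimulus
exposure.

Freezing is the summed duration of no-movement bouts of at least 2 s
(clipped to the window) as % of the stimulus window.

## Synthetic generators

The generators plant exactly the structure the analyses assume:
binomial-mixture amplitudes; spatially embedded directed graphs with
independent distance-dependent edges; sweep sets whose postsynaptic
trace carries a difference-of-exponentials EPSP (1-ms rise, 10-ms
decay — chosen so the transient fits the 5-ms detection window; no
kernel is published) at a planted latency with per-pulse scaling and
stochastic failures in white Gaussian noise; discrete-time Bernoulli
spike trains where a presynaptic spike adds to the target's firing
probability in a 1–5-ms lag window (the monosynaptic latency range);
and Poisson rasters with a controlled evoked-rate change. Acyclic
coupling simulates vectorized in topological order; recurrent matrices
fall back to time-stepping. A single seed per call splits
deterministically per cell/trial.

What they do not emulate: correlated (non-white) recording noise,
electrode drift, dendritic filtering or conductance-based integration,
calcium dependence of release probability (low-Ca²⁺ conditions are
emulated by setting p directly), spike-sorting errors, and
non-Poisson baseline firing (bursting, refractoriness beyond the 1-ms
bin). Passing round-trip tests therefore demonstrates correctness of
the estimators under the stated statistical assumptions, not robustness
to every pathology of real recordings.

## Problem sizes in the test suite

The suite exercises the pipeline at sizes chosen to make the
statistical assertions sharp while staying desk-scale: 20 replicate
quantal fits of 150 amplitudes; 100 calibration repeats of the motif
null at 10,000 simulations (the reference analysis uses 100,000; band
quantiles at 10,000 are precise to well inside the assertion margins);
Granger calibration on 500 null ordered pairs and 50 planted-edge
replicates of 2-minute trains; detector specificity on 500
connectionless sweep sets.

## Known limitations

* The binomial fit assumes uniform release probability across sites;
  compound-binomial alternatives are out of scope by design.
* (n, p) trade-offs flatten the likelihood when q/σ is small or p is
  extreme; the ±1-site recovery guarantee holds in the p ∈ [0.3, 0.7],
  ≥ 150-trial regime.
* The GC significance test is asymptotic; at short durations (minutes)
  it is mildly conservative in simulation but has no finite-sample
  guarantee.
* The temporal-summation factor is one defensible formalization among
  several; its definition (decay constant, reference pulse) is exposed
  as parameters.
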