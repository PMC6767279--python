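# Methods

This note records the models, parameter choices, and numerical decisions
behind piezosleep, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Signal model

A recording is 18 synchronized channels at a common sampling rate Fs
(100 Hz by default, matching the reference acquisition hardware), each the
amplified voltage of one piezoelectric ceramic sensor in a 2×9 grid under
the mattress. Detection operates on *periods*: fixed-length segments of
10, 30, or 60 s of one channel, re-evaluated every 10 s (sliding windows
with a 10 s hop regardless of period length; trailing partial windows are
dropped because every formula below assumes a fixed sample count N).
Indexing is 0-based internally; windows are half-open `[start, end)`.

## Occupancy, channel selection, turnover

All three decisions derive from the per-period population variance
S_{t,i} (denominator N, not N−1) of each channel:

* Presence: occupied iff CSₜ = Σᵢ S_{t,i} strictly exceeds a threshold.
  No universal threshold exists — it depends on gain, noise floor, and
  mattress — so it is calibrated as mean + k·std (default k = 5,
  population std) of CSₜ over at least two empty-bed periods.
* Channel selection: argmax of S_{t,i}, ties to the lowest channel id so
  results are deterministic.
* Turnover: channels partition into three regions of six (column bands
  1–3, 4–6, 7–9 across both rows by default; the grouping is configurable
  because only the six-per-region structure is fixed, not the geometry).
  A change of the argmax-energy region between consecutive occupied
  periods is a turnover; an absence resets the comparison memory.

## Mains preprocessing

A second-order digital IIR notch (the digital counterpart of an analog
twin-T band-stop), default f₀ = 50 Hz, Q = 30, applied forward-backward so
that peak positions — which carry the rate information — are not delayed.
Zero-phase application doubles the stop-band attenuation; the design
target is ≥ 40 dB at f₀ with the 0.1–3 Hz physiological band within 1% of
unit gain. A notch at or above Nyquist is mathematically undefined; since
50 Hz sits exactly at Nyquist for Fs = 100 Hz, the pipeline skips the
notch there (aliased mains lands on the Nyquist bin, which the moving
averages and band reconstructions annihilate) and applies it for any
higher sampling rate.

## Dynamic smoothing

The centered moving average with half-window W replaces each sample by the
mean of 2W+1 neighbours; the left edge (1-based n ≤ W) uses the symmetric
growing window of 2n−1 points and the right edge 2(N−n)+1 points, so a
constant series is reproduced exactly at every index, including the edges.
The half-windows adapt to the latest rates: W = ⌊Fs/(4r)⌋, w = ⌊Fs/(4h)⌋
(floor; minimum 1 sample), i.e. the window spans about a quarter of the
oscillation period — long enough to suppress the faster component and
noise, short enough to keep the peaks countable. Initial states are
r = 0.5 Hz (sleep breathing stays below 30/min, so W ≥ 50 at 100 Hz) and
h = 2 Hz. After each window the state is updated with the new estimate,
clamped to r ∈ [0.05, 1.0] Hz and h ∈ [0.5, 3.5] Hz so a single bad window
cannot drive W beyond what the next window can support; if N < 2W+1 the
half-window is additionally clamped to ⌊(N−1)/2⌋. Invalid (zero-peak)
windows leave the state untouched.

The amplification coefficient α compensates the moving average's
attenuation of the breathing waveform before subtraction:
α = Σ x(n) / Σ x′(n) over the 2L+1 samples around a respiratory peak
(L = 10 by default, shrunk to < W/4 when W is clamped). Two implementation
choices matter here:

* α is evaluated at **every** detected respiratory peak and the median
  taken, for robustness against a single corrupted peak.
* The sums are taken on the **mean-removed** window. The coefficient's
  purpose is to undo the attenuation of the breathing *oscillation*, and
  only on a mean-free series does the ratio of sums equal that attenuation
  factor; on the raw series the ~1.5 V static posture offset dominates
  both sums and biases the ratio toward 1, leaving a respiratory residual
  of up to ~30% of the breathing amplitude in y = x − α·x′ — enough to
  swamp the heartbeat whenever breathing is faster than ~20/min. With the
  mean removed the subtraction cancels a sinusoidal breathing component
  almost exactly (measured on the synthetic study conditions: median
  heart-rate accuracy 99.0% versus 89.4% with raw sums). A vanishing
  denominator (flat or centered signal) raises a degenerate-signal error;
  the caller retries after shifting both series above zero.

Peaks are local maxima at least min-distance apart whose prominence
exceeds 0.25 × the 5–95 percentile span of the series (a scale-free
criterion); of any conflicting pair the higher peak wins. Minimum
distances come from the physiological band edges: ⌊Fs/(2·0.5 Hz)⌋ for
respiration, ⌊Fs/(2·3 Hz)⌋ for heartbeat. A series whose 5–95 span is at
float-noise level (≤ 1e-12) is treated as constant. The rate is the peak
count divided by the period length, so every estimate is quantized to one
event per window.

A heart estimate additionally passes a plausibility gate before being
reported valid: at least 4 peaks, a rate within 30–210/min, and a
normalized peak-interval MAD (median absolute deviation / median) of at
most 0.12. Real beat trains in these signals measure ≤ ~0.05 (the
simulator jitters beats by 2%; sleep heart rates are similarly regular)
while peaks found in a heartbeat-free residual — breathing leakage or
noise — measure ≥ ~0.18, so the threshold sits between the regimes. The
same gate guards the wavelet and EEMD heart estimates.

## Wavelet baseline

A 10-level multilevel (cascaded two-band) decomposition with each of db5,
db6, sym6, and coif4, symmetric (half-point) signal extension throughout
so results are bit-stable. Layer *i* denotes the band-pass detail dᵢ
occupying (Fs/2^{i+1}, Fs/2^i): at Fs = 100 Hz, layers 7 (0.39–0.78 Hz)
and 8 (0.20–0.39 Hz) bracket sleep respiration and are reconstructed for
the respiratory rate; layers 4–6 (0.78–6.25 Hz) for the heart rate. The
heart set nominally extends to 6.25 Hz, above the stated 0.8–3 Hz
heartbeat band; the literal three-layer set is kept because the upper
layers carry the sharp flanks of the beat complex that make its peaks
countable. Each wavelet's band is peak-counted separately (same peak rule
as above; heart trains must pass the plausibility gate) and the rate is
the median of the surviving counts — the four wavelets act as an ensemble
with no stated combination rule, and the median tolerates one failed
basis. Deep decomposition levels of short windows fall below the advisory
maximum level and simply carry very short coefficient vectors; the
perfect-reconstruction identity (≤ 1e-8 relative error) holds regardless.

## EMD / EEMD baseline

Sifting subtracts the mean of the cubic-spline upper and lower envelopes
through the strict local maxima/minima; the two nearest extrema are
mirrored about each boundary before fitting to tame end swings. Sifting
stops when the pointwise normalized squared difference between successive
iterates, Σ (h_prev − h_new)² / (h_prev² + 1e-12), reaches 0.2, or after
100 iterations; decomposition stops at extrema deficit (fewer than two
maxima or two minima), which is a normal termination, not an error. The
IMFs plus residual reconstruct the input to numerical precision.

EEMD averages the IMFs of EMD runs on noise-perturbed copies (defaults:
ensemble 50, noise sd 0.2 × sd(x), seeded and reproducible; smaller
ensembles are used where runtime matters, at some cost in residual
ensemble noise). IMF lists are aligned by index and shorter lists
zero-padded before averaging. The IMF count is whatever the data yield
(typically around 9–12 on these signals at N = 6000) and is reported, not
forced, where the cost model assumes its average value.

Rate extraction assigns each averaged IMF its dominant Fourier frequency;
IMFs in 0.2–0.5 Hz sum to the respiratory series and IMFs in 0.8–3 Hz to
the heartbeat series. The respiratory series is peak-counted directly. The
heartbeat series is an oscillatory packet train — band-limiting a
once-per-beat complex to 0.8–3 Hz makes its carrier swing about twice per
beat, so counting carrier peaks double-counts (measured: 144 counts at a
true 75 bpm) — therefore beats are counted on the analytic-signal
(Hilbert) envelope, which has one bump per beat.

## Complexity model

Closed-form per-period costs, counting multiplications, additions and
comparisons separately (an embedded core pays very differently for each),
with 4-byte floats and 2-byte integers for storage: see
`piezosleep.complexity` for the expressions. Non-integer values from the
log₂ terms are rounded to nearest. The 4N peak-search comparisons are
included in every method's comparison column. Defaults are the study
conditions: N = 1000 (10 s at 100 Hz), X = 100 sift iterations, Y = 9
IMFs, W = 83 and w = 20 (the half-windows at the average sleep rates
0.3 Hz and 1.25 Hz), L = 10.

## Synthetic-data generator

The generator emulates the signal structure the detectors assume, not the
physiology itself. Per channel: baseline offset (1.5 V, keeping signals
positive in the 0–3 V acquisition range and the α sums well-conditioned)
plus a gain-scaled physiological component, plus mains ripple, white
noise, and optional movement bursts. Channel gains decay geometrically
with Euclidean grid distance from the chest cell (factor 0.5 per cell), so
the nearest sensor carries the strongest vitals — the premise of
variance-based channel selection.

* Respiration: a sinusoid with ±5% per-cycle period jitter and ±5%
  per-cycle amplitude jitter. Real breathing has richer waveform shape
  (inspiratory/expiratory asymmetry, pauses); the detectors only use
  periodicity and band location, which the sinusoid provides.
* Heartbeat: a pulse train at the scheduled rate (±2% beat jitter) of
  smooth biphasic complexes — the difference of two bell curves with
  standard deviation equal to the pulse-width parameter (0.08 s) and
  centers at ±1.5 × that width, normalized to unit peak and zero net area.
  The complex spans roughly half a second, placing most of its energy near
  the heart fundamental, as in real ballistocardiographic deflections
  where the whole body recoils once per ejection; a narrow spike train
  would have almost no heart-band energy and no time-domain counting
  method could see it. Beat complexes scale with
  heart_to_resp_ratio × resp_amplitude (default 0.12 — the heartbeat is an
  order of magnitude weaker than breathing, as observed on chest
  channels).
* Movement artifacts: low-pass-filtered (10 Hz) noise bursts with a Tukey
  taper, added to all channels with the same spatial gains.
* Occupancy schedule: non-overlapping intervals with a chest position
  each; outside them only offset + mains + noise. Ground truth reports,
  per analysis window (labelled by its center), the scheduled rates,
  occupancy, chest region, and turnover flags — standing in for the
  bedside reference instruments of a clinical comparison.

Identical configurations (including the seed) produce bit-identical
recordings.

What passing tests show — and do not. The synthetic signals establish that
the implementations are correct (oracle and identity checks), that the
pipeline recovers known rates across the physiological bands (median
respiratory accuracy ≥ 95%, heart ≥ 90% over 50 seeded 60 s scenarios),
and that scripted occupancy/turnover sequences are recovered exactly in
noise-free runs. They do not certify performance on real mattresses:
waveform morphology, posture-dependent coupling, sensor drift and
nonlinearity, and multi-sleeper scenarios are all outside the generator.
The known weak spot carries over from the method itself: at breathing
rates above ~25/min the respiratory residual grows and heart estimates
degrade or are gated invalid, which mirrors the method's declining
heart-rate accuracy at short periods in bedside comparisons.

## Numerical conventions

Moving averages are computed from a cumulative sum (exact for these
magnitudes); ties in argmax decisions break to the lowest id; stochastic
components (EEMD noise, simulation) take explicit integer seeds; all
detection defaults (prominence 0.25, validity gate, clamps) are exposed as
arguments so studies can override them. Problem sizes in the test suite —
50 seeds × 60 s for parameter recovery, ensembles of 5–20 for EEMD tests,
two-scenario benchmarks — keep the full suite around two minutes while
leaving each statistical check comfortably powered for its threshold.
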