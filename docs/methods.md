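# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Signal model and synthetic data

The generator emulates a camera trace from a resting adult. Per channel
`c ∈ {r,g,b}`:

```
x_c(t) = g_c · [ A_card (1 + m cos 2π f_rr t) cos 2π f_hr t
               + A_resp cos 2π f_rr t
               + A_drift cos 2π f_drift t ] + ε(t),   ε ~ N(0, σ²)
```

Respiration enters twice, matching how breathing imprints on a
photoplethysmogram: as amplitude modulation of the cardiac tone (depth
`m`) and as an additive baseline oscillation. Defaults: `f_hr = 1.2 Hz`
(72 bpm), `f_rr = 0.25 Hz` (15 brpm), `A_card = 1`, `A_resp = 0.5`,
`m = 0.2`, `A_drift = 0.5` at 0.01 Hz, 60 s at 23 frames/s, channel gains
(0.7, 1.0, 0.5) with green largest, as camera studies consistently report.
The drift amplitude sits below the cardiac amplitude so that the noise-free
green spectrum peaks at the pulse — a documented generator contract that
the tests rely on. The canonical noisy condition is 10 dB SNR on the green
channel (`snr_noise_sd` converts SNR to σ against the AC power of the
clean signal). Seeding: one root seed, with per-generator substreams
derived via `SeedSequence((seed, stream_id))`, so the trace, tone-mixture,
frame, and pixel-cloud generators are mutually independent but each
bitwise reproducible.

What the generator does **not** emulate: motion artifacts, illumination
changes, compression, skin-tone diversity, heart-rate variability, or
non-sinusoidal pulse morphology. Passing the benchmarks therefore
demonstrates the correctness and noise behavior of the algorithms under
stationary sinusoidal physiology — not clinical-grade performance on real
video.

Frame rendering places an ellipse (the "skin" region) on a static
background; the ellipse color equals a base skin tone plus the trace value
at that frame, so spatial averaging over the true mask reproduces the
trace exactly when per-pixel noise is off.

## Key-frame extraction

Frames are summarized by 16×16 histograms over brightness-free
chromaticity (r/(r+g+b), g/(r+g+b)); per-channel 1-D histograms are
available behind a flag. Histograms are normalized to unit mass so the
intersection similarity lies in [0, 1] and is 1 exactly at equality.
Clustering is single-pass leader clustering in temporal order (threshold
`T`, default 0.8): cheapest scheme consistent with online shot
abstraction; the centroid is the running mean histogram, renormalized.
Key frame per cluster: the member most similar to the centroid, ties to
the smallest index. The refinement distance between consecutive key frames
sums the *squared* region-histogram intersections over the G segmentation
regions — note this quantity grows with similarity, so both retention
senses ("keep dissimilar", the default, and "keep similar") are exposed
rather than hard-coding one.

## GMM segmentation

Pixel features (raw RGB or chromaticity) are modeled as a G-component
Gaussian mixture (default G=2, object vs. background), fitted by EM with
diagonal covariances and a variance floor of 1e-6; full covariances behind
a flag. Initialization is k-means++ on a ≤10⁴-pixel subsample, seeded, so
fits are deterministic. A component whose responsibility mass collapses is
re-seeded once at the lowest-likelihood point. The log-likelihood trace is
kept and must be non-decreasing (asserted in tests at 1e-8 slack).
Which component is "skin" is a heuristic: largest mean green value.

## Trace path

Detrending subtracts a centered moving average (mirror-padded). The window
default is 4.0 s: the moving average passes ≈99.7% of 0.01 Hz drift
(so subtraction removes it by ~50 dB) while 0.25 Hz respiration falls on a
null of the 4-s window and passes at full amplitude. A shorter window
(e.g. 1.5 s) whitens the sub-pulse band more aggressively but attenuates
respiration to ~20–35% — measurably degrading respiratory-rate recovery —
so 4.0 s is the default and the window remains configurable.
Normalization is a per-channel z-score with the population standard
deviation. Resampling is linear interpolation onto a uniform 23 fps grid,
bridging typical acquisition rates (~10 fps) and the analysis rate.

## Kalman smoothing

State `A_k = [a_k, a_{k−1}, a_{k−2}]`. The default `reconstructed` preset
is the unique shift-register model consistent with a first-order
derivative approximation on a uniform grid: top row `a_{k+1} = 2a_k −
a_{k−1}`, measurement row `Y = [1,0,0]`, process noise 0.4 entering only
the newest lag, measurement noise `Q = 1` (trace units are z-scores, so
unit measurement noise is a neutral prior). A `literal` preset transcribes
an alternative published parameterization whose indefinite process-noise
matrix is symmetrized and eigenvalue-floored to the nearest PSD matrix; it
is kept for comparison, not used by defaults. "Adaptive" is realized as
optional innovation-based rescaling: `Q ←` sample variance of the
innovations over a sliding 2 s window (enabled in the pipeline). The
covariance update is symmetrized each step; P stays PSD along trajectories
(asserted). The α-β predictor is provided as the fixed-gain fallback; its
gains are validated to α ∈ [0,2), β ∈ [0,1).

## Decomposition engines

**AFD (tag `mafd`).** Greedy adaptive Fourier decomposition of the
analytic signal on the unit circle: at each level the Szegő-kernel
evaluator `e_a` maximizing `|⟨G_n, e_a⟩|²` is chosen from a grid of
Blaschke points (magnitudes {0, 0.1, …, 0.9, 0.95} × 64 phases); the
emitted term is the projection coefficient times the evaluator times the
accumulated Blaschke product; the reduced remainder is updated by the
standard shift. Stopping: remainder energy < 1% of input energy or 200
levels. The level budget matters: a tone at `f` Hz in a `D`-second record
sits at circle harmonic `k = fD`, and the best single kernel captures only
about `1/(e·k)` of its energy (k = 72 for 1.2 Hz in 60 s), so a handful of
levels cannot represent physiological tones; with the Blaschke shift
walking energy down the spectrum, convergence to 1% typically takes
~100 levels on the 60 s fixture (milliseconds of compute). Raw levels are
then assembled into band-limited mono-components: the mutually orthogonal
complex levels are clustered by spectral-peak frequency (tolerance:
max(2 FFT bins, 25% relative)), and clusters sharing a merged dominant
frequency are fused. Grouping preserves exact energy bookkeeping (the
groups partition an orthogonal set) and is what the "M" in the engine tag
denotes here. A grouped component's center frequency is its dominant
spectral peak; the spectral centroid remains available as a diagnostic.
Energy conservation `‖ψ‖² = Σ‖c_nB_n‖² + ‖Ψ_N‖²` holds to the
discrete-circle aliasing floor, which scales as ρ_max^N — below 1e-11 for
N ≥ 512 samples, the length used by the conservation benchmarks.

**HVD (tag `ehvd`).** Iterative largest-component extraction. Per
component: the residual is extended by clamped AR(12) linear prediction
(mirror reflection creates a phase kink at the crop boundary that
dominated extraction error; LP extension continues oscillations
coherently); the frequency track is initialized at the residual's dominant
spectral peak — under broadband noise the classical low-passed
instantaneous-frequency average sits mid-band and tracks noise — then
refined over 3 passes by low-passing (zero-phase Butterworth, cutoff
0.05 × Nyquist) the instantaneous frequency of the current component
estimate; synchronous detection (quadrature mixing + low-pass capped at
0.8 × the tracked frequency, so the 2f detection ripple is rejected)
yields envelope and phase. The component's center frequency is its
envelope²-weighted mean tracked frequency. Reconstruction is exact by
bookkeeping (residual = input − Σ components).

**VMD (tag `ivmd`).** Standard ADMM on the mirror-extended signal:
spectral Wiener-filter mode updates, center-of-mass frequency updates over
the positive half-spectrum, dual ascent with step τ (default 0, i.e.
exact-reconstruction pressure off, tolerant to noise), tolerance 1e-7,
max 500 iterations, α_bw = 2000. ω initialization is `0.5k/K` normalized,
k = 0…K−1 — the first mode starts at DC so slow rhythms (respiration) are
reachable. Auto-K: start at K=2 and increment while the fitted centers
stay separated by > 0.005·fps **and** the residual energy ratio drops by
> 0.02 per increment; this keeps K small exactly when extra modes would
crowd the spectrum and destabilize center-frequency estimates.

## Rate estimation

Bands: cardiac 0.75–3.0 Hz (45–180 bpm), respiratory 0.1–0.5 Hz
(6–30 brpm) — resting-adult ranges. Band content is selected from a mode
set by **band synthesis**: every component whose center frequency or
dominant spectral peak lies in the band is summed; a single qualifier is
used as is; if none qualifies, the component with the largest in-band
energy is taken. Synthesis was chosen over picking one highest-energy
qualifier because decompositions (AFD especially) split one rhythm across
components, and the sum approaches the signal's own in-band content —
measured on the canonical fixture it lifted AFD respiratory recovery from
15/20 to 20/20 seeds without affecting the other engines. The primary
estimator is the argmax of the classical normalized Lomb periodogram
(valid for uneven sampling) over the band on a 0.005 Hz grid; a band whose
best candidate explains < 1% of the signal variance returns a failure
status rather than a number. The secondary estimator counts peaks (minimum
separation 0.8/band.high, prominence 0.25 σ) on the zero-phase
FIR-band-passed signal (Hamming-windowed sinc, taps = 4·fps/low rounded up
to odd, capped at the record length; AR-extended edges); agreement within
10% sets a confidence flag. Rates are amplitude-invariant by construction.

## Numerical choices and degenerate inputs

- Histogram normalization rejects empty histograms; similarity requires
  unit mass on both sides.
- EM: responsibilities via log-sum-exp; variance floor 1e-6; one re-seed
  on component collapse, then error.
- Kalman: covariances symmetrized every step; non-finite states and
  non-positive innovation variances raise immediately.
- Posterior/argmax ties resolve to the lowest index; peak plateaus report
  their left edge — all outputs deterministic given inputs.
- Constant signals are rejected by normalization, the periodogram, and
  rate estimation (degenerate-input errors), not silently zeroed.
- AR extension falls back to mirror reflection whenever the forecast is
  unstable (clamped at 3× the signal's max amplitude).

## Benchmark problem sizes

The quantitative suite runs on one CPU in well under a minute: 20 seeded
60 s subjects for end-to-end recovery, 100 seeded 30 s tones for Kalman
noise reduction, 50 tones for Lomb/FFT agreement, 512-sample signals for
AFD conservation, 5000-point clouds for GMM recovery. These sizes were
chosen so each statistic is stable at the asserted tolerance while the
suite stays fast to iterate on.

## Known limitations

- The HVD frequency tracker assumes one dominant rhythm per extraction
  pass; two tones of nearly equal amplitude and frequency confuse it.
- AFD level grouping keys on spectral peaks; chirps whose peak moves by
  more than the grouping tolerance during the record will fragment.
- VMD auto-K is a greedy heuristic; heavily overlapping bands can stop it
  early.
- The skin-component heuristic (largest mean green) fails on green
  backgrounds; supply an explicit mask in that case.
- Rates are single-window estimates over the whole record; no streaming or
  time-varying rate tracking is provided.
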