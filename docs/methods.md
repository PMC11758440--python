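# Methods

This note records the models, numerical choices and known limitations of
the package, in the order data flows through it.

## Signal model

All signals are uniformly sampled `TimeSeries` (start time, rate, values):
iEEG voltage in mV at a nominal 5 kHz, instantaneous power in mV², and
fMRI region-of-interest traces in arbitrary signal units at 2-s volumes
(or 0.1 s after event-reordered rebinning). Stimulus-locked analysis uses
`EpochSet` windows on the recording's own sample grid — the first epoch
sample is the first grid point at or after `onset + rel_start`, so no
resampling occurs and per-epoch alignment error is below one sample.
Windows are half-open `[start, end)` throughout: a "22-s window" at 2-s
volumes sums 11 samples, the "first 4 s" sums 2.

## The impulse response function and its grid fit

The IRF is a gamma probability density with onset delay,
`f(t) = (t−τ)^(α−1) β^α e^(−β(t−τ)) / Γ(α)` for `t ≥ τ`, evaluated in log
space (stable up to large shapes). It integrates to one, so a unit-area
impulse of neuronal power maps onto the kernel itself; the discrete
convolution weights each term by the sample interval to preserve this.

The fit is an exhaustive search over `α, β ∈ {0.1, …, 15}` (step 0.1) and
`τ ∈ {0, …, 1}` (step 0.1), 247,500 combinations, constructed from scaled
integers so the printed decimals are represented exactly. For each
combination the power epoch is convolved, bin-averaged to the fMRI
resolution, and fitted by a single least-squares amplitude without
intercept — both series are baseline-corrected, and the no-intercept
convention matches the time-course regressions (`y = xβ₁`) used
elsewhere. `R²` is computed against the raw sum of squares of the
(baseline-corrected) fMRI epoch, the convention consistent with an
amplitude-only fit; it is then guaranteed to lie in `[0, 1]`. Ties in the
argmin resolve to the lexicographically smallest `(α, β, τ)`.

Two numerical choices make the full grid fast without changing the
mathematics:

* convolution + binning is linear in the kernel, so both are collapsed
  into one binning matrix built from cumulative sums of the power epoch;
  scoring all kernels is then a single matrix product per α-chunk
  (~6 s for the full grid on one core). A brute-force per-combination
  reimplementation is kept in the test suite and must agree exactly.
* the power epoch enters the fit at 100 Hz (bin-averaged down from
  5 kHz). The kernel and the 0.1-s output bins are smooth at that scale,
  so the discretization error is far below one output bin; tests confirm
  noise-free recovery is exact.

Kernel characterization (OT/TTP/FWHM) works on any single positive pulse:
OT is the earliest rise above zero (bisection-refined; equals τ for the
gamma kernel), TTP the argmax (fine grid + bounded scalar refinement),
FWHM the distance between the half-maximum crossings found by bisection
to 1e-6 s; all reported at 0.1-s precision by default. Multimodal or
non-positive inputs are rejected.

### Identifiability

The grid's `(α, β, τ)` axes are strongly correlated: kernels along the
ridge `τ + (α−1)/β ≈ const` are nearly indistinguishable over a 14-s,
140-sample epoch. Noise-free recovery of a generating on-grid triple is
exact, and recovery remains exact in 100/100 seeded replicates at noise
up to ~1% of the response peak; at 5% noise the argmin frequently lands
on a neighbouring ridge cell (the nearest competitor sits within ~2 noise
variances), while TTP/FWHM of the selected kernel stay within ~0.1–0.2 s
of the truth. The characterization, not the raw triple, is therefore the
robust summary under realistic noise.

### Reference kernels

The double-gamma BOLD reference (`b=2.5, p1=10, p2=11.7, V=1.5`; TTP
3.1 s, post-stimulus undershoot) is implemented as printed. The
gamma-variate CBV/CBF reference is distributed only as a clearly flagged
best-effort reconstruction: its printed formula is typographically
ambiguous, and the implemented reading — a gamma density with shape
`δ²/τ` and rate `δ/τ` — was chosen because it reproduces the peak times
reported next to both parameter sets (2.0 s and 2.0 s). It is excluded
from all quantitative checks.

## iEEG processing

* **Gradient artifact removal**: the artifact is phase-locked to volume
  triggers, so the mean over 90 stimulus-free baseline volumes converges
  on the artifact waveform (residual ∝ 1/√90) and is subtracted at every
  trigger before filtering. Subtraction of a perfect tiling cancels to
  machine precision; trailing partial windows are skipped with a warning.
* **Filtering**: 4th-order Butterworth band-pass 4–190 Hz plus
  second-order IIR notches at 50/100/150 Hz (Q = 30), each applied
  forward–backward (zero phase, so evoked-component timing is
  preserved). The band edges and notch frequencies are data constants;
  order and Q are this package's design choices — standard, stable, and
  giving > 40 dB attenuation at the line frequency.
* **Electrode selection**: the channel maximizing mean power during
  stimulation relative to mean power over the whole recording; ties go to
  the lowest index.
* **Power**: element-wise squaring; no smoothing is applied before
  convolution.
* **Baseline correction** subtracts the per-epoch mean over the
  pre-stimulus window (3 s in design 1, 28 s in design 2), exactly
  zeroing the baseline mean.

## fMRI processing

* **Detrending**: subtraction of a centred moving-average baseline whose
  window equals the 100-s cutoff (odd-length, reflected edges). This
  rejects DC exactly and is zero-phase; components slower than the cutoff
  are suppressed by ≥ 90%, 10-s-scale responses pass within 5%. The
  boxcar has sidelobes near the cutoff, visible as mild leakage of very
  large block responses into neighbouring baseline windows; at the
  response amplitudes simulated here the effect is small.
* **ROI extraction**: per-volume mean over a 3-D mask (nibabel images or
  arrays); an optional left–right flip maps left-side stimulation
  experiments onto a common hemisphere before masking.
* **Event-reordered rebinning**: each ~1-ms spoke carries a timestamp;
  spokes with event-relative times in `[−3, 11)` s are assigned to
  `floor((t_rel + 3)/0.1)` of 140 bins and pooled across the 20
  onset-jittered events (~2000 spokes per bin, the design's volume size).
  Empty bins are flagged and carry NaN. The scheduler works on scalar
  per-spoke surrogate values; image reconstruction is out of scope, so
  the spoke value stands for the ROI intensity that volume-by-volume
  reconstruction of the reordered spokes would deliver.

## Coupling analysis

Response size is the sum of time-course values in a window (22 s from
onset, or the first 4 s). Sizes are z-scored within each experiment
(sample sd, n−1), then averaged over the 4–12 trials per subject and
frequency; each subject–frequency mean is one regression point. Fits are
ordinary least squares; `MSE = SSR/n`; with-intercept `R²` uses total
variance about the mean, no-intercept `R²` about zero. Mean time courses
are means of subject means, so subjects weigh equally regardless of trial
count. The fixed-scaling residual analysis pins one global gain on the
first 4 s of the 7-Hz mean response — the regime the IRF was derived in —
and reports `fmri − β₁ · convolved power` everywhere else. The
"low-frequency" subset is {1, 3, 5, 7} Hz.

## Synthetic data generator

The generator emulates the two study designs with seeded, value-passed
RNG (no global state; identical seeds give bit-identical outputs).

* **Design 1**: 20 × [1-s train of 7 pulses at 7 Hz + 47-s break].
  Onsets receive a deterministic jitter grid — a seed-permuted assignment
  of offsets {0, 0.1, …, 1.9} s, tiling one 2-s volume period — so
  peristimulus spoke phases cover the sub-volume interval. A 4-s
  acquisition baseline precedes the first train so the 14-s analysis
  window fits. The exact acquisition-side reordering scheme of the
  original instrument is not public; this grid jitter reproduces its
  combinatorics (140 bins × ~2000 spokes), not its trajectory.
* **Design 2**: 180-s baseline + 28 × [16-s block + 44-s break], four
  blocks per frequency in {1, 3, 5, 7, 9, 13, 17} Hz, order randomized
  per experiment.
* **Evoked waveform**: three Gaussian lobes (fast positive 0.20 mV at
  12 ms, dominant negative −0.50 mV at 30 ms, slow positive 0.12 mV at
  75 ms; widths 4/9/16 ms), spanning < 143 ms so consecutive 7-Hz pulses
  do not overlap. Within a block the k-th pulse is scaled by
  `a(k) = a_inf + (1 − a_inf) e^(−(k−1)/κ(f))` with rate `κ(f) = 21/f`
  pulses (≈3 at 7 Hz) and floor `a_inf(f) = 1/√(1+(f/5)²)`: both the rate
  and the degree of adaptation grow with frequency, which makes total
  block power peak at 5–7 Hz and decline gently towards 17 Hz — the
  tuning shape evoked responses display in this preparation. Scalar
  floors are also accepted.
* **Contamination**: broadband Gaussian noise (0.05 mV), line sinusoids
  at 50/100/150 Hz (0.10/0.04/0.02 mV, seeded phases), and a gradient
  artifact template (0.5 mV peak, a harmonic stack of the volume rate)
  tiled at the volume triggers.
* **fMRI forward model**: IRF-convolved neuronal power × gain (default
  50 signal units per mV²·s, putting block responses at ~0.3 units),
  bin-averaged to the volume time, plus a slow sinusoidal drift (period
  300 s — beyond the 100-s detrending cutoff, amplitude 0.3) and white
  noise (sd 0.05, ~15% of a mid-frequency block response). Design-1 spoke
  values add white noise of sd 1.0 per spoke (~5% of the response peak
  after pooling 2000 spokes).
* **Planted coupling structure** (off by default): a frequency gain
  profile and/or a *sustained* gain applied to power from 4 s after block
  onset, scaled with stimulation frequency (`1 + (S−1)f/7`). The
  frequency scaling matters: a frequency-uniform late gain rescales all
  response sizes nearly collinearly and leaves the full-window regression
  intact, whereas the frequency-scaled form reproduces the observed
  signature — full-window/all-frequency R² collapsing while the
  first-4-s and 1–7 Hz fits stay tight, and per-frequency β₁ rising
  monotonically. The demonstration scenario uses S = 6, chosen to match
  the severity of the reported effect (full-window R² ≈ 0.2).

What the generator does **not** emulate: k-space/radial image formation,
motion, physiological (cardiac/respiratory) noise, electrode drift,
inter-subject IRF variability, or any nonlinearity beyond the planted
gain structure. Passing tests therefore validate the analysis chain's
correctness and its qualitative behaviour under the modelled effects —
not performance on raw scanner data.

## Pipeline and problem sizes

`run_simulate` / `run_derive_irf` / `run_correlate` orchestrate the
stages behind `PipelineConfig` (YAML-serializable; study-design values —
filter band, notches, windows, bins, grids, 90 baseline volumes — are the
immutable defaults). Every report embeds the seed, a config hash, and the
defaults decided where the design is silent (filter order/Q, tie-breaks,
z-score denominator, MSE definition), so any report regenerates
identically from its manifest. The CLI exposes the three operations as
`simulate`, `derive-irf` and `correlate` (exit codes: 2 validation,
3 I/O, 4 degenerate numerics); preprocessing and reporting are folded
into the latter two rather than being separate subcommands.

Default scales follow the study designs (20 events / 28 blocks; 13
subjects × 2 sessions for design 2). Tests and the bundled demonstration
runs use 2–6 subjects and, where noted, shortened block schedules — sizes
at which every qualitative property these runs check (recovery,
R² orderings, determinism) is already stable.

## Known limitations

* The `(α, β, τ)` triple is not identifiable under realistic noise (see
  Identifiability); report the characterization.
* The boxcar detrend leaks a small fraction of very large block responses
  into adjacent baselines; a sharper high-pass trades this against edge
  ringing and was not adopted.
* The gamma-variate reference kernel is a flagged reconstruction of an
  ambiguous printed formula.
* The spoke-level fMRI model bypasses image reconstruction entirely;
  reconstruction-induced bias in rebinned responses is out of scope.
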