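# Methods

This note documents the models, conventions and numerical choices behind
`photoscratch`, in the spirit of a methods section a maintainer can audit.

## The measurement being modeled

Fiber photometry of GCaMP6s-expressing neurons with frequency-multiplexed
excitation: a 405 nm LED (calcium-insensitive, isosbestic) and a 470 nm LED
(calcium-sensitive) are sinusoidally modulated at distinct carrier
frequencies (defaults 211 Hz and 537 Hz), both emission streams land on one
photoreceiver, and the voltage is digitized at 10 kHz. The per-channel
fluorescence envelopes are recovered in software; the isosbestic channel is
used to remove motion and fiber-bending artifacts from the calcium channel;
the result is normalized to dF/F and analyzed around scratching-bout onsets.

## Forward model (synthetic sessions)

The generator is the package's ground-truth instrument; all acceptance-level
claims are parameter-recovery statements against it.

- **Events.** Scratching is a Neyman–Scott cluster process: bout "centers"
  arrive as a homogeneous Poisson process (default 0.01 s⁻¹), each spawning
  `1 + Poisson(events_per_cluster − 1)` events (default mean 4) with
  exponential intra-burst gaps (default mean 2 s). Scratching occurs in
  trains, and the downstream 30-s merge should recover the clusters.
- **Calcium transients.** One difference-of-exponentials kernel per bout
  onset (the 30-s merge of the event train), peak-normalized, default
  0.2 s rise / 1.5 s decay (GCaMP6s-like), fractional amplitude 0.2 over
  baseline, Gaussian onset jitter (default 0.05 s).
- **Bleaching.** Exponential decay per channel. Both channels default to a
  shared time constant of 2400 s (≈ 22% decay over a 10-min session). A
  shared constant is the physically matching choice when one indicator pool
  dominates both emission streams, and it is the regime in which a
  session-wide affine scaling of the control channel is correctly
  specified; per-channel constants are configurable to study
  misspecification, in which case the session fit absorbs part of the
  bleach mismatch into the gain and motion suppression degrades.
- **Motion.** A unit-variance Gaussian process band-limited below 2 Hz
  (white noise filtered zero-phase at 2 Hz, standardized), added linearly
  to both envelopes. Default gains are 6% of the 405 nm baseline and 12% of
  the 470 nm baseline — i.e. proportional to the channel baselines, as for
  a multiplicative optical-path artifact. This linear shared-artifact model
  is the minimal one under which isosbestic subtraction is exact.
- **Modulation and noise.** `raw(t) = Σ_c env_c(t)·(1 + sin 2πf_c t)/2 +
  ε(t)`, ε white Gaussian (default SD 5 mV against a 1–2 V baseline). A
  square-wave drive is available behind `waveform="square"` (note the
  lock-in calibration is exact for the sinusoidal drive).

What the generator does **not** emulate: hemodynamic artifacts,
wavelength-dependent motion coupling beyond a shared linear term,
non-exponential bleaching, sensor nonlinearity/saturation, room-light
pickup, or behavioral mislabeling of events. Passing tests therefore show
the pipeline is correct under its own stated assumptions, not that those
assumptions hold for any particular rig.

Desk-scale statistical studies (thousands of replicates) use
`simulate_dff_trace`, which emulates the *output* of the pipeline directly:
baseline + transients + Gaussian noise band-limited to the 4 Hz output
bandwidth with dF/F-scale SD 0.02 (a typical post-filtering noise floor).
This avoids re-simulating the 10 kHz front end where only the statistics of
the corrected trace matter.

## Demodulation

Quadrature lock-in: multiply by sine and cosine references at the carrier,
low-pass both products (zero-phase Butterworth via `sosfiltfilt`), take the
magnitude ×4 (exact for the raised-sinusoid drive, and phase-insensitive).
Defaults: 4 Hz cutoff, order 4, decimation to 100 Hz.

- Order 4 keeps the constant-envelope gain error below 0.1% for any carrier
  above ~10 Hz and puts both carriers far beyond 60 dB down; order is
  configurable.
- Settling: zero-phase filtering contaminates the trace ends. Samples
  within 3 effective time constants (τ = (order/2)/cutoff, i.e. 1.5 s at
  the defaults) of either edge are flagged in `settling_mask` and excluded
  from every downstream statistic.
- Decimation after filtering is alias-free because the content is already
  band-limited to the cutoff.
- Measured fidelity (zero sensor noise, default session): ≈ 0.2–0.3%
  relative RMS envelope error; the residual is mostly the few-percent
  attenuation of near-2 Hz motion content inside the 4 Hz passband.

## Isosbestic correction and dF/F

The control channel is scaled to fit the signal channel by ordinary least
squares over the whole session's unmasked samples — affine (gain + offset)
by default, the offset absorbing dark current and making the exact-identity
case exact; pure-gain mode behind `gain_only=True`. The scaled control is
subtracted: `corrected = signal − (a·control + b)`.

Two dF/F conventions:

- `session-mean`: `dff = corrected / mean(corrected)` (unmasked mean exactly 1 by
  construction). **Caveat:** affine OLS residuals have *exactly* zero mean,
  so after affine subtraction this divisor is degenerate by construction.
  `compute_dff` guards the divisor (default: it must exceed 5% of the
  uncorrected signal mean) and raises a `DegenerateBaselineError` naming
  the alternative.
- `fitted-control`: `dff = (signal − fitted_control)/fitted_control`, the
  widespread convention for isosbestic-corrected photometry. Baseline sits
  at 0 and a transient of fractional amplitude *a* appears as a dF/F
  excursion of *a*. Because it is well-posed under the default affine fit,
  the end-to-end pipeline (`PipelineConfig`) defaults to this mode; the
  divide-by-own-mean convention remains the `compute_dff` default for
  callers who work with traces that retain a baseline.

Session-wide fitting only ("for the recording session"); per-segment fits
are deliberately not implemented. No bleach detrending beyond what the
subtraction provides.

## Peri-event analysis

- **Bout merging:** successive events with onset-to-onset gap ≤ 30 s join
  one bout (offset-to-onset mode behind a flag when event durations exist).
  The implementation is checked against a brute-force interval-union
  oracle; it is idempotent and the bout count is non-increasing in window
  size, with event counts conserved exactly.
- **Alignment:** one matrix row per bout onset whose full [−pre, +post]
  window lies inside the unmasked trace; other onsets are excluded with a
  recorded reason (no padding/imputation). Rows are linearly interpolated
  onto a common bin grid (default bin = one output sample, 10 ms).
- **Z-score:** z = (x − μ)/σ with the sample (n−1) convention, consistent
  with the SEM and t test. The reference is selectable: each trial's own
  window (default), a pre-onset baseline window, or the whole session
  trace. The default is a documented package choice; rigs and labs differ
  on this convention.
- **Pre/post comparison:** per-trial means over [−5, 0] s and [0, +5] s
  (configurable), returned as two groups and compared with a
  pooled-variance two-sample t test (df = n₁ + n₂ − 2; Welch available).
  The pre/post window means of one trial are computed from disjoint
  segments whose noise correlation is small at the 4 Hz bandwidth, and the
  Monte-Carlo calibration confirms the unpaired test's size (type-I error
  ≈ 0.05 at α = 0.05 over 2000 null simulations).

## Behavioral scoring

All scores are dwell-time arithmetic on piecewise-constant occupancy
records (accepted in per-sample or per-interval dialects and normalized
internally; an optional debounce suppresses sub-threshold boundary
flickers, off by default to keep the stated scoring exact):

- CPA score = time in the pruritogen-paired compartment, post-test minus
  pre-test (antisymmetric under phase swap, zero on identical records).
- RTPT: time-in-chamber, and the closed-loop stimulation intervals are the
  maximal occupancy intervals of the stimulation zone (their total length
  equals time-in-zone identically).
- EZM: open-section time, fraction, and entries (closed→open transitions;
  starting in an open section is not an entry).
- Scratching time course: histogram of bout onsets, counts conserved.

## Colocalization

A cell is positive for a channel when its nuclear puncta count reaches the
threshold (≥ 5 by default, the cFos rule; configurable per channel — the
same threshold is applied to all channels unless overridden). Overlap is
reported bidirectionally (100·|A∩B|/|A| and /|B|), with NaN (never 0) for
empty denominators and raw counts always attached. Multi-section results
pool counts before taking percentages (the mean of per-section percentages
is also reported, but pooled counts are primary).

## Problem sizes and defaults used in validation

Validation runs use 600-s sessions at the native 10 kHz for
signal-fidelity checks, 20 seeded sessions for end-to-end amplitude
recovery, 2000/200 desk-scale replicates for test size/power, and 500
random event trains for the bout-merge oracle. These sizes give
Monte-Carlo error comfortably below the tolerances being checked.

## Known limitations

- The lock-in gain calibration assumes the raised-sinusoid drive; square
  drives recover the envelope up to a known 4/π fundamental factor.
- No time-division multiplexing or camera photometry support.
- The session-mean-mode dF/F is undefined when the corrected trace loses its
  baseline (see above); this is inherent to the convention, not a bug.
- Occupancy scoring consumes zone labels; distances/velocities would need
  coordinate streams the package does not model.
- No spike inference or mixed-effects modeling across animals.
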