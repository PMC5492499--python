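# Methods

This note documents the signal models, the parameters that matter, the
synthetic-data generator, and the numerical design choices — in enough
detail to reproduce or audit any stage.

## Frame model and regions

A recording is a real amplitude matrix W of m slow-time frames × n
fast-time bins (raw ADC units), with slow-time sampling frequency
`fs_slow` (default 110 Hz) and fast-time bin spacing (default 1 m/256 ≈
3.9 mm of range per bin).  Two half-open fast-time regions are analysed
independently: the *phone* region (bins 0–64, the 25 cm nearest the
radar) and the *vitals* region (bins 64–192, ~50 cm covering the torso).
The bin offsets of the regions relative to the radar face are
configurable, not asserted; the widths follow from the stated 25 cm and
~50 cm extents.  Indices are 0-based and half-open internally; reporting
helpers convert to the 1-based inclusive reporting convention.

On disk a recording is a comma-separated text matrix (one frame per row,
`%.17g`, so doubles round-trip exactly) with a JSON sidecar
(`fs_slow_hz`, `bin_spacing_m`, `origin_m`, `created_by`, `seed`), or an
HDF5 container for large runs.

## Clutter removal

The static background is tracked per region by the exponential loopback
filter c_k = α·c_{k−1} + (1−α)·r_k and subtracted.  Conventions fixed
here (the recursion itself does not dictate them):

* y_k is computed against c_{k−1}, the clutter *before* frame k is
  absorbed; c_0 is seeded with the first frame, so y_0 = 0 and there is
  no startup spike.
* α = 0.97 for vitals (slow, noise-robust), α = 0.8 for the phone region
  (fast adaptation).  The filter acts as a high-pass on slow time: at
  110 Hz and α = 0.97 a 0.3 Hz breathing tone passes with gain ≈ 0.49
  and a 1.2 Hz heart tone with gain ≈ 0.91, which slightly *flattens*
  the breathing-to-heart amplitude ratio.
* For the detector's frozen mode, the clutter captured `k_margin` frames
  (default 10 ≈ 0.09 s) before the triggering transient is kept aside
  and never updated.  The detector buffers the last `k_margin + 1`
  clutter states; if a transient fires earlier than `k_margin` frames
  into a run, the margin is clamped to the history available.

## Single-sinusoid maximum-likelihood fit

Each bin's mean-removed slow-time signal is modelled as
x[n] = A·cos(ωn) + B·sin(ωn) + w[n], n = 1..N, with white Gaussian
noise.  For fixed ω the ML amplitude estimate is ordinary least squares
against H(ω); concentrating the likelihood leaves
g(ω) = xᵀH(HᵀH)⁻¹Hᵀx to maximize over ω.

* ω search: a dense deterministic grid of 1024 points over 0.05–3.0 Hz
  (covering respiration and heart bands), then up to 3 parabolic
  refinement steps around the grid argmax.  Grid ties break toward the
  lowest frequency.  A derivative-free search was chosen over
  Gauss–Newton for determinism and robustness to the objective's many
  local maxima.
* The offset term is excluded by default (callers pass clutter-removed,
  mean-removed signals); `include_offset` adds the ones column.
* σ̂² divides by N (the ML estimator), not N − df.
* Fit quality is R² = 1 − SS_res/SS_tot of the fitted sinusoid.  R² of a
  constant signal is undefined and reported as a flagged zero-amplitude
  fit.
* The grid evaluation is vectorized across bins with the closed-form 2×2
  inverse of HᵀH, and the trig tables are cached per (grid, N) — fitting
  128 bins × 6600 samples takes ~1 s after the first call.

## Candidate selection

A fit's R² is replaced by zero if its frequency is outside 0.15–0.5 Hz
or its amplitude is below a threshold; the gated profile is smoothed with
a centered 5-bin moving average (edges truncate) and bins with smoothed
profile ≥ 0.3 are selected.  Choices:

* Amplitude threshold: the procedure requires one without fixing its
  value.  Default is `auto` = 3 × the median fitted amplitude
  over the region's bins — robust to overall gain, weak when most bins
  are noise.  An absolute value can be configured.
* Smoothing runs *after* gating (gating a smoothed profile would let
  out-of-band bins borrow credit from their neighbours).
* The selected rows are the raw clutter-removed, mean-removed slow-time
  signals, not the fitted sinusoids — segmentation must operate on
  measured data.
* The pipeline forwards at most the 9 best-profile candidates to the
  reconstruction (`select.max_candidates`; the method is designed around a handful of
  best-fit columns, typically four to twenty).
  On clean synthetic data ~50 bins can clear the threshold, and the
  low-amplitude edge bins among them add stitching noise without adding
  information.  The selection operation itself always returns every
  above-threshold bin.

## Vital-signal reconstruction

Each candidate is segmented at its zero crossings; the vital signal is
grown greedily: initialisation copies, from the candidate whose *first*
crossing is furthest out, everything up to that crossing; each iteration
tentatively appends, from every candidate, the samples between the
current end and that candidate's next crossing, scores each concatenation
by its autocorrelation width, and keeps the widest.  All ties break
toward the lowest candidate index; the procedure is deterministic and
each appended segment is verbatim from one source row.

Numerical choices, each load-bearing:

* **Width definition.** The width is the *total* lag extent (all runs,
  exits linearly interpolated, hence fractional) over which the
  normalized biased autocorrelation of the mean-removed concatenation
  stays ≥ `level` (default 0.5).  Two rejected alternatives: (i) the
  integer count of contiguous lags from zero ties constantly and the
  greedy degenerates; (ii) restricting to the contiguous run from lag 0
  measures only the local oscillation shape — inverting a signal's
  second half at a zero crossing leaves that shape untouched, so phase
  breaks went *unpunished*.  The total-extent form sees the long-lag
  coherence collapse (a 3-cycle tone scores ~175 lags against ~77 for
  its half-inverted twin) while noise still scores ~1 lag and the width
  of fixed-cycle tones still grows with period.
* **Mean removal inside the width.**  Without it, a run of sign-inverted
  appends gives the construction a net offset that holds the
  autocorrelation above the level at every lag, and the score goes
  blind.
* **Bounded scoring context.**  The width is evaluated on the trailing
  `score_context` samples of the construction (default 220 ≈ 2 s at
  110 Hz, about one breathing half-period) plus the tentative segment.
  On a 60 s recording the width of the full concatenation moves by less
  than 0.1 lag per appended segment — no discrimination — whereas with a
  bounded context one segment is a large fraction of the scored signal,
  which is the regime the procedure is designed for (constructions a
  few hundred samples long, where one segment is a large fraction).  `score_context: null`
  restores whole-signal scoring.
* **Segmentation robustness.**  Crossings are detected with a Schmitt
  trigger of half-width `hysteresis_frac` × row RMS (default 0.2) and a
  minimum spacing `min_segment` (default 33 samples ≈ 0.3 s, far below
  any breathing half-period).  Sampled noise flickers the sign near
  every true crossing of a slow oscillation; without the band a 60 s
  candidate shows hundreds to thousands of crossings instead of ~36 and
  the segments fragment into meaningless scraps.  Both default to off
  (`0.0` / `1`) in the pure `zero_crossings` function, whose contract is
  the strict sign-change definition.
* Candidates with no further crossings drop out of later iterations;
  their earlier segments remain.  Zero samples at a crossing belong to
  the preceding segment (half-open arithmetic).

## Rate readout

The constructed signal is mean-removed, zero-padded to a 2¹⁵-point FFT
(resolution 110/2¹⁵ × 60 ≈ 0.2014 cycles/min), and each rate is the
frequency of the maximum-magnitude bin in its band: respiration
0.15–0.5 Hz, heart 0.8–2.0 Hz (the heart band is not printed in the
source material; 48–120 bpm is the configurable default).  No peak
interpolation; integer reporting rounds half up.  Since chest
displacement from breathing dominates, the heart peak is the globally
second-highest peak, matching how the spectrum is read by eye.  There is
no cancellation of breathing harmonics: when a breathing harmonic falls
inside the heart band with comparable magnitude (e.g. 24 cpm breathing
puts its second harmonic at 48 bpm), the readout can lock onto it — a
known limitation of the method.

## Phone detector

States: S1 no detection, S2 transient, S3 phone detected, S4 background
change.  "Peak value" means the max over fast-time bins of |y| (sign
convention is not observable in magnitude plots).  Transitions, per
frame:

* S1: running clutter updates; if max|y| > threshold 1 (3.0), freeze the
  clutter from `k_margin` frames earlier and go to S2 (the triggering
  frame starts the hold count).
* S2: if max|y̆| ≤ threshold 1 → S1 (momentary event).  Else if the max
  of max|y| over the trailing `t_y` = 1.0 s window < threshold 2 (0.8)
  → S4, logging `background_change`.  Else the hold count grows; at
  `t_hold` = 1.2 s (132 consecutive frames with max|y̆| above
  threshold 1; one sub-threshold frame resets the count) → S3, logging
  `phone_start`.
* S3: y̆ dropping → S1 (`phone_end`); windowed y dropping → S4
  (`background_change`).
* S4 is a one-frame absorbing state: the running clutter is re-seeded
  from the current frame, the frozen copy and window are discarded, and
  the detector returns to S1 on the next step.

The running clutter continues updating in S2/S3 — that is what makes y
distinguish micro-motion from a static absorbed object — while the
frozen copy is never touched.  With an object entering at 0.7 s and
sustained micro-motion, detection fires at 0.7 + 1.2 ≈ 1.9 s.  One
behaviour worth noting: after a momentary object leaves, its departure
transient can re-trigger S2 against a clutter that had absorbed it, and
the detector then traverses S4 to re-absorb the restored background.
This never reaches S3, so momentary events are still never flagged as
phone use.

## Synthetic-data generator

The generator emulates the structure the pipeline assumes, not radar
electromagnetics (no multipath, no antenna pattern, no scattering
model).

* **Pulse template**: a Hann-windowed carrier at the two-way spatial
  frequency 2f_c/c (defaults 6.8 GHz center, 2.3 GHz bandwidth), unit
  energy, support = range resolution c/2B ≈ 17 bins.  Rendering at
  fractional offsets evaluates the analytic expression — a
  piecewise-linear table lookup puts kinks at integer offsets, exactly
  where sub-bin chest motion dithers, and rectifies it; and the window
  is clipped where it reaches zero with zero slope, keeping the rendered
  pulse C¹ in the offset.  (An earlier hard clip at the last nonzero
  sample produced a displacement-independent spectral line at 3× the
  breathing rate from template-edge bins switching on and off.)
* **Vitals scenes**: a smooth static clutter profile; a torso spanning
  40 bins, each bin a template reflection with reflectivity ~U(0.7, 1.3)
  × 10 ADC and phase jitter uniform in ±0.3 rad (candidates similar but
  not identical, as the reconstruction assumes); chest displacement =
  breathing sinusoid + heartbeat sinusoid, defaults 4 mm and 0.4 mm
  *peak-to-peak* (quiet-breathing chest physiology).  The peak-to-peak
  convention matters: at ±4 mm amplitude the two-way carrier phase
  modulation (≈1.15 rad) pushes the breathing third harmonic above the
  heartbeat line at most bins, destroying the heart-as-second-peak
  structure the readout relies on.  White noise sd 0.05 ADC.  Optional
  broadband motion artifacts (white, sd 20 ADC — body motion is an
  order of magnitude above chest micro-motion) over a time × bin window,
  and an optional slow 0.05 Hz global drift.  Two named conditions are
  used throughout: `transient_artifact_scenario` (60 s, 18 cpm / 72 bpm,
  a 5 s artifact over the upper half of the torso) and
  `slow_drift_scenario` (60 s, 1 mm drift).
* **Phone scenes**: a peak-normalized template at one bin; sustained
  kinds (texting/scrolling/viewing) appear at 0.7 s with peak amplitude
  8 ADC and micro-motion bursts of ±2 ADC, ~0.1 s long, every 0.3–0.45 s
  (always inside the 1 s window); momentary kinds persist 0.5 s (below
  the 1.2 s hold); background kinds step and stay (or are present from
  the start and vanish).  Ground truth — rates, artifact windows,
  intended verdicts — travels in a separate sidecar; no test reads truth
  from the waveforms.

What passing tests on this generator do **not** show about real data:
real chest reflections have continuous range profiles rather than 40
discrete template copies, real motion artifacts are correlated rather
than white, breathing is non-sinusoidal (its true harmonics are larger),
and real clutter drifts thermally.  The generator is calibrated so that
the R² profiles, best-fit column counts (a handful, not dozens) and
spectral structure (heart = second peak) match what this class of
radar reports for real seated subjects.

## Analysis sizes

The stock analysis window is 30 s (hop 5 s) for monitoring; the
reference-recovery computations in `scripts/acceptance.py` and the test
suite use single 60 s windows, ten seeds per condition, and 50 episodes
per detector condition — sizes at which the full run completes in well
under a minute on one CPU.

## Known limitations

* No harmonic cancellation: heart readout fails gracefully to a
  breathing harmonic when the true heart line is weaker than it within
  the band.
* The greedy reconstruction does not backtrack; a mis-chosen early
  segment is never revisited.
* The detector cannot distinguish a phone from any other hand-held,
  micro-moving object — the discrimination is purely temporal.
* Phase estimates of the sinusoid fit depend on the n = 1..N indexing
  convention and are reported but nowhere asserted.
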