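# Methods

`walkvep` re-implements, as a reusable and tested pipeline, the
analysis chain of a mobile-EEG experiment in which observers detect
contrast targets on a 15 Hz flickering grating while standing still,
walking slowly, or walking at normal speed, with the grating embedded
in a surround of 0/33/67/100% contrast. Because the package is
exercised against synthetic sessions rather than the original
recordings, this note describes both the analysis conventions and the
generative model behind the synthetic data, and states explicitly what
passing tests do and do not show.

## Experimental design encoded in the generator

One participant completes 21 blocks (7 per walking condition, shuffled).
Each block presents the four surround-contrast levels for 35 s each in
random order, giving 84 contrast periods. Six targets appear per
period in the window 5–31.5 s after period onset with stimulus-onset
asynchronies drawn uniformly from 3.5–6.5 s (rejection sampling over
the SOA vector guarantees feasibility), giving 504 targets per
participant. Responses within 1 s of a target onset count as hits;
every other press is a false alarm.

## Signal model

EEG (16 channels), EOG (6), earlobe (2) and a 3-axis gyroscope share a
500 Hz clock; body/ankle speed traces run at 120 Hz. Per channel the
EEG is a sum of:

* **1/f background** — Gaussian noise spectrally shaped to
  `P(f) ∝ f^(-χ)` with χ = 1 by default and RMS 4 μV;
* **SSVEP** — a 15 Hz sinusoid whose amplitude is
  `base × map(condition, contrast) × jitter`, projected through an
  occipital gain profile (Oz strongest). The default map is flat in
  contrast when standing still and increasingly suppressed by surround
  contrast when walking — the qualitative effect the pipeline is meant
  to recover. Amplitudes are in μV but are free parameters: the source
  study reports no microvolt values for them;
* **alpha** — a sinusoid at a participant-specific integer peak
  frequency (8–12 Hz, so the 1 Hz analysis grid can recover it
  exactly), slowly amplitude-modulated, with condition-dependent
  amplitude (4/3/2 μV for still/slow/normal: walking reduces alpha);
* **high-frequency noise** — band-limited 20–99 Hz Gaussian noise with
  RMS 1/1.5/2 μV for still/slow/normal, emulating the broadband
  spectral upshift of walking EEG without modelling EMG explicitly;
* **gait components** — sinusoids at 1 Hz (slow) or 1.75 Hz (normal)
  plus a second harmonic; the same frequencies drive the ankle speed
  traces.

Per-period SSVEP and alpha amplitude jitters are log-normal with
configurable correlation (`alpha_ssvep_coupling`), so trial-level
association analyses have a known ground truth.

Artifacts: blinks are 400 ms raised cosines with a 150 μV peak on the
vertical EOG difference (comfortably above the 20/40 μV detector
thresholds); saccadic spike potentials are biphasic
derivative-of-Gaussian wavelets (σ = 2.2 ms, energy inside the
20–90 Hz detection band) injected on all six EOG channels with peak
amplitude quadratic in saccade size, `a(s) = 35 + 15 s + 1.6 s²` μV
with sizes log-normal in 0.1–5°; head movements are 0.7 s velocity
bursts on the gyroscope. Artifact counts per period are deterministic
(`round(rate × 35 s)`) with random placement, so ground-truth
bookkeeping is exact. Defaults (6 blinks/min, 40 saccades/min — free
walking elicits frequent small saccades) set the signal-to-noise
regime in which the detectors are expected to operate well; they are
generator properties, not detector tuning.

The simulated observer detects each target with probability
`(1 − λ)·Φ((level − θ)/σ)`, with threshold θ depending on condition ×
contrast (walking and surround contrast raise it), slope σ = 0.02,
lapse λ = 0.02. Reaction times are shifted log-normal (shift 200 ms,
median ≈ 450 ms), keeping most hits inside the 1 s response window.
Determinism: all draws flow from `SeedSequence(seed, spawn_key=
(participant, stream))`, so a configuration fully determines a session
bit for bit.

## Analysis conventions

* **Time** — seconds from recording start, 0-based samples, half-open
  windows `[t0, t1)`; an event on a trial's start boundary belongs to
  the trial.
* **Filtering** — windowed-sinc FIR, Kaiser window, 60 dB stopband,
  transition width 25% of the lower band edge with a 1 Hz floor; the
  symmetric odd-length kernel is applied once with its group delay
  compensated (exactly zero-phase). The 14.5–15.5 Hz envelope filter
  uses a Hamming-window FIR; its ±0.5 s edges are excluded from
  envelope statistics.
* **Spectra** — Welch, 1-s periodic-Hamming windows, 50% overlap,
  density scaling on the 1 Hz grid (band sums then satisfy Parseval).
  SSVEP power is read at 15 Hz and referenced by subtraction to the
  mean of 13/14/16/17 Hz; alpha is referenced to 10/11/12 Hz at the
  participant's peak alpha frequency, estimated from still-condition
  trials only (the estimation context is not specified by the
  protocol; still trials have the highest alpha SNR). Note that when
  the peak frequency is 10–12 Hz the reference set contains the peak
  bin itself — implemented as specified, flagged here for users.
* **Trial exclusion** — trials with a button press in the 2.5 s before
  target onset are dropped; then, within each walking condition,
  trials whose 20–99 Hz power sum `p` satisfies
  `|p − median(P)|×0.6745 > 2.24×MAD` are dropped. The rule is
  scale-invariant; groups under 3 trials are skipped with a warning.
  Trials starting before their period are flagged and dropped (the
  protocol is silent; in-design they cannot occur since targets start
  at 5 s).
* **Channel selection** — the 3 occipital-pool channels with highest
  mean 15 Hz power over all trials; ties break by pool order.
* **Epoch repair** — "visual inspection" is replaced by an explicit
  (epoch, channel) mask argument repaired by neighbour averaging, for
  reproducibility.
* **Detectors** — blink: vertical EOG (above − below, left eye),
  0.2–20 Hz, 20 μV crossing, peak ≥ 40 μV, local SD ≥ 15 μV in a
  400 ms window centred on the peak (the window length is this
  package's choice), 100 ms merge. Saccade: REOG (mean of 6 EOG − Pz)
  band-passed 20–90 Hz with a 6th-order Butterworth (applied
  forward–backward for zero phase), Hilbert envelope thresholded at
  mean + 2.5 SD per block, 20 ms grouping, detections within 100 ms of
  block edges discarded. Head movement: per-block deviation magnitude
  of the mean-subtracted gyro vector at mean + 2.5 SD, 2 s merge.
* **Spike-size calibration** — a degree-2 polynomial is fitted
  directly from amplitude to size (the inverse reading of a
  size-vs-amplitude fit); monotonicity inside the calibrated range is
  checked rather than assumed, and out-of-range amplitudes are clamped
  and flagged.
* **Staircases** — 1-up-4-down with a fixed 2% step (screening; the
  step is not documented in the protocol), 1-up-3-down with 6% steps
  before the fourth reversal and 3% after, stopping at 13 reversals;
  threshold = mean of the last 10 reversal levels; initial level 0%.
  Levels clamp at zero with a flag.
* **Preference index** — implemented as `Σ|T − tᵢ| / (6T)`. The
  protocol prints the numerator as the absolute value of the *sum* of
  deviations from the mean, which is identically zero; the
  sum-of-absolute-deviations reading reproduces the stated anchor
  values (0 for uniform rates, 1 for single-location responding) and
  is what this package computes. The simulation null assigns each
  detected target independently and uniformly to the four locations;
  the p-value is the fraction of null indices ≥ the observed one,
  which is conservative under the discrete null distribution.
* **ANOVA** — two-way within-subjects, computed directly from sums of
  squares (each effect against its effect-by-subject interaction) so
  that oracle-equivalence tests against independent implementations
  are meaningful. Greenhouse–Geisser ε follows the Box definition on
  the orthonormalized effect contrasts (including the interaction);
  the correction is applied when Mauchly's test rejects sphericity at
  α = 0.05, and a singular contrast covariance (n − 1 ≤ df) is treated
  as a sphericity violation. Block-wise "normalisation" in the
  two-level regression is a z-score; the protocol does not name the
  transform.
* **Median split** — trials split at the per-condition median of raw
  SSVEP power, median trial to the weak group; in walking conditions
  the 5 lowest-HF weak trials and 5 highest-HF strong trials are
  removed, but only when both groups keep ≥ 5 trials afterwards.

## Problem sizes in the test suite

Routine tests use one block per condition (12 periods, 72 targets) —
the smallest session exercising all three conditions. The
interaction-recovery study uses a trial-level generator that renders
2-s occipital trials directly (identical signal model, no 35-s
rendering or EOG/gyro streams): 100 experiments × 25 participants ×
12 cells × 6 trials. Staircase checks use 2,000 trials × 100 seeds
(1-up-4-down) and 200 runs (1-up-3-down).

## What passing tests show — and what they do not

The synthetic generator contains exactly the structure the analysis
assumes: sinusoidal narrowband components, stationary noise within a
period, template artifacts, an observer with a stationary psychometric
function. Passing tests therefore demonstrate correctness of the
computations and recoverability of effects *under the assumed model* —
they do not show that real free-walking EEG satisfies those
assumptions (non-stationary EMG, electrode motion, blink–saccade
interplay, drifting thresholds are all absent). Detector
recall/precision figures in the tests are specific to the generator's
default SNR. No claim is made about reproducing the original study's
F statistics or topographies, which would require its recordings.

## Known limitations

* EDF output quantizes each channel to 16 bits over its own range.
* The envelope band-pass (1 Hz wide) has a ~2 s impulse response;
  target-evoked perturbation estimates inherit that smoothing.
* `simulate_observer` models false alarms as a homogeneous Poisson
  process, uncorrelated with gait or condition difficulty.
* The repair operation implements plain neighbour-set averaging, not
  spherical-spline interpolation.
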