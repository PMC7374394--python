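# Methods

## The optimization problem

The package optimizes the architecture of a 1D convolutional classifier for
five respiration patterns over a discrete space of per-layer kernel sizes
(KS), per-layer kernel counts (KC) and two dense-layer widths (DLNC).  The
convolutional depth (`cld`) is a fixed configuration value, not a search
axis; the dense head always has exactly two layers.  Kernel sizes are
odd-only by default: the reference configuration's stated axis count (40
values between 3 and 81) is consistent only with an odd grid, so the parity
flag is on unless a space explicitly disables it.  Cardinality is computed
in exact integer arithmetic as `|KS|^cld · |KC|^cld · |DLNC|²`; the
~9.7 × 10²⁰ of the full space never touches floating point.

## Harmony Search engine

One candidate ("harmony") is proposed per iteration:

* **Memory recall** with probability HMCR, uniform over the memory.
* **Pitch adjustment** of a recalled candidate with probability PAR.  Every
  coordinate is adjusted — all kernel sizes, all kernel counts, both dense
  widths.  The step δ is drawn uniformly from the signed nonzero integers in
  [−MPAP, MPAP]; on the odd-only axis only even steps are admissible, so
  parity is preserved by construction.  A literal additive mode (always
  +MPAP) is available behind `signed=False` for fidelity experiments, but
  the default is symmetric: a one-sided step would drift every coordinate
  monotonically to its upper bound, which contradicts the role of pitch
  adjustment as a *local* search around existing candidates.  Out-of-bounds
  results are clipped to the nearest admissible value (with parity restored
  toward the interior) rather than redrawn, keeping proposals total and
  cheap.
* **Random selection** otherwise: a uniform draw over the whole space.

The memory replaces its worst entry only on strict improvement — ties never
replace — and stays sorted by rate descending, ties broken newest-first so
runs are fully deterministic under a seed.  Duplicates are permitted (tiny
spaces force them).  HMCR/PAR/MPAP are fixed once per run, sampled from the
recommended grids (HMCR 0.50–0.70, PAR 0.60–0.80 in 0.05 steps, MPAP 10–18)
unless overridden; overrides off the grid are configuration errors.

**Stagnation accounting** follows the *best* entry: a strict improvement of
the top rate resets the counter (`I_prev = I_curr = j, ΔI = 0`); any other
iteration — including a memory update that does not touch the top — sets
`ΔI = I_curr − I_prev`, and the run stops once `ΔI ≥ k`.  Consequently a run
whose last best-update happened at iteration *j\** terminates at *j\* + k*.
With a constant objective the stop lands exactly at iteration `k`.

Objective values are cached by candidate tuple within a run (identical
architectures are not retrained); the cache is optional.  Rates are stored
at full float precision and displayed to one decimal.

MPAP's recommended 10–18 range is sized for the full-width axes (40–3841
values).  On deliberately shrunken test spaces those steps mostly clip to
the bounds, so scaled-down verification runs use proportionally smaller
steps (e.g. MPAP = 2 on single-digit axis widths).

## Synthetic respiration signals

The simulator emulates the study protocol — subjects × 5 patterns × pieces,
fixed 10 s pieces, a learning pool split 8:2 into train/validation with the
remainder held out for test — not radar physics.  Defaults follow the
reference protocol: 10 subjects × 50 pieces per type (2500 pieces), pool
1500 → 1200/300, test 1000.  Splits are class-stratified with remainders
distributed at random, so the reference sizes come out exactly.

* **Waveform**: an asymmetric raised sinusoid `A·sin(φ + 0.35·sin φ)` —
  faster inspiratory rise, slower expiratory decay — with a uniform random
  phase per piece and Gaussian sensor noise at the subject's level.
* **Class semantics**: rates drawn uniformly per piece — eupnea 15–20,
  bradypnea 6–12 (depth × 0.6), tachypnea 20–30 (depth × 0.35), apnea
  amplitude × 0.04 of the subject baseline (peak-to-peak stays below 10 % of
  eupnea's even with harmonics), movement adds a random-walk baseline drift
  scaled to 3–6 × the respiratory peak-to-peak.
* **Subjects**: baseline amplitude U(0.8, 1.2), rate offset U(−1.5, 1.5)
  breaths/min, noise s.d. 0.5–1.5 × the configured level (default 0.05).
* **Sampling rate**: 20 Hz by default (200 samples per piece) — comfortably
  above the ≤ 1 Hz respiration band while keeping the largest kernel (81)
  smaller than the input.  The true sensor rate of the reference recordings
  is unknown; any choice here is a stand-in, and the scaled-down runs use
  10 Hz to halve the input length.

**Rate estimation** is by harmonic least squares rather than an FFT peak: a
10 s window holds only one or two bradypnea cycles, so a windowed-FFT peak
is biased by several breaths/min at the low end.  The estimator scans
0.05–0.8 Hz with a fundamental-only projection (a design including
harmonics would score a subharmonic f/2 exactly as well as f), then refines
the minimum locally with two harmonics added.  On noiseless pieces the
recovery error is below 0.01 breaths/min — far inside the ±1 acceptance
band.

What the simulator does *not* model: radar clutter and ranging artifacts,
inter-breath variability within a piece, gradual rate drift, partial
patterns, class imbalance, or sensor dropout.  Tests passing on this data
show the pipeline is correct and the task learnable; they do not certify
performance on real recordings.

## The CNN objective

Each candidate builds a network of `cld` valid-convolution blocks (stride 1,
no padding, ReLU, width-2 max-pooling skipped automatically when the feature
map is too short to pool), a flatten, two ReLU dense layers and a 5-way
softmax.  Training is plain minibatch SGD on cross-entropy; forward and
backward passes are written directly on numpy (im2col convolution via
sliding windows).  Defaults: learning rate 0.1, 25 epochs, batch 30, loss
satisfaction threshold 10⁻³ (training stops early when the epoch-mean loss
drops below it).  Weights are He-initialized from the run's seeded
generator, making loss curves bit-reproducible.

Per-piece z-normalization is available but off by default: amplitude is
itself class-discriminative (apnea is *defined* by a > 90 % amplitude
reduction), and standardizing each piece erases that cue — enabling it
measurably hurts separability on this data.

Architectures that cannot be built for the input length, and trainings that
diverge to a non-finite loss, score 0 % with a logged warning, so the
objective is total over the valid space and the optimizer simply discards
such candidates.

## Scaled-down verification conditions

Full-scale runs (HMS 1000, 10 000 iterations, thousands of CNN trainings)
are out of reach of a single-CPU test suite, so optimizer-times-CNN behaviour
is verified on a deliberately small instance, chosen once: 3 subjects × 12
pieces per type at 10 Hz (180 pieces; pool 150 → 120/30, test 30), noise
0.15, space `cld=2`, KS 3–15 (odd), KC 1–12, DLNC 2–32, training 10 epochs.
The noise and the inclusion of very weak architectures (single-kernel
layers, two-neuron dense layers) keep validation rates off the 100 %
ceiling so that the comparison against an equal-budget (30 trainings)
random search is informative.  The comparison statistic is the median best
validation rate over 5 paired seeds; the best-so-far curve of every run is
checked to be non-decreasing.

## Numerical and design notes

* Exact integer cardinality; no floating overflow at any space size.
* Strict-inequality memory updates; equal-rate candidates never displace
  incumbents, and sort ties prefer newer entries for determinism.
* A single master seed spawns independent streams (simulate, split, search,
  train) via `numpy.random.SeedSequence`, so every pipeline output is a pure
  function of its archived config.
* Dataset files are plain delimited text with SHA-256 checksums verified on
  load.
* The grid-baseline command refuses Cartesian products above a configured
  budget, printing the count, instead of silently launching huge runs.
* Headline full-scale figures from the reference study (≈ 96.7 % recognition
  after ≈ 3652 evaluations) depend on non-public recordings and
  thousand-fold larger budgets; this package reproduces the *mechanisms* and
  verifies them at desk scale, not those numbers.
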