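# Methods

## The measurement and its model

A cochlear implant can record the synchronous auditory-nerve response to
one of its own current pulses (an electrically evoked compound action
potential, ECAP) on a neighbouring intracochlear electrode.  Because the
stimulus artifact dwarfs the neural signal, each measurement uses the
forward-masking four-frame paradigm: probe alone (A), masker then probe
(B), masker alone (C) and no stimulus (D).  The combination

    ecap(t) = A(t) − B(t) + C(t) − D(t)

cancels every component shared between frames (both artifacts, the masker
response and the system signature) and leaves the part of the probe
response that the preceding masker suppressed.  The ECAP amplitude is the
voltage difference between the first negative peak (N1) and the following
positive peak (P2).  Collecting this amplitude for every probe electrode
`p` and masker electrode `m` gives the n×n matrix **M**.

The panoramic model explains **M** with two per-electrode vectors: current
spread σ (the SD, in electrode spacings, of a unit-peak Gaussian excitation
profile centred on each electrode, bounded to [1, 6]) and neural health η
(relative responsiveness in [0, 1]).  The excitation pattern of electrode
`e` is the Gaussian row C(e,·) scaled pointwise by η; a forward-masked ECAP
reflects neurons excited by *both* masker and probe, so the predicted
amplitude is the summed pointwise minimum of the two patterns:

    raw(p, m) = Σₓ min(C(p,x)·η(x), C(m,x)·η(x))

The minimum-overlap operator is this package's concrete reading of
"overlap of excitation patterns": the masked population is the one both
pulses recruit.  Predicted and measured matrices are max-normalized before
comparison, so η carries only relative amplitude information (η̂ is
reported both as fitted and max-normalized).  Gaussians are peak-normalized
and truncated at the grid bounds without renormalization; the default grid
is the electrode positions themselves (spacing 1), with an optional linear
oversampling factor under which η is linearly interpolated.

## Acquisition scheduling

The telemetry transfers frames in batches (19-frame buffer by default)
with roughly one second of command upload and one of data download per
batch.  Three redundancies shorten acquisition:

1. **Symmetry**: min-overlap predicts M(p,m) = M(m,p) exactly, so only the
   diagonal plus one triangle is recorded — n(n+1)/2 of n² conditions
   (253 instead of 484 for n = 22).  The triangle side is configurable.
2. **Batch transfer**: packing k conditions into one transaction divides
   the communication overhead by k (75% saving at k = 4).
3. **Frame recycling**: for a fixed probe, the A and D frames are
   identical across maskers; one shared A and one shared D per batch plus
   a B and a C per masker fits ⌊(19 − 2)/2⌋ = 8 ECAPs per batch.

Batches are self-contained (A/D re-recorded per batch, never reused across
batches): this matches the 8-ECAP/19-frame arithmetic and is robust to
drift between transactions.  The time model is
`stimulation = frames × sweeps / rate` plus `batches × (up + down)`
overhead; with 50 sweeps at 80 Hz and 1 s overheads the full-array fast
schedule takes ≈ 7.5 min against ≈ 36 min for the one-condition-per-batch
standard schedule.  The model deliberately ignores vendor-software slack,
so the standard-schedule estimate is a lower bound on observed clinical
times.

## The inversion

`solve_pecap` minimizes the RMSE between the max-normalized measured
matrix and the normalized prediction over (σ, η), using SLSQP (sequential
quadratic programming) under hard bounds σ ∈ [1,6], η ∈ [0,1] and hard
smoothness caps on adjacent differences, |Δσ| ≤ 1.0 and |Δη| ≤ 0.5 per
electrode step (all configurable).  Unrecorded cells are excluded from the
objective; callers mirror half matrices or symmetrize full ones first
(asymmetry beyond 1e-6 relative is rejected).  Multi-start: one
deterministic start (η₀ from the matrix diagonal clipped to [0.05, 1] and
step-limited, σ₀ = 2.0), one coarse-to-fine start (the objective first
minimized on a ~n/3-point linear-interpolation basis, then polished at
full resolution — this suppresses spurious single-electrode dips at the
array edges, where the data constrain η weakly), and seeded random smooth
starts up to `n_starts` (default 5).  The lowest objective wins, ties by
lowest start index; convergence uses ftol 1e-8 and at most 500 iterations
per start.  Non-convergence is reported through `converged=False`, never
an exception.  The η scale is not identified (normalization absorbs it),
so η̂ is compared across fits after max-normalization.

## Error metrics

Matrix comparisons use the normalized cell-wise RMSE in percent,

    ε = f · sqrt(mean((Ma − Mb)²)) / max(Ma, Mb) × 100,

with the normalizer taken over the included cells of both matrices and
f = 1/√2 for split-half (half-sweep) comparisons: halving the sweeps
inflates measurement noise by √2, and the correction restores the
full-sweep error scale.  The symmetry error εsym compares a full matrix
with its transpose-average (M + Mᵀ)/2, which is the Frobenius projection
onto symmetric matrices and the format submitted to the inversion.
Parameter-estimate errors εσ and εη are plain RMS differences, also
expressed as percent of the parameter ranges (5 spacings and 1).  Pooled
within-participant correlations demean each participant's vectors before
pooling; df = pooled N − 2, a declared convention.

## Synthetic data: what it emulates and what it does not

The generator draws smooth ground-truth profiles (bounded random walks,
default σ ∈ [1.5, 4.0] with 0.3-spacing steps, η ∈ [0.3, 1.0] with 0.1
steps — within the solver's smoothness caps by construction), optionally
imposing dead regions (contiguous η floors; these violate the caps at
their edges by design, so the fit can only approximate them).  The
waveform path synthesizes all four frames per condition: a
difference-of-Gaussians ECAP template (N1 at 300 µs, P2 at 650 µs, scaled
so the sampled P2-N1 equals the target amplitude), exponentially decaying
stimulus artifacts that cancel exactly under the four-frame combination,
and white per-sweep recording noise whose trace SD is s/√(sweeps).  The
defaults — 20 kHz sampling, 32-sample traces, 100 µV amplitude scale and
s = 8 µV per sweep — put split-half repeatability errors in the
few-percent-of-maximum range typical of clinical recordings.  Study
designs: full-matrix acquisition as four 12-sweep blocks (48 sweeps, with
reconstructable 24-sweep halves), two independent 50-sweep half-matrix
repeats, and diagonal-only screening; a multiplicative `asymmetry_bias`
can stress the symmetry assumption (default off).  An amplitude-level
path (`noisy_amplitude_matrix`) perturbs model amplitudes with
multiplicative Gaussian noise and is used for large recovery sweeps.

Not emulated: refractory/temporal effects of the 80 pps pulse train,
loudness growth, impedance differences, non-Gaussian or correlated noise,
and any asymmetry mechanism beyond the optional triangle bias.  Passing
tests therefore certify the pipeline's arithmetic and the inversion's
behaviour under the model's own assumptions, not clinical performance.

## Numerical choices and degenerate inputs

Peak search windows default to 100–500 µs (N1) and up to 900 µs (P2,
starting at N1); extremum ties break to the earliest sample.  A
measurement is flagged low-quality below 3× the out-of-window trace SD;
an empty P2 window yields amplitude 0 with the flag set, never a negative
amplitude.  An all-zero matrix, a zero normalizer or an all-zero η raise
degenerate-input errors; a constant matrix fits without exception and
reports its (uninformative) result honestly.  Matrix CSVs round-trip at
full precision (17 significant digits, `float_precision="round_trip"` on
read).

## Problem sizes used in the shipped benchmarks

The recovery and detection benchmarks shipped with the tests use arrays of
8–16 electrodes with 50 seeded runs per condition and 500 replicates for
the sweep-correction experiment — sizes at which the full pipeline runs in
a few minutes while the medians are stable.

## Known limitations

* **Edge ambiguity under noise.**  With ≥ ~5% proportional amplitude
  noise, the RMSE landscape develops near-degenerate minima in which η̂
  dips to zero at an array edge (objective differences ~1e-5 in
  normalized units).  Dead-region localization by the η̂ minimum is
  essentially perfect without noise, ≈ 80% reliable at 2% noise, and
  degrades to ≈ 65–70% at 5% — a property of the objective/constraint
  formulation, not of the optimizer: polishing from the ground truth
  reaches the same or higher objective in the failing cases.
* **Peak-picking nonlinearity.**  Measured P2-N1 amplitudes grow slightly
  sub-linearly with trace noise (extremum statistics), so the √2
  split-half inflation is exact for trace noise but ~6% compressed at the
  amplitude level under the default noise; the sweep-correction
  experiment exposes both an averaging-level and a full-waveform variant.
* The time model's communication term is a two-parameter abstraction;
  real acquisition software adds unmodelled per-condition slack.
* The inversion provides point estimates only; no uncertainty
  quantification.
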