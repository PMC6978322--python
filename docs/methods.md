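# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of the `termcycle` package.  It is written for a
reader who wants to judge what the tests and the acceptance run do and
do not demonstrate.

## Trace model and calibration

A trace is a three-channel record (template DNA, labeled RNAP,
transcript hybridization probe) at one DNA spot, sampled at a regular
frame interval (default 2 s; an optional gap pattern lengthens every
k-th interval to mimic interleaved acquisition of the DNA channel).
The RNAP channel is tied to position through the TIRF evanescent-field
decay: during elongation at constant rate the intensity is a single
exponential `I(t) = I_P e^(−λt) + I_mn`.  The same map, inverted,
converts post-termination intensities to positions.  Assumptions
inherited from the experimental design and kept as-is:

* **Constant elongation rate** per molecule.  Pausing is not modeled;
  a pause during the calibration window would bias `λ` and every
  downstream position.
* **Per-molecule rate heterogeneity.**  Each enzyme has its own
  characteristic rate.  Both the intensity decay constant `λ` (mean
  0.01 s⁻¹, CV 0.3) and the elongation rate `r` (mean 21 bp/s, CV 0.2)
  are lognormal — lognormality is our choice, made to keep rates
  positive; only the existence of molecule-specific rates is an
  experimental fact.  The simulator field `r_mean` exists because the
  intensity–position tie cannot be realized without an elongation
  rate; 21 bp/s makes a 2.1 kbp unit take ~100 s, consistent with the
  calibration worked example (ln-term = 1 at `λ = 0.01 s⁻¹` gives
  exactly 21 bp/s).
* **Template geometry**: promoter at 200 bp, terminator at 2300 bp on
  a 2500 bp contour (a 2.1 kbp transcription unit), tethered at the
  promoter-proximal ("up") or distal ("down") end.  Down-orientation
  records are processed by fitting the elongation window in reversed
  time and sign-flipping the position axis about (z_P, z_T).

The fit is ordinary least squares (`scipy.optimize.curve_fit`), seeded
by a derivative-free heuristic: background from the dimmest frames,
amplitude from the first five frames, rate from a log-linear slope.
The loss is our choice; the experimental description does not state
one.  Elongation windows are an input: the simulator's ground-truth
windows are used in tests, and a probe-interval change-point heuristic
is provided for unlabeled data.  `I_T` is taken from the fitted curve
at the termination time rather than the single noisy frame, which
makes the identity `z(t_T) = z_T` exact (asserted at 10⁻⁶ of the
template length — it is algebra, not an estimate).

Frames at or below background (`I ≤ I_mn`) are masked, never
extrapolated; >50 % masked frames logs a warning.

## Post-termination state model

At termination a molecule is retained with probability `p_retain`
(default 0.87).  Retained molecules alternate between **sliding**
(reflected Brownian steps, variance `2 D Δt`, `D = 3.5 × 10⁴ bp² s⁻¹`)
and **stuck** states.  Per-frame switching probabilities default to
0.005 (mean sojourn ~400 s at 2-s frames), matching the minutes-long
episodes visible in example records; the state entered at termination
is a fair coin.  Dissociation (rate `k_RNAP = 1/1140 s⁻¹` post-
termination) competes with photobleaching (`k_PB = 1/3000 s⁻¹` from
t = 0); only the first event is observable, which is exactly the
additivity `k_obs = k_RNAP + k_PB` the lifetime correction assumes.

A retained molecule may schedule one secondary-initiation episode:
antisense with probability 0.25, else sense with probability 0.02,
after an exponential delay (mean 60 s).  The antisense start position
is drawn just upstream of the terminator (SD 30 bp — the AT-rich
terminator-proximal region), and the episode retraces the intensity
map in reverse with the *same* molecule's `λ` and `r`, which is the
generative counterpart of the observation that sense and subsequent
antisense events on one DNA share a rate.  The probe channel follows
the sense transcript (appearance lagged by a configurable
hybridization delay, default 10 s — the real lag is not known) or, in
antisense-probe mode, turns on when the antisense run-off completes.

## Diffusion estimation and behavior calls

MSD is time-averaged within each window on a regular grid; pairs
spanning acquisition gaps contribute at their true lag and off-grid
frames are dropped.  `D` is slope/2 of a free-intercept line through
the first ten lag points; the intercept absorbs static localization
error.  Negative `D` values are kept in histograms and never classify
as sliding.  Windows are 50 s, advanced one frame at a time
(overlapping); the stride is configurable.

Two facts about this estimator matter for interpretation:

* **Confinement bias.**  On the 2.5 kbp template, `2Dτ` at the fit
  lags is comparable to the `L²/6` saturation, so windowed `D` on
  template-bounded sliding is biased low.  `D_slide` should therefore
  be read as the *generative* step-variance parameter; estimator
  validation (unbiasedness, bimodality) is done on long-DNA walks
  where confinement is negligible.
* **Skew.**  A 50-s window holds few independent displacements, so
  single-window `D̂` scatters widely and skews right; the raw
  histogram peak of the sliding population falls below its mean.  Mode
  locations are therefore extracted as the component means of a
  two-component Gaussian mixture (`motion.histogram_modes`), which is
  unbiased where the raw argmax is not.

Sliding is scored if any window reaches `D ≥ 2.2 × 10⁴ bp² s⁻¹`
(inclusive).  Secondary initiation is scored on the earliest
post-termination monotone intensity episode lasting ≥25 % of the sense
elongation duration with amplitude ≥3× the calibration residual SD —
our reproducible surrogate for a "visible" elongation profile — whose
(time-mirrored where promoter-ward) exponential fit has a rate in the
closed band `[0.002, 0.04] s⁻¹` **and** fit residuals no worse than
1.7× the calibration residual SD (or 2.5 % of the episode amplitude
when the noise floor is tiny; ramp ends are frame-quantized).  The
fit-quality criterion is part of the operationalization: without it,
diffusive sliding excursions that happen to trend monotonically pass
the rate band.  On labeled simulations genuine episodes sit at
residual ratios ≲1.5 and sliding artifacts at ≳1.9.  Antisense and
sense re-initiation are mutually exclusive per episode; the earliest
qualifying episode sets the call.

## Lifetimes, departures, drift

Departure classes use the inclusive 4-s simultaneity threshold (the
maximum interval between consecutive frames); censored RNAP departures
count as "after".  Class fractions carry binomial standard errors
`√(p(1−p)/n)`.

The censored-exponential MLE is the closed form
`k̂ = N_uncensored / Σ durations`; tests verify it against a numeric
likelihood maximizer.  The corrected lifetime `1/(k_obs − k_PB)` gets
a bootstrap SE and a 95 % percentile CI from 1000 joint resamples of
(duration, censored) records, with optional normal propagation of an
externally measured `k_PB` uncertainty.  `k_obs ≤ k_PB` yields a
flagged (infinite) estimate, not an exception.  CI endpoints are order
statistics, so infinite resamples are handled without interpolation.

Boltzmann's constant is the exact SI value expressed as
1.380649 × 10⁻² pN·nm/K.  The bp→nm conversion defaults to the
canonical 0.34 nm/bp rise; the round-number conversion
4 × 10⁴ bp² s⁻¹ → 4 × 10³ nm² s⁻¹ implies ~0.316 nm/bp, and both are
supported through the `rise` argument with neither asserted as the
intended value.

## Rend-seq battery

Coordinates are 0-based half-open internally; wig (1-based) and
bedGraph/BED are converted at I/O and each track carries a convention
tag.  The "10 bp region" for `k_max` is realized as a centered
inclusive ±5 nt window, and the `k_max2` search as ±500 nt inclusive;
whether the original windows were centered or endpoint-inclusive is
not stated, so these choices are fixed here and documented.  Ties
resolve to the leftmost coordinate.  `k_max = 0` leaves `Δ_S`
undefined: such terminators are dropped from peak-height scatters but
kept in distance-profile denominators when their window is fully
inside the genome (avoiding coverage bias).

Peak z-scores use a flank of 50 nt per side excluding the center
±2 nt, with the SD floored at the flank-mean Poisson SD
`√(max(mean, 1))` — the floor keeps flat tracks at z = 0 and guards
against zero-variance flanks.  All three numbers are arguments.  A
vectorized cumulative-sum implementation (`zscore_track`) matches the
per-position function and makes the 100-replicate control affordable.

The distance profile reports, for each signed 200-nt bin out to
±2000 nt (oriented along each terminator's reading direction), the
binomial fraction ± s.e.m. of locations with any opposite-strand 5′
position above z = 12 in the bin window.  Control locations are drawn
uniformly without replacement from positions >700 nt from every
terminator inside runs of ≥3 consecutive same-orientation genes; each
of the 100 replicates re-runs the central-bin measurement, and the
empirical p-value is the fraction of replicates at or above the
terminator-proximal fraction.

TSS information content is `2 − H` bits per position over a ±3 nt
window (reverse-complemented on the minus strand), with the standard
small-sample correction `3/(2 ln2 · n)`.  Position-weight matrices are
emitted as tables; no logo rendering is included.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analysis
assumes: exponential intensity decay with molecule-specific rates,
slide/stick switching with reflected Brownian sliding, mirror-image
antisense ramps reusing the molecule's rate, competing
dissociation/bleaching with acquisition censoring, and Poisson end
counts with planted terminator/antisense spikes on a block-structured
annotation (operon-like runs of 2–5 same-strand genes, ~250 kb
genome).  They do **not** emulate image-level effects (PSFs, spot
detection, drift), transcriptional pausing, peak shadows or coverage
structure of real Rend-seq libraries, or sequence-dependent initiation
preferences beyond optional planted motifs.  Passing tests therefore
demonstrate the correctness and calibration of the *estimators under
the stated model*, not robustness to every artifact of real
recordings.

## Problem sizes and numerics

Tests and the acceptance run use desk-scale sizes chosen to keep the
whole suite in minutes: cohorts of 100–200 molecules at 700 frames,
41 slide/stick walks for the mode study, n = 200 lifetime records with
100 replicate simulations for CI coverage, a ~250 kb genome with 60
terminators and 100 control replicates.  Seeds are explicit
everywhere; identical seeds reproduce outputs bit for bit.  Fit
non-convergence is flagged and downstream operations refuse flagged
fits; degenerate inputs (zero uncensored events, empty windows,
all-censored records, `t_censor = 0`) raise with specific messages.

## Known limitations

* The elongation-window choice dominates calibration quality; the
  probe-interval heuristic starts the window at probe appearance,
  which lags true elongation start and slightly biases `I_P`.
* Windowed-D values on the bounded template underestimate the
  microscopic `D`; quantitative comparisons should use the mixture
  modes on long-DNA simulations or correct for confinement.
* The secondary-initiation screen was tuned for the simulator's noise
  model; heavy-tailed noise or baseline drift in real data would merit
  revisiting the amplitude and fit-quality gates.
* The z-score windowing reproduces a peak-calling convention that is
  configurable precisely because the original convention is defined
  elsewhere; absolute peak counts depend on it, the terminator-vs-
  control contrast much less so.
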