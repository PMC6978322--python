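# termcycle

Quantitative analysis of the **alternative bacterial transcription
cycle**: what happens to RNA polymerase (RNAP) *after* intrinsic
termination.  In single-molecule TIRF experiments, most RNAP molecules
do not leave the DNA when the transcript is released at an intrinsic
terminator.  They remain bound for hundreds of seconds, slide along the
template as a one-dimensional random walk, and frequently re-initiate
transcription — usually in the antisense direction.  Genome-wide,
end-enriched RNA sequencing (Rend-seq) shows the predicted footprint of
this behavior: 5′ ends of antisense transcripts cluster within a few
hundred nucleotides of intrinsic terminators.

This package implements the full analysis chain for both data types,
plus synthetic-data generators with ground truth so every stage is
testable without any experimental downloads.  It is aimed at
single-molecule biophysicists and bacterial-transcription researchers
who want to reproduce, stress-test, or extend this style of analysis.

## The models at the core

**Intensity → position calibration.**  Under TIRF illumination the
evanescent field decays with height, so a labeled RNAP tethered on
surface-anchored DNA dims as it transcribes away from the coverslip.
During steady-state elongation,

    I(t) = I_P · e^(−λt) + I_mn,

with `I_P` the promoter-proximal intensity, `I_mn` the background and
`λ` a per-molecule decay constant.  With a constant elongation rate
`z(t) = r_RNAP · t + z_P` and the measured termination intensity `I_T`,
anchoring at the known promoter and terminator positions gives

    r_RNAP = (z_T − z_P) / [ (1/λ) ln( I_P / (I_T − I_mn) ) ],
    z(I)   = (r_RNAP/λ) ln( I_P / (I − I_mn) ) + z_P,

which converts any post-termination intensity to a position in bp.

**Sliding.**  Post-termination motion is modeled as a bounded 1D random
walk.  Time-averaged MSD curves are computed in overlapping 50-s
windows; `D` is half the slope of a free-intercept line through the
first ten lag points.  A molecule *slid* if any window reaches
`D ≥ 2.2 × 10⁴ bp² s⁻¹`; the windowed-D distribution is bimodal with
modes near 0 (stuck) and ~3.5 × 10⁴ bp² s⁻¹ (sliding).

**Secondary initiation.**  A monotone post-termination intensity ramp
that retraces the elongation profile (mirrored in time for
promoter-ward motion) with a fitted exponential rate in
`[0.002, 0.04] s⁻¹` is scored as antisense (promoter-ward) or sense
re-initiation (promoter-distal).

**Lifetimes.**  Spot survival mixes dissociation and photobleaching,
`k_obs = k_RNAP + k_PB`, right-censored when acquisition stops.  The
censored-exponential MLE is the closed form
`k̂_obs = N_uncensored / Σ durations`; the corrected characteristic
lifetime is `1/(k_obs − k_PB)` with bootstrap errors.

**Drift under force.**  The Einstein–Smoluchowski relation
`D = k_B T v_d / F` predicts how fast an optical-trap force drags a
sliding RNAP along DNA — reconciling second-scale trap observations
with the minutes-long lifetimes seen without force.

**Rend-seq statistics.**  Per terminator, `Δ_S = log₂(k_max)` (peak 3′
sense count in a 10 nt window) and `Δ_AS = log₂(k_max2)` (peak 5′
antisense count within ±500 nt).  Antisense peaks are called at
z-score > 12 against the local flank; a terminator-relative distance
profile (200-nt bins) is compared with 100 replicates of a constrained
random-location control (>700 nt from any terminator, inside runs of
≥3 same-orientation genes).

## Worked example

```bash
python analysis/01_simulate_traces.py 1
python analysis/02_calibrate_positions.py 1
python analysis/03_classify_motion.py 1
python analysis/04_lifetimes_and_drift.py 1
python analysis/05_simulate_rendseq.py 1
python analysis/06_terminator_antisense.py 1
```

The drivers print, among other lines (seed 1):

```
  retained at termination: 0.89 (config p_retain=0.87)
  slid:      0.73 +/- 0.04
  antisense: 0.17 +/- 0.03
post-termination lifetime: 1338 s (95% CI 1007-1884; 93 events, 34 censored; simulator k_RNAP^-1 = 1140 s)
drift velocity at 3 pN, 300 K: 2.90e+03 nm/s; 150 nm traversed in 0.052 s
30/60 terminators flanked by same-orientation genes
7/30 eligible terminators show a strong (z > 12) antisense 5' peak within 500 nt
100 constrained random-location replicates: max central fraction 0.000; empirical p = 0.00 (< 0.01)
```

Reading these: 89 % of simulated molecules keep their RNAP spot after
transcript release (generator truth 87 %); about three quarters of the
retained molecules show at least one 50-s window of sliding; the
censored-MLE lifetime CI covers the simulator's 1140-s dissociation
time; a 3-pN force would drag the sliding state over 150 nm in ~0.05 s;
and on the synthetic genome the strong antisense 5′ peaks sit at
terminators far more often than at matched random control locations.

The same stages are scriptable through a CLI (`termcycle --help`):
`simulate-traces`, `simulate-rendseq`, `calibrate`, `motion`,
`kinetics`, `rendseq`, and `report` for an end-to-end run with a
manifest.

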