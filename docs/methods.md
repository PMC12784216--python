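# Methods

`septrial` simulates and analyzes median-nerve stimulation sessions in
which somatosensory evoked potentials (SEPs) are measured trial by trial
with 19-channel EEG while the effective afferent input is monitored through
the sensory nerve action potential (SNAP, recorded at the finger) and the
compound muscle action potential (CMAP, recorded at the thenar muscle).
This note documents the generative model, the analysis conventions, the
calibration of defaults, and what the synthetic results do and do not show.

## Generative model

### Strength–duration thresholds and recruitment

Excitation thresholds follow the Weiss strength–duration law
`I(t) = b (1 + c/t)` with rheobase `b` (mA) and chronaxie `c` (ms).
Calibration fits the law in charge form (`Q = I t = b(t + c)`, linear in
`t`) through the supplied per-pulse-width target intensities; the default
anchors are the group means 24.2 / 9.5 / 8.3 mA at 0.1 / 0.5 / 1 ms.  These
anchors are *not* exactly Weiss-consistent (the two-point fit through the
0.5 and 1 ms anchors predicts ≈19 mA at 0.1 ms, not 24.2 mA), so the
calibrated subject stores the exact per-pulse-width thresholds as overrides
used by the recruitment model, while the fitted backbone and its residuals
(`weiss_residuals`) remain available for inspection rather than being
hidden or forced.

Response amplitude recruits sigmoidally with intensity:
`amp = max / (1 + exp(-(I - I50)/s))` with scale `s = 0.5` mA and midpoint
`I50 = threshold + 2 s`, so that the first *detectable* response (~10 % of
maximum) sits at the threshold current.  CMAP thresholds sit 0.2 mA above
SNAP thresholds (motor fibers recruit slightly later at these pulse widths),
and CMAP-channel noise scales with `cmap_max / snap_max` so that both
channels have the same detection behavior in units of their own background.

### EMG sweeps

Each sweep spans [-50, 50) ms at 3200 Hz and contains: a decaying stimulus
artifact at t = 0 (time constant 0.25 ms, confined well below the 2 ms
analysis windows); a SNAP wavelet — Gaussian envelope (σ = 1 ms) times a
150 Hz cosine, unit peak at 3.8 ms; a CMAP wavelet (σ = 1.5 ms, 100 Hz
carrier, peak at 6.0 ms); multiplicative trial-to-trial amplitude
variability (CV 0.10); and Gaussian background noise (SD 1.5 a.u. on the
SNAP channel).  The acquisition hardware band (10–1000 Hz) is emulated by
zero-phase filtering the noisy sweep, after which a small quantization-scale
dither is added.

### EEG sessions

Stimulus trains draw inter-stimulus intervals i.i.d. uniform on
1.8–2.2 s (mean rate 0.5 Hz); events are placed on the 300 Hz sampling
grid after a 2 s lead-in.  Each stimulus adds two Gaussian-windowed
components to the focus channel (C4 for left-hand stimulation, C3 for
right): a positive P50 (σ = 10 ms, latency 45 ms) and a negative N70
(σ = 12 ms, latency 80 ms), with amplitudes calibrated per condition to the
group-mean averaged-SEP values (P50: 46.4 / 49.3 / 55.4 a.u.; N70: -39.0 /
-55.1 / -66.9 a.u. at 0.1 / 0.5 / 1 ms).  Hjorth neighbors of the focus
channel receive the component at gain 0.2; other channels receive none.
Per-trial amplitudes vary with CV 0.25 and latencies jitter with SD 3 ms.
Background activity per channel is 1/f noise (exponent 1, SD 58 a.u.) plus
a 10 Hz alpha oscillation (amplitude 24 a.u., random phase per channel) and
a 60 Hz line component (amplitude 8 a.u.); channels are independent.

Under the impaired profile (emulating unilateral afferent damage) the whole
response focus shifts posteriorly to P4, the N70 is scaled to 0.4 of its
calibrated amplitude and the P50 to 0.8 — the contralateral central site
retains no distinguishable response, which is what the topography contrast
test checks.

### Between-subject and between-session structure

Cohort sampling perturbs thresholds by a single shared factor with CV 0.10
(matching the observed between-participant CV of target intensities) and
component amplitudes by a per-component shared gain with CV 0.25 plus a
small (CV 0.05) condition-specific factor.  The shared-gain structure is
deliberate: between-participant amplitude differences are dominated by
factors common to all conditions (electrode coupling, cortical
responsiveness), which preserves each subject's within-condition ordering —
without it, the repeated-measures effect sizes the cohort is calibrated to
produce would be unattainable at realistic noise levels.  A second session
re-scales EEG and EMG amplitudes by independent factors with CV 0.12,
which is what limits test–retest ICC below 1.

Seeding is hierarchical: one master seed spawns per-subject streams
(`numpy` `SeedSequence.spawn`), so subject *k* is bit-identical regardless
of cohort size, and every stage is reproducible from (parameters, seed).

### Ground truth convention

The configured component latencies (3.8 / 6.0 ms EMG, 45 / 80 ms EEG) do
not generally fall on the 3200 / 300 Hz sampling grids, so the truth table
records both the drawn per-trial parameters and the *realized* peaks of the
noiseless component evaluated on the epoch grid under the analysis
conventions (baseline subtraction, half-open windows).  "Noiseless recovery
is exact" therefore means: the analysis returns the realized sampled peak
bit-exactly, which is the strongest statement a discrete pipeline can make;
realized latencies sit within one sample of the configured values.

## Analysis conventions

* **Windows** are half-open `[start, stop)` in ms; a sample at time `t_k =
  k/fs` belongs to the window when `start <= t_k < stop`.  At 300 Hz the
  25–65 ms window holds 12 samples, 55–95 ms holds 12, and the background
  -50–0 ms holds 15.
* **EMG**: band-pass 100–300 Hz (order-2 Butterworth, forward–backward /
  zero phase); background = median of the rectified pooled -50 to -15 ms
  segment, with its SD from the same pool (a per-trial-median variant is
  available); peak = signed maximum in the SNAP [2, 8) ms or CMAP
  [3, 15) ms window (artifact blanked below 2 ms), earliest sample on ties.
* **Target rule**: smallest acquired intensity whose SNAP peak exceeds
  background median + 3 SD in at least 3 of 4 trials, with the CMAP
  meeting the same criterion against its own background.  Absence of a
  qualifying level is a value (None), not an error.
* **Maintenance controller**: a trial is in-band when the CMAP lies within
  ±20 % of its target; two consecutive out-of-band trials in the same
  direction trigger a ±0.1 mA step, and the changed intensity persists
  until another change is required.  The trigger count and direction logic
  are implementation choices (chosen for stability against single-trial
  noise) and are logged per trial.  Delivered intensity never exceeds the
  subject's discomfort limit.
* **EEG**: order-2 Butterworth band-stop 55–65 Hz then band-pass 2–40 Hz,
  both forward–backward (zero-phase; effective order 4).  Bad channels are
  those whose band-passed median absolute deviation exceeds 5× the montage
  median (or is ~0); rejection of the contralateral central analysis
  channel is a hard error.  The surface Laplacian is Hjorth-style
  (channel minus the mean of its available nearest 10–20 neighbors, fixed
  table in `montage.py`, minimum two neighbors).  Epochs span [-50, 300) ms
  with the mean of [-50, 0) subtracted per trial.
* **Averaged path**: trials whose peak-to-peak or RMS on the analysis
  channel exceeds median + 3·(1.4826·MAD) are masked before averaging;
  P50 = maximum of the average in [25, 65) ms, N70 = minimum in [55, 95) ms
  (signed, earliest on ties).
* **Single-trial path**: no trial rejection (mimicking real-time
  constraints); per-trial RMS in the two component windows and the
  background window at the spatially filtered contralateral electrode;
  separability = ROC AUC of component-window RMS against background-window
  RMS, computed by the rank (Mann–Whitney) formulation with explicit 0.5
  tie credit.  One background epoch is drawn per trial and the AUC is the
  pooled unpaired statistic.
* **r² topography**: per channel, a per-trial response statistic is pooled
  over component (label 1) and background (label 0) epochs and the squared
  Pearson correlation with the labels is reported.  The default statistic
  is the signed window extremum (minimum for the N70), with the background
  window trimmed to the same sample count: because baseline correction pins
  the background window's mean to zero while every other window's mean is
  free, a windowed-RMS comparison separates the pools at *every* channel
  under autocorrelated background, flattening the spatial map; the
  length-matched extremum restores a symmetric null.  An `rms` option
  reproduces the single-trial feature convention when the global level (not
  the topography) is of interest.

## Statistics

Sample standard deviations (ddof = 1) are used wherever an SD appears.

* **SNR** = |mean| / SD of per-trial peak values; **CV** = SD / mean.
* **Friedman** test with within-row midranks and the standard tie
  correction; p exact by full enumeration of the `(k!)^n` equally likely
  within-row rank configurations for n ≤ 5 complete rows and k ≤ 3,
  chi-square(k-1) reference otherwise.  **Kendall's w** = χ²/(n(k-1)),
  clipped to [0, 1], attached as the effect size.
* **Wilcoxon signed-rank**, two-sided: zero differences dropped, |d|
  midranked; exact null distribution of the positive-rank sum by dynamic
  programming over doubled ranks for n ≤ 25, tie-corrected normal
  approximation (no continuity correction) beyond.
* **Holm** step-down adjustment, returned in input order.
* **Lilliefors** composite-normality test: KS distance against a normal
  with moment-estimated parameters; p from a seeded Monte-Carlo null table
  (10⁴ replicates per sample size, cached), resolution ≈ 10⁻⁴.
* **ICC(2,1)** (single measurement, absolute agreement, two-way model):
  `(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))` from the two-way
  ANOVA decomposition; 95 % CI by the standard F-based formulas and the
  test of ICC = 0 by `F = MSR/MSE` with (n-1, (n-1)(k-1)) df.  The same
  arithmetic is labelled both "two-way mixed" and "ICC(2,1)" in common
  usage; this estimator matches both descriptions.  Negative estimates
  (no between-subject variance) are reported, not clamped.  Interpretation
  bands: <0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, >0.9 excellent.

## Calibration of defaults

Defaults were fixed once against the generator's own contracts, then
frozen; they are calibrations, not empirical claims about any recording:

* EMG noise (1.5 a.u.) and the recruitment scale (0.5 mA) place the
  detected target intensity within one 0.5 mA acquisition step of the
  calibrated threshold across cohorts and pulse widths.
* EEG background (1/f SD 58, alpha 24, line 8 a.u.), component CV 0.25 and
  latency jitter 3 ms put the cohort-mean single-trial N70 AUC near
  0.79 / 0.82 / 0.85 across the three pulse widths, with the N70 r² at the
  contralateral electrode near 0.2–0.3 and the r² map peaking there for the
  default-calibration subject.

## Problem sizes

The shipped validation suite runs five 12-subject single-session studies
(70 assessment trials per condition, three conditions) for the cohort-level
checks, 10⁴ replicates for the Friedman type-I and Holm family-wise-error
calibrations, and 30 replicates of n = 100 two-session designs for ICC
recovery.  These sizes give stable estimates at interactive runtimes; all
of them are plain function arguments and scale up freely.

## What passing tests show — and what they do not

The synthetic sessions share the statistical *structure* the analysis
assumes: stationary colored background, Gaussian-windowed components with
multiplicative amplitude and additive latency variability, sigmoidal
recruitment, independent channels.  Real recordings violate several of
these: background EEG is nonstationary and spatially correlated (volume
conduction), alpha power waxes and wanes, components are dipolar fields
rather than single-channel injections, artifacts are structured (blinks,
EMG bursts) rather than i.i.d., and habituation/gating can make response
amplitude history-dependent.  Passing the suite therefore demonstrates that
the pipeline recovers known parameters under its stated assumptions and
that the statistics are calibrated — not that the same effect sizes would
be obtained from human data.  No biophysical nerve-membrane model, no
volume-conduction head model, and no habituation dynamics are included;
single trials are exchangeable by construction.

## Known limitations

* EDF is supported for reading real recordings (via MNE, optional extra);
  sessions are written as delimited text + JSON rather than EDF, as no EDF
  writer is available in the supported dependency set.
* The exact-enumeration Friedman path is limited to n ≤ 5, k ≤ 3 by the
  (k!)^n cost; beyond that the chi-square reference is used (its null
  rejection rate at n = 12, k = 3 is verified to sit in [0.04, 0.06]).
* Latency ICCs on synthetic cohorts are often near zero because sampled
  peak latencies quantize to a few grid values (near-zero between-subject
  variance), mirroring — more severely than in real data — the instability
  of latency reliability estimates.
* The maintenance controller is a deliberately simple rule; it is not an
  optimal or adaptive estimator of the recruitment state.
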