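# septrial

Simulation and analysis of **single-trial median-nerve somatosensory evoked
potentials (SEPs)** for clinical neurophysiology and BCI research.

Measuring a cortical response to a *single* nerve stimulus with noninvasive
EEG is hard: the mid-latency SEP components ride on background activity an
order of magnitude larger, so SEPs are classically averaged over hundreds
of trials.  A real-time-compatible alternative combines longer stimulus
pulse widths (0.5–1 ms instead of 0.1 ms), slow jittered stimulation
(0.5 Hz, inter-stimulus intervals uniform on 1.8–2.2 s), and stimulus
intensities anchored to objective peripheral markers — the sensory nerve
action potential (SNAP) at the finger and the compound muscle action
potential (CMAP) at the thenar muscle — rather than subjective thresholds.
`septrial` implements that methodology end to end, together with a seeded
synthetic-session generator so every stage is testable without any
recorded data.

## What it does

* **`septrial.synth`** — generates complete sessions: strength–duration
  (rheobase/chronaxie) thresholds, sigmoidal SNAP/CMAP recruitment, jittered
  stimulus trains, per-trial EMG sweeps (3200 Hz), and 19-channel EEG
  (300 Hz) with embedded P50/N70 components over 1/f + alpha + line-noise
  background — plus per-trial ground truth.
* **`septrial.emg`** — SNAP/CMAP processing: 100–300 Hz zero-phase
  filtering, rectified-background statistics, windowed peak readout,
  recruitment curves (groups of four trials per 0.5 mA step), the target
  rule (smallest intensity with SNAP > background median + 3 SD in ≥3 of 4
  trials and a discernible CMAP), the ±20 % maintenance controller
  (±0.1 mA steps), and charge = pulse width × current.
* **`septrial.eeg`** — 55–65 Hz band-stop + 2–40 Hz band-pass (zero-phase
  Butterworth), bad-channel and bad-trial rejection, Hjorth surface
  Laplacian, [-50, 300) ms epochs with baseline correction, averaged-SEP
  P50/N70 peaks, and r² topography.
* **`septrial.single_trial`** — the real-time-mimicking path: windowed RMS
  features per trial and ROC-AUC separability from background (rank
  formulation, 0.5 tie credit).
* **`septrial.stats`** — SNR (|mean|/SD), CV, tie-corrected Friedman with
  exact small-sample p, Kendall's w = χ²/(n(k−1)), exact Wilcoxon
  signed-rank, Holm adjustment, Monte-Carlo Lilliefors, and ICC(2,1) with
  F-based 95 % confidence intervals.
* **`septrial.report`** — `run_study` simulates a whole cohort
  (recruitment → target detection → maintenance → EEG pipeline → averaged +
  single-trial analysis → group statistics) reproducibly from one seed.

The library is the interface: import it, or start from the narrative
scripts in `examples/` (one per capability).  Real EEG in European Data
Format is read via `septrial.io.read_eeg_edf` (requires the `edf` extra).

## Worked example

`python examples/single_trial_auc.py` simulates one subject calibrated to
the group-mean target intensities, runs 70-trial sessions at each pulse
width through the real-time path, and prints:

```
pulse width   P50 AUC   N70 AUC
    0.1 ms     0.825     0.793
    0.5 ms     0.837     0.824
    1.0 ms     0.853     0.858
```

Each AUC is the probability that a randomly chosen single-trial
component-window RMS exceeds a randomly chosen background-window RMS
(0.5 = inseparable, 1.0 = perfectly separable).  The N70 grows with pulse
width by calibration, so its single-trial separability rises from ~0.79 at
0.1 ms to ~0.86 at 1 ms — the methodological point the package exists to
make quantitative.  `examples/full_study.py` runs a 6-subject, 2-session
cohort and prints the target-intensity table (mean ± SE, CV ≈ 0.10,
charge per condition), the averaged-SEP table, the Friedman/Kendall-w
test on |N70| with Holm-corrected post hocs, and the test–retest ICC(2,1)
grid.

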