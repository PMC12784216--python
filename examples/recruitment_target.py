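"""Acquire a SNAP/CMAP recruitment curve and select the target intensity.

Ramps the stimulus in 0.5 mA steps (four trials per step), band-pass
filters the sweeps (100-300 Hz), builds the recruitment curves, and applies
the target rule: the smallest intensity whose SNAP exceeds background
median + 3 SD in at least 3 of 4 trials, with a discernible CMAP.
"""

import numpy as np

from septrial import emg, synth

subject = synth.calibrate_subject(synth.TABLE_TARGET_INTENSITY)
pulse_width = 0.5
rng = np.random.default_rng(3)

rows_snap, rows_cmap, intensities = [], [], []
for level in np.arange(5.0, 12.5, 0.5):
    for _ in range(4):
        snap, cmap, _ = synth.synth_emg_trial(level, pulse_width, subject, seed=rng)
        rows_snap.append(snap)
        rows_cmap.append(cmap)
        intensities.append(level)

fs = synth.EMG_FS
snap_ep = emg.EmgEpochs(emg.filter_emg(np.asarray(rows_snap), fs), fs=fs,
                        intensities=np.asarray(intensities))
cmap_ep = emg.EmgEpochs(emg.filter_emg(np.asarray(rows_cmap), fs), fs=fs,
                        intensities=np.asarray(intensities))
snap_curve = emg.build_recruitment_curve(snap_ep, emg.SNAP_WINDOW_MS)
cmap_curve = emg.build_recruitment_curve(cmap_ep, emg.CMAP_WINDOW_MS)
target = emg.detect_target_intensity(snap_curve, cmap_curve)

print(f"pulse width {pulse_width} ms; calibrated threshold "
      f"{subject.threshold('snap', pulse_width):.1f} mA")
print(f"SNAP background: median {snap_curve.background_median:.2f}, "
      f"SD {snap_curve.background_sd:.2f} (criterion = median + 3 SD)")
for lv, mean in zip(snap_curve.intensities, snap_curve.means):
    marker = "  <- target" if target is not None and lv == target else ""
    print(f"  {lv:5.1f} mA: mean SNAP peak {mean:6.2f} a.u.{marker}")
print(f"target intensity: {target} mA; charge "
      f"{emg.compute_charge(target, pulse_width):.2e} C")
# The detected target should sit within one 0.5 mA step of the calibrated
# threshold; the charge at (9.5 mA, 0.5 ms) is 4.75e-06 C.
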