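"""Maintain effective afferent excitation during an assessment run.

Runs the closed-loop +/-20 % maintenance controller against a subject whose
responses sag by 30 % mid-run (emulating electrode drift): two consecutive
out-of-band trials in the same direction trigger a 0.1 mA intensity step.
"""

from septrial import emg, synth

subject = synth.calibrate_subject(synth.TABLE_TARGET_INTENSITY)
pw = 1.0
target = subject.threshold("snap", pw)
target_snap = synth.recruitment_amplitude(target, pw, "snap", subject)
target_cmap = synth.recruitment_amplitude(target, pw, "cmap", subject)


def respond(intensity, trial):
    sag = 0.70 if trial >= 20 else 1.0   # 30 % response sag from trial 20 on
    return (sag * synth.recruitment_amplitude(intensity, pw, "snap", subject),
            sag * synth.recruitment_amplitude(intensity, pw, "cmap", subject))


log = emg.monitor_assessment(respond, target_snap, target_cmap,
                             start_intensity=target, n_trials=70,
                             discomfort_limit=subject.discomfort_limit)
tbl = log.table
adjusted = tbl[tbl["adjustment_mA"] != 0]
print(f"target CMAP {target_cmap:.1f} a.u., band +/-20% "
      f"= [{0.8 * target_cmap:.1f}, {1.2 * target_cmap:.1f}]")
print(f"trials out of band: {(~tbl['in_band']).sum()} of {len(tbl)}")
print(f"adjustments issued: {log.n_adjustments} "
      f"(all +0.1 mA: {set(adjusted['adjustment_mA'].round(10))})")
print(f"intensity: start {tbl['intensity_mA'].iloc[0]:.1f} mA "
      f"-> end {tbl['intensity_mA'].iloc[-1]:.1f} mA")
print(f"last 10 trials back in band: {tbl['in_band'].tail(10).all()}")
# The controller steps the current up until the CMAP re-enters the band,
# then holds, mirroring how an experimenter maintains afferent input.
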