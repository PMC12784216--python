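"""Simulate one stimulation session and save it as plain-text artifacts.

Builds a subject calibrated to the group-mean target intensities, generates
a 70-trial assessment run at the 1 ms pulse width (EEG + per-trial EMG +
ground truth), and writes it to ./scratch_session/.
"""

from septrial import io, synth

subject = synth.calibrate_subject(synth.TABLE_TARGET_INTENSITY)
protocol = synth.StimulationProtocol(n_trials=70)
session = synth.synth_eeg_session(subject, protocol, pulse_width=1.0, seed=7)

out = io.write_session(session, "scratch_session")
print(f"EEG: {session.eeg.data.shape[0]} channels x {session.eeg.data.shape[1]} samples "
      f"at {session.eeg.fs:.0f} Hz")
print(f"EMG sweeps: {session.emg_snap.shape} at {session.emg_fs:.0f} Hz")
print(f"events: {len(session.events)} stimuli, first at "
      f"{session.events['onset_s'].iloc[0]:.2f} s, "
      f"intensity {session.events['intensity_mA'].iloc[0]:.1f} mA")
print(f"truth: per-trial component amplitudes/latencies, e.g. trial 0 N70 = "
      f"{session.truth['n70_amp'].iloc[0]:.1f} a.u. at "
      f"{session.truth['n70_lat'].iloc[0]:.1f} ms")
print(f"written to {out}/")
# The truth table is what every downstream analysis stage is validated
# against; the EEG/EMG tables are what the analysis stages actually see.
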