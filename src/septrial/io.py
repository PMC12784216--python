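"""Session and table I/O.

Synthetic sessions are serialized as plain-text artifacts: EEG and EMG
matrices as delimited tables and events/truth as CSV, with a small JSON
manifest tying them together.  A reader entry point for real recordings in
European Data Format (EDF) with event annotations is provided through MNE
(imported lazily; install the ``edf`` extra to use it).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import EegRecording

__all__ = ["write_session", "read_session", "read_eeg_edf"]


def write_session(session, out_dir) -> Path:
    """Write a SyntheticSession as delimited text + JSON manifest; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "eeg.tsv", session.eeg.data.T, delimiter="\t",
               header="\t".join(session.eeg.labels), comments="")
    np.savetxt(out / "emg_snap.tsv", session.emg_snap, delimiter="\t")
    np.savetxt(out / "emg_cmap.tsv", session.emg_cmap, delimiter="\t")
    session.events.to_csv(out / "events.csv", index=False)
    session.truth.to_csv(out / "truth.csv", index=False)
    manifest = {
        "eeg_fs": session.eeg.fs,
        "emg_fs": session.emg_fs,
        "labels": session.eeg.labels,
        "pulse_width_ms": session.pulse_width,
        "focus_channel": session.focus_channel,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_session(in_dir):
    """Read back a session directory written by :func:`write_session`.

    Returns ``(EegRecording, emg_snap, emg_cmap, events, truth, manifest)``.
    """
    p = Path(in_dir)
    manifest = json.loads((p / "manifest.json").read_text())
    eeg_tbl = pd.read_csv(p / "eeg.tsv", sep="\t")
    events = pd.read_csv(p / "events.csv")
    truth = pd.read_csv(p / "truth.csv")
    rec = EegRecording(data=eeg_tbl.to_numpy().T, fs=manifest["eeg_fs"],
                       labels=list(eeg_tbl.columns),
                       events=events["sample"].to_numpy())
    emg_snap = np.loadtxt(p / "emg_snap.tsv", delimiter="\t", ndmin=2)
    emg_cmap = np.loadtxt(p / "emg_cmap.tsv", delimiter="\t", ndmin=2)
    return rec, emg_snap, emg_cmap, events, truth, manifest


def read_eeg_edf(path, event_annotation_prefix: str | None = None) -> EegRecording:
    """Read an EDF recording with stimulus events from its annotation track.

    Annotations whose description starts with ``event_annotation_prefix``
    (all annotations when None) become stimulus events.  Requires MNE.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    onsets = []
    for ann in raw.annotations:
        desc = str(ann["description"])
        if event_annotation_prefix is None or desc.startswith(event_annotation_prefix):
            onsets.append(int(round(ann["onset"] * raw.info["sfreq"])))
    keep = [i for i, name in enumerate(raw.ch_names)]
    return EegRecording(data=data[keep], fs=float(raw.info["sfreq"]),
                        labels=[n.replace("EEG ", "").strip() for n in raw.ch_names],
                        events=np.asarray(sorted(onsets), dtype=int))
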