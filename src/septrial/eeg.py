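"""EEG preprocessing, epoching, averaged-SEP extraction and r² topography.

The processing chain mirrors a real-time-capable evoked-potential pipeline:
bad-channel removal, 55–65 Hz band-stop plus 2–40 Hz band-pass (zero-phase,
second-order Butterworth prototypes), Hjorth surface-Laplacian spatial
filtering, epoching to [-50, 300) ms around each stimulus with per-trial
baseline correction over [-50, 0) ms, and peak readout of the mid-latency
P50 (maximum in [25, 65) ms) and N70 (minimum in [55, 95) ms) components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import montage

__all__ = [
    "EegRecording",
    "EegEpochs",
    "SepPeaks",
    "AnalysisChannelLost",
    "reject_bad_channels",
    "preprocess_eeg",
    "laplacian",
    "laplacian_montage",
    "epoch_and_baseline",
    "reject_bad_trials",
    "average_sep",
    "topography_r2",
]

P50_WINDOW_MS = (25.0, 65.0)
N70_WINDOW_MS = (55.0, 95.0)
BASELINE_MS = (-50.0, 0.0)
EPOCH_MS = (-50.0, 300.0)


class AnalysisChannelLost(RuntimeError):
    """The contralateral central analysis channel was rejected."""


@dataclass
class EegRecording:
    """Continuous multichannel EEG with stimulus event markers.

    ``data`` is channels x samples; ``events`` holds stimulus onset sample
    indices.  Channel labels are 10-20 names (classic aliases accepted).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    events: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = [montage.canonical(l) for l in self.labels]
        self.events = np.asarray(self.events, dtype=int)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be channels x samples matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.events.size and (self.events.min() < 0
                                 or self.events.max() >= self.data.shape[1]):
            raise ValueError("event indices must lie within the record")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.labels.index(montage.canonical(name))]


@dataclass
class EegEpochs:
    """Trial-locked epochs: trials x channels x samples in [-50, 300) ms."""

    data: np.ndarray
    fs: float
    labels: list[str]
    window_ms: tuple[float, float] = EPOCH_MS
    baseline_ms: tuple[float, float] = BASELINE_MS
    mask: np.ndarray = field(default=None)   # True = rejected
    dropped_events: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.data.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.data.shape[0],):
            raise ValueError("mask length must equal the number of trials")
        if not (self.window_ms[0] <= self.baseline_ms[0]
                and self.baseline_ms[1] <= self.window_ms[1]):
            raise ValueError("baseline window must lie inside the epoch window")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        i0 = int(round(self.window_ms[0] * self.fs / 1000.0))
        return (np.arange(self.data.shape[2]) + i0) / self.fs * 1000.0

    def window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for a half-open [start, stop) window in ms."""
        t = self.times_ms
        m = (t >= window_ms[0]) & (t < window_ms[1])
        if not m.any():
            raise ValueError(f"window {window_ms} lies outside the epoch")
        return m

    def channel_index(self, name: str) -> int:
        return self.labels.index(montage.canonical(name))


@dataclass
class SepPeaks:
    """Averaged-SEP component peaks at the analysis channel (signed amplitudes)."""

    p50_amp: float
    n70_amp: float
    p50_lat: float
    n70_lat: float
    channel: str


def preprocess_eeg(recording: EegRecording,
                   notch_band=(55.0, 65.0),
                   bandpass=(2.0, 40.0)) -> EegRecording:
    """Zero-phase band-stop (55–65 Hz) then band-pass (2–40 Hz) filtering.

    Both stages use order-2 Butterworth prototypes applied forward-backward
    (effective order 4, zero phase).
    """
    nyq = recording.fs / 2.0
    for edge in (*notch_band, *bandpass):
        if edge >= nyq:
            raise ValueError(f"filter edge {edge} Hz >= Nyquist {nyq} Hz")
    sos_stop = sps.butter(2, notch_band, btype="bandstop", fs=recording.fs, output="sos")
    sos_pass = sps.butter(2, bandpass, btype="bandpass", fs=recording.fs, output="sos")
    out = sps.sosfiltfilt(sos_pass, sps.sosfiltfilt(sos_stop, recording.data, axis=1),
                          axis=1)
    return EegRecording(data=out, fs=recording.fs, labels=list(recording.labels),
                        events=recording.events.copy())


def reject_bad_channels(recording: EegRecording, k: float = 5.0,
                        protect: tuple[str, ...] = ("C3", "C4")):
    """Remove channels with outlying robust amplitude or near-zero variance.

    A channel is rejected when the median absolute deviation (MAD) of its
    band-passed trace exceeds ``k`` times the montage-median MAD, or when
    its MAD is effectively zero (flat channel).  Raises
    :class:`AnalysisChannelLost` if a protected analysis channel (C3/C4)
    would be rejected.  Returns ``(recording_without_bad, rejected_labels)``.
    """
    if recording.n_channels < 8:
        raise ValueError("need at least 8 channels for robust rejection")
    filt = preprocess_eeg(recording)
    med = np.median(filt.data, axis=1, keepdims=True)
    mads = np.median(np.abs(filt.data - med), axis=1)
    montage_med = np.median(mads)
    scale = montage_med if montage_med > 0 else 1.0
    bad = (mads > k * scale) | (mads < 1e-12 * scale) | (mads == 0)
    rejected = [recording.labels[i] for i in np.nonzero(bad)[0]]
    lost = [ch for ch in rejected if ch in {montage.canonical(p) for p in protect}]
    if lost:
        raise AnalysisChannelLost(f"analysis channel(s) rejected: {lost}")
    keep = ~bad
    out = EegRecording(data=recording.data[keep], fs=recording.fs,
                       labels=[l for l, k_ in zip(recording.labels, keep) if k_],
                       events=recording.events.copy())
    return out, rejected


def laplacian(recording: EegRecording, channel: str) -> np.ndarray:
    """Hjorth surface Laplacian: channel minus the mean of its available neighbors."""
    channel = montage.canonical(channel)
    if channel not in montage.NEIGHBORS:
        raise ValueError(f"no neighbor table entry for channel {channel!r}")
    present = set(recording.labels)
    nbrs = [n for n in montage.NEIGHBORS[channel] if n in present]
    if channel not in present:
        raise ValueError(f"channel {channel!r} not in recording")
    if len(nbrs) < 2:
        raise ValueError(f"channel {channel!r} has fewer than 2 neighbors available")
    nbr_mean = np.mean([recording.channel(n) for n in nbrs], axis=0)
    return recording.channel(channel) - nbr_mean


def laplacian_montage(recording: EegRecording) -> EegRecording:
    """Apply the Hjorth Laplacian to every channel with >= 2 available neighbors.

    Channels with fewer than two available neighbors are left referential.
    """
    rows = []
    for ch in recording.labels:
        try:
            rows.append(laplacian(recording, ch))
        except ValueError:
            rows.append(recording.channel(ch))
    return EegRecording(data=np.asarray(rows), fs=recording.fs,
                        labels=list(recording.labels), events=recording.events.copy())


def epoch_and_baseline(recording: EegRecording,
                       events: np.ndarray | None = None,
                       window_ms: tuple[float, float] = EPOCH_MS,
                       baseline_ms: tuple[float, float] = BASELINE_MS) -> EegEpochs:
    """Cut [-50, 300) ms epochs and subtract the per-trial baseline mean.

    Events too close to the record edges are dropped and listed in
    ``dropped_events``.  After correction the mean over the baseline window
    is zero to numerical precision for every trial and channel.
    """
    if events is None:
        events = recording.events
    events = np.asarray(events, dtype=int)
    i0 = int(round(window_ms[0] * recording.fs / 1000.0))
    i1 = int(round(window_ms[1] * recording.fs / 1000.0))
    n = recording.data.shape[1]
    keep, dropped = [], []
    for e in events:
        (keep if (e + i0 >= 0 and e + i1 <= n) else dropped).append(int(e))
    data = np.stack([recording.data[:, e + i0:e + i1] for e in keep]) if keep else \
        np.zeros((0, recording.n_channels, i1 - i0))
    ep = EegEpochs(data=data, fs=recording.fs, labels=list(recording.labels),
                   window_ms=window_ms, baseline_ms=baseline_ms,
                   dropped_events=dropped)
    if ep.n_trials:
        bl = ep.window_mask(baseline_ms)
        ep.data -= ep.data[:, :, bl].mean(axis=2, keepdims=True)
    return ep


def reject_bad_trials(epochs: EegEpochs, channel: str, k: float = 3.0) -> EegEpochs:
    """Mask trials with outlying peak-to-peak or RMS amplitude on the analysis channel.

    The cut is median + k * 1.4826 * MAD across trials for either statistic.
    Used only in the averaged-SEP path; the single-trial path bypasses trial
    denoising to mimic real-time constraints.
    """
    if epochs.n_trials < 10:
        raise ValueError("need at least 10 trials for robust trial rejection")
    x = epochs.data[:, epochs.channel_index(channel), :]
    ptp = x.max(axis=1) - x.min(axis=1)
    rms = np.sqrt((x ** 2).mean(axis=1))
    mask = np.zeros(epochs.n_trials, dtype=bool)
    for stat in (ptp, rms):
        med = np.median(stat)
        mad = np.median(np.abs(stat - med))
        mask |= stat > med + k * 1.4826 * mad
    if mask.mean() > 0.5:
        warnings.warn("more than 50% of trials masked; proceeding", RuntimeWarning)
    return EegEpochs(data=epochs.data, fs=epochs.fs, labels=list(epochs.labels),
                     window_ms=epochs.window_ms, baseline_ms=epochs.baseline_ms,
                     mask=mask, dropped_events=list(epochs.dropped_events))


def average_sep(epochs: EegEpochs, channel: str,
                p50_window_ms: tuple[float, float] = P50_WINDOW_MS,
                n70_window_ms: tuple[float, float] = N70_WINDOW_MS):
    """Average the unmasked trials and read out the P50/N70 peaks.

    P50 is the maximum of the averaged trace in [25, 65) ms, N70 the
    minimum in [55, 95) ms; amplitudes are signed and latencies taken at
    the extremum (earliest sample on ties).  Returns ``(avg, SepPeaks)``.
    """
    keep = ~epochs.mask
    if not keep.any():
        raise ValueError("no unmasked trials to average")
    avg = epochs.data[keep, epochs.channel_index(channel), :].mean(axis=0)
    t = epochs.times_ms
    w50 = epochs.window_mask(p50_window_ms)
    w70 = epochs.window_mask(n70_window_ms)
    i50 = int(np.argmax(avg[w50]))
    i70 = int(np.argmin(avg[w70]))
    peaks = SepPeaks(
        p50_amp=float(avg[w50][i50]), n70_amp=float(avg[w70][i70]),
        p50_lat=float(t[w50][i50]), n70_lat=float(t[w70][i70]),
        channel=montage.canonical(channel),
    )
    return avg, peaks


def _rms(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=axis))


def label_r2(values, labels) -> float:
    """Squared Pearson correlation between responses and their 0/1 labels.

    Zero-variance input on either side yields 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.ptp(values) == 0 or np.ptp(labels) == 0:
        return 0.0
    r = np.corrcoef(values, labels)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def topography_r2(epochs: EegEpochs,
                  component_window_ms: tuple[float, float],
                  background_window_ms: tuple[float, float] = BASELINE_MS,
                  statistic: str = "min") -> dict[str, float]:
    """Per-channel r² separating component-window from background-window responses.

    For each channel a per-trial response ``statistic`` ('min' for negative
    components such as the N70, 'max' for positive ones, or 'rms') is pooled
    over the component window (label 1) and the background window (label 0),
    and the squared Pearson correlation between values and labels is
    computed.  A signed extremum is the default response measure: it is the
    same per-trial quantity the averaged-SEP peak readout uses, and it
    keeps the spatial contrast of the map (windowed RMS is systematically
    larger in any free window than in the baseline window — whose mean the
    correction step pins to zero — so it separates the pools at every
    channel under autocorrelated background, flattening the topography).
    Zero-variance pools yield r² = 0.  Returns ``{channel: r2}``.
    """
    stat_fn = {"min": lambda x: x.min(axis=1),
               "max": lambda x: x.max(axis=1),
               "rms": lambda x: _rms(x)}.get(statistic)
    if stat_fn is None:
        raise ValueError(f"statistic must be 'min', 'max' or 'rms', got {statistic!r}")
    wc = epochs.window_mask(component_window_ms)
    wb = epochs.window_mask(background_window_ms)
    if statistic in ("min", "max") and wb.sum() > wc.sum():
        # Extrema grow with window length; trim the background to the same
        # number of samples (trailing portion) so the null is symmetric.
        idx = np.nonzero(wb)[0][-int(wc.sum()):]
        wb = np.zeros_like(wb)
        wb[idx] = True
    labels01 = np.concatenate([np.ones(epochs.n_trials), np.zeros(epochs.n_trials)])
    out: dict[str, float] = {}
    for i, ch in enumerate(epochs.labels):
        comp = stat_fn(epochs.data[:, i, wc])
        bg = stat_fn(epochs.data[:, i, wb])
        out[ch] = label_r2(np.concatenate([comp, bg]), labels01)
    return out
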