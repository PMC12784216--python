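"""SNAP/CMAP processing: filtering, epoching, recruitment curves, target
intensity selection, assessment-run maintenance, and charge arithmetic.

Conventions: sweeps span [-50, 50) ms at 3200 Hz relative to stimulus onset;
peak responses are the signed maximum within investigator-set windows
(defaults bracket the expected SNAP latency near 3.8 ms and CMAP latency
near 6 ms, with the stimulation artifact blanked below 2 ms); background is
the median of the rectified pre-stimulus segment [-50, -15) ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EmgEpochs",
    "RecruitmentCurve",
    "AssessmentLog",
    "SNAP_WINDOW_MS",
    "CMAP_WINDOW_MS",
    "filter_emg",
    "background_level",
    "peak_response",
    "build_recruitment_curve",
    "detect_target_intensity",
    "monitor_assessment",
    "compute_charge",
]

SNAP_WINDOW_MS = (2.0, 8.0)
CMAP_WINDOW_MS = (3.0, 15.0)
BACKGROUND_WINDOW_MS = (-50.0, -15.0)


@dataclass
class EmgEpochs:
    """Stimulus-locked EMG sweeps: trials x samples, window [-50, 50) ms."""

    data: np.ndarray
    fs: float = 3200.0
    window_ms: tuple[float, float] = (-50.0, 50.0)
    intensities: np.ndarray | None = None   # per-trial delivered current (mA)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not (self.window_ms[0] <= 0.0 < self.window_ms[1]):
            raise ValueError("epoch window must contain t = 0")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
            if self.intensities.shape != (self.data.shape[0],):
                raise ValueError("intensities must have one value per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        i0 = int(round(self.window_ms[0] * self.fs / 1000.0))
        return (np.arange(self.data.shape[1]) + i0) / self.fs * 1000.0

    def window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        t = self.times_ms
        m = (t >= window_ms[0]) & (t < window_ms[1])
        if not m.any():
            raise ValueError(f"window {window_ms} lies outside the epoch")
        return m


@dataclass
class RecruitmentCurve:
    """Per-intensity peak responses (acquired in groups of up to four trials)."""

    intensities: np.ndarray                  # mA, strictly increasing
    trial_peaks: list[np.ndarray]            # per intensity, per-trial peaks
    means: np.ndarray                        # per-intensity mean peak response
    background_median: float
    background_sd: float
    target_intensity: float | None = None
    underfilled: list[float] = field(default_factory=list)  # levels with < 4 trials

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if np.any(np.diff(self.intensities) <= 0):
            raise ValueError("intensities must be strictly increasing")


@dataclass
class AssessmentLog:
    """Per-trial maintenance record of an assessment run."""

    table: pd.DataFrame     # trial, snap, cmap, intensity_mA, in_band, adjustment_mA
    target_snap: float
    target_cmap: float
    band: float

    @property
    def n_adjustments(self) -> int:
        return int((self.table["adjustment_mA"] != 0).sum())


def filter_emg(trace: np.ndarray, fs: float,
               band: tuple[float, float] = (100.0, 300.0)) -> np.ndarray:
    """Zero-phase 100–300 Hz band-pass (order-2 Butterworth, forward-backward)."""
    if fs < 800.0:
        raise ValueError(f"sampling rate {fs} Hz too low for the {band} Hz band")
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(trace, dtype=float), axis=-1)


def background_level(epochs: EmgEpochs,
                     window_ms: tuple[float, float] = BACKGROUND_WINDOW_MS,
                     per_trial: bool = False) -> tuple[float, float]:
    """Background statistics from the rectified pre-stimulus segment.

    Default: pool |x| over the [-50, -15) ms window across all trials and
    return (median, SD) of the pool.  With ``per_trial=True`` the median is
    taken per trial first and the statistics summarize the per-trial
    medians across trials.
    """
    m = epochs.window_mask(window_ms)
    rect = np.abs(epochs.data[:, m])
    if per_trial:
        med_per_trial = np.median(rect, axis=1)
        return float(np.median(med_per_trial)), float(np.std(med_per_trial, ddof=1))
    pool = rect.ravel()
    return float(np.median(pool)), float(pool.std(ddof=1)) if pool.size > 1 else 0.0


def peak_response(epochs: EmgEpochs, window_ms: tuple[float, float],
                  polarity: str = "max"):
    """Per-trial peak amplitude and latency within a half-open window.

    ``polarity`` is 'max' (signed maximum; the default peak convention),
    'min', or 'absmax'.  Ties resolve to the earliest latency.  Returns
    ``(amplitudes, latencies_ms)``.
    """
    m = epochs.window_mask(window_ms)
    x = epochs.data[:, m]
    t = epochs.times_ms[m]
    if polarity == "max":
        idx = np.argmax(x, axis=1)
    elif polarity == "min":
        idx = np.argmin(x, axis=1)
    elif polarity == "absmax":
        idx = np.argmax(np.abs(x), axis=1)
    else:
        raise ValueError(f"polarity must be 'max', 'min' or 'absmax', got {polarity!r}")
    rows = np.arange(x.shape[0])
    return x[rows, idx], t[idx]


def build_recruitment_curve(epochs: EmgEpochs,
                            response_window_ms: tuple[float, float] = SNAP_WINDOW_MS,
                            polarity: str = "max",
                            trials_per_step: int = 4) -> RecruitmentCurve:
    """Group per-trial peak responses by stimulation intensity and average.

    Epochs must carry per-trial intensities.  Levels with fewer than
    ``trials_per_step`` trials are retained and flagged in ``underfilled``.
    """
    if epochs.intensities is None:
        raise ValueError("epochs must carry per-trial intensities")
    levels = np.unique(epochs.intensities)
    if levels.size < 2:
        raise ValueError("need at least two intensity levels")
    peaks, _ = peak_response(epochs, response_window_ms, polarity)
    bg_med, bg_sd = background_level(epochs)
    groups, means, underfilled = [], [], []
    for lv in levels:
        g = peaks[epochs.intensities == lv]
        groups.append(g)
        means.append(g.mean())
        if g.size < trials_per_step:
            underfilled.append(float(lv))
    return RecruitmentCurve(intensities=levels, trial_peaks=groups,
                            means=np.asarray(means), background_median=bg_med,
                            background_sd=bg_sd, underfilled=underfilled)


def _level_detected(peaks: np.ndarray, bg_median: float, bg_sd: float,
                    min_trials: int) -> bool:
    return int((peaks > bg_median + 3.0 * bg_sd).sum()) >= min_trials


def detect_target_intensity(snap_curve: RecruitmentCurve,
                            cmap_curve: RecruitmentCurve | None = None,
                            min_trials: int = 3) -> float | None:
    """Smallest intensity with a consistently discernible SNAP (and CMAP).

    A level qualifies when the SNAP peak exceeds background median + 3 SD in
    at least ``min_trials`` of its trials and, when a CMAP curve is given,
    the CMAP peak meets the same criterion against its own background.
    Returns ``None`` when no level qualifies (absence is a value).
    """
    cmap_by_level = {}
    if cmap_curve is not None:
        cmap_by_level = dict(zip(cmap_curve.intensities, cmap_curve.trial_peaks))
    for lv, peaks in zip(snap_curve.intensities, snap_curve.trial_peaks):
        if not _level_detected(peaks, snap_curve.background_median,
                               snap_curve.background_sd, min_trials):
            continue
        if cmap_curve is not None:
            if lv not in cmap_by_level:
                continue
            if not _level_detected(cmap_by_level[lv], cmap_curve.background_median,
                                   cmap_curve.background_sd, min_trials):
                continue
        return float(lv)
    return None


def monitor_assessment(trials: Callable[[float, int], tuple[float, float]] | Iterable,
                       target_snap: float, target_cmap: float,
                       start_intensity: float,
                       n_trials: int = 70,
                       band: float = 0.2,
                       step: float = 0.1,
                       discomfort_limit: float | None = None) -> AssessmentLog:
    """Maintain the CMAP (and thereby the SNAP) within ±band of its target.

    ``trials`` is either a callable ``(intensity, trial_index) -> (snap, cmap)``
    (closed loop against a response model or hardware proxy) or an iterable
    of pre-recorded ``(snap, cmap)`` pairs (open loop; adjustments are still
    logged as they would have been issued).  The controller issues a ±``step``
    mA change after two consecutive out-of-band trials in the same direction,
    and the adjusted intensity persists until another change is required.
    Delivered intensity never exceeds ``discomfort_limit``.
    """
    if target_snap <= 0 or target_cmap <= 0:
        raise ValueError("targets must be positive")
    closed_loop = callable(trials)
    if not closed_loop:
        trials = list(trials)
        n_trials = len(trials)
    lo, hi = target_cmap * (1 - band), target_cmap * (1 + band)
    intensity = float(start_intensity)
    run_low = run_high = 0
    rows = []
    for k in range(n_trials):
        snap, cmap = trials(intensity, k) if closed_loop else trials[k]
        in_band = lo <= cmap <= hi
        adjustment = 0.0
        if in_band:
            run_low = run_high = 0
        elif cmap < lo:
            run_low, run_high = run_low + 1, 0
            if run_low >= 2:
                adjustment = step
                run_low = 0
        else:
            run_high, run_low = run_high + 1, 0
            if run_high >= 2:
                adjustment = -step
                run_high = 0
        rows.append({"trial": k, "snap": snap, "cmap": cmap,
                     "intensity_mA": intensity, "in_band": in_band,
                     "adjustment_mA": adjustment})
        intensity = round(intensity + adjustment, 10)
        if discomfort_limit is not None:
            intensity = min(intensity, discomfort_limit)
    return AssessmentLog(table=pd.DataFrame(rows), target_snap=target_snap,
                         target_cmap=target_cmap, band=band)


def compute_charge(current_ma: float, pulse_width_ms: float) -> float:
    """Delivered charge in coulombs: pulse width (s) times current (A)."""
    if current_ma < 0 or pulse_width_ms < 0:
        raise ValueError("current and pulse width must be non-negative")
    return (current_ma * 1e-3) * (pulse_width_ms * 1e-3)
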