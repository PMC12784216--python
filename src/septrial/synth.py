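"""Seeded generation of synthetic median-nerve stimulation sessions.

A session emulates what the acquisition stack records during one
pulse-width condition: per-trial EMG sweeps containing a stimulus artifact,
an antidromic sensory nerve action potential (SNAP, peak near 3.8 ms) and a
compound muscle action potential (CMAP, peak near 6 ms) whose amplitudes
follow a sigmoidal recruitment over intensity with strength-duration
(pulse-width-dependent) thresholds; and 19-channel EEG at 300 Hz in which
each stimulus adds a positive mid-latency component (P50) and a later
negative one (N70) at the contralateral central electrode, on top of a
1/f + alpha + line-noise background.

Ground truth is carried alongside every session so the analysis stages can
be validated without any recorded data.  Truth stores both the *drawn*
per-trial component parameters and the *realized* peaks of the noiseless
component on the sampling grid (the configured latencies do not generally
fall on the 300/3200 Hz grids, so the realized sampled peak is the
quantity an ideal analysis of the noiseless data can recover).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import montage
from .eeg import EegRecording

__all__ = [
    "SubjectParams",
    "StimulationProtocol",
    "SyntheticSession",
    "CalibrationError",
    "TABLE_TARGET_INTENSITY",
    "TABLE_P50_AMP",
    "TABLE_N70_AMP",
    "weiss_threshold",
    "calibrate_subject",
    "sample_cohort",
    "recruitment_amplitude",
    "generate_isi_train",
    "synth_emg_trial",
    "synth_eeg_session",
]


class CalibrationError(ValueError):
    """Raised when subject calibration inputs are inconsistent or degenerate."""


# Group-mean calibration anchors (healthy cohort): target stimulation
# intensity per pulse width, and P50/N70 averaged-SEP peak amplitudes per
# pulse-width condition, in acquisition-native arbitrary units.
TABLE_TARGET_INTENSITY: dict[float, float] = {0.1: 24.2, 0.5: 9.5, 1.0: 8.3}
TABLE_P50_AMP: dict[float, float] = {0.1: 46.4, 0.5: 49.3, 1.0: 55.4}
TABLE_N70_AMP: dict[float, float] = {0.1: -39.0, 0.5: -55.1, 1.0: -66.9}

EMG_FS = 3200.0  # Hz
EEG_FS = 300.0   # Hz
EMG_WINDOW_MS = (-50.0, 50.0)

# Component waveform shapes (Gaussian envelopes; see docs/methods.md).
SNAP_SIGMA_MS = 1.0
SNAP_CARRIER_HZ = 150.0
CMAP_SIGMA_MS = 1.5
CMAP_CARRIER_HZ = 100.0
P50_SIGMA_MS = 10.0
N70_SIGMA_MS = 12.0

# Spatial gain of the injected cortical component: 1 at the focus channel,
# attenuated at its Hjorth neighbors, 0 elsewhere.
NEIGHBOR_GAIN = 0.2


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def weiss_threshold(rheobase: float, chronaxie: float, pulse_width) -> float | np.ndarray:
    """Strength-duration threshold current I(t) = b * (1 + c / t).

    Parameters are the rheobase ``b`` (mA; threshold current for an
    infinitely long pulse) and chronaxie ``c`` (ms; pulse width at which
    threshold is twice rheobase).  Strictly decreasing in pulse width.
    """
    pw = np.asarray(pulse_width, dtype=float)
    if rheobase <= 0 or chronaxie <= 0 or np.any(pw <= 0):
        raise ValueError("rheobase, chronaxie and pulse_width must all be positive")
    out = rheobase * (1.0 + chronaxie / pw)
    return float(out) if np.isscalar(pulse_width) else out


@dataclass
class SubjectParams:
    """Generative parameters of one simulated participant.

    Thresholds are stored both as a Weiss strength-duration backbone
    (rheobase/chronaxie) and as exact per-pulse-width overrides, because the
    calibration anchors are not exactly Weiss-consistent; the overrides are
    what the recruitment model uses, and ``weiss_residuals`` reports the
    backbone's misfit at each calibrated pulse width.
    """

    rheobase_snap: float = 7.1           # mA
    chronaxie_snap: float = 0.169        # ms
    rheobase_cmap: float = 7.3           # mA
    chronaxie_cmap: float = 0.169        # ms
    recruit_slope: float = 0.5           # mA, sigmoid scale
    snap_max: float = 50.0               # a.u.
    cmap_max: float = 200.0              # a.u.
    snap_thresholds: dict[float, float] = field(
        default_factory=lambda: dict(TABLE_TARGET_INTENSITY))
    cmap_thresholds: dict[float, float] = field(
        default_factory=lambda: {pw: v + 0.2 for pw, v in TABLE_TARGET_INTENSITY.items()})
    p50_amp: dict[float, float] = field(default_factory=lambda: dict(TABLE_P50_AMP))
    n70_amp: dict[float, float] = field(default_factory=lambda: dict(TABLE_N70_AMP))
    p50_lat: float = 45.0                # ms
    n70_lat: float = 80.0                # ms
    snap_lat: float = 3.8                # ms
    cmap_lat: float = 6.0                # ms
    lat_jitter_sd: float = 3.0           # ms, trial-to-trial latency jitter
    amp_cv: float = 0.25                 # trial-to-trial amplitude CV (EEG components)
    emg_amp_cv: float = 0.10             # trial-to-trial amplitude CV (SNAP/CMAP)
    emg_noise_sd: float = 1.5            # a.u., SNAP-channel background
    eeg_noise_sd: float = 58.0           # a.u., 1/f background SD per channel
    alpha_amp: float = 24.0              # a.u., 10 Hz oscillation amplitude
    line_amp: float = 8.0                # a.u., 60 Hz line component amplitude
    discomfort_limit: float = 40.0       # mA
    impaired: bool = False               # reduced N70, shifted to parietal (P4)
    weiss_residuals: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("rheobase_snap", "chronaxie_snap", "rheobase_cmap",
                     "chronaxie_cmap", "recruit_slope", "snap_max", "cmap_max",
                     "p50_lat", "n70_lat", "snap_lat", "cmap_lat",
                     "emg_noise_sd", "eeg_noise_sd", "discomfort_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lat_jitter_sd < 0 or self.amp_cv < 0 or self.emg_amp_cv < 0:
            raise ValueError("jitter/CV parameters must be non-negative")
        if not self.p50_lat < self.n70_lat:
            raise ValueError("p50_lat must precede n70_lat")
        for pw, thr in self.snap_thresholds.items():
            if self.discomfort_limit <= thr:
                raise ValueError(
                    f"discomfort_limit {self.discomfort_limit} mA not above the "
                    f"SNAP threshold {thr} mA at pulse width {pw} ms")

    def threshold(self, fiber: str, pulse_width: float) -> float:
        """Threshold current (mA) for ``fiber`` in {'snap','cmap'} at a pulse width."""
        overrides = self.snap_thresholds if fiber == "snap" else self.cmap_thresholds
        if pulse_width in overrides:
            return overrides[pulse_width]
        if fiber == "snap":
            return weiss_threshold(self.rheobase_snap, self.chronaxie_snap, pulse_width)
        if fiber == "cmap":
            return weiss_threshold(self.rheobase_cmap, self.chronaxie_cmap, pulse_width)
        raise ValueError(f"fiber must be 'snap' or 'cmap', got {fiber!r}")


@dataclass
class StimulationProtocol:
    """Stimulation schedule for one session."""

    pulse_widths: tuple[float, ...] = (0.1, 0.5, 1.0)  # ms
    isi_mean: float = 2.0               # s
    isi_jitter_frac: float = 0.1        # fraction of isi_mean
    n_trials: int = 70                  # assessment-run length
    intensity_step_recruit: float = 0.5  # mA
    intensity_step_assess: float = 0.1   # mA
    trials_per_step: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.isi_mean <= 0 or not (0 <= self.isi_jitter_frac < 1):
            raise ValueError("invalid ISI parameters")
        if self.n_trials < 1 or self.trials_per_step < 1:
            raise ValueError("trial counts must be >= 1")


def calibrate_subject(mean_intensities: dict[float, float],
                      seed=None,
                      population_cv: float = 0.10,
                      amp_cv_between: float = 0.25,
                      **overrides) -> SubjectParams:
    """Build a SubjectParams whose detectable-SNAP thresholds sit at the
    supplied per-pulse-width target intensities.

    A Weiss strength-duration law is least-squares fitted through the
    supplied (pulse width, intensity) pairs in charge form (Q = b*(t + c));
    the fit residual at each pulse width is reported on the returned object,
    and the exact supplied intensities are installed as per-pulse-width
    threshold overrides (used by the recruitment model).  With a ``seed``,
    parameters are perturbed to emulate between-participant variability:
    thresholds by a shared factor with CV ``population_cv``, component
    amplitudes independently with CV ``amp_cv_between``.
    """
    if len(mean_intensities) < 2:
        raise CalibrationError("need at least two (pulse_width, intensity) pairs")
    pws = np.array(sorted(mean_intensities), dtype=float)
    currents = np.array([mean_intensities[pw] for pw in pws], dtype=float)
    if np.any(np.diff(currents) >= 0):
        raise CalibrationError(
            "threshold intensities must decrease with pulse width (non-monotone pairs)")

    rng = _as_rng(seed) if seed is not None else None
    thr_factor = 1.0
    if rng is not None:
        thr_factor = max(0.5, 1.0 + population_cv * rng.standard_normal())
    snap_thr = {float(pw): float(mean_intensities[pw] * thr_factor) for pw in pws}

    # Least-squares Weiss fit in charge form: Q = I*t = b*t + b*c.
    q = np.array([snap_thr[pw] * pw for pw in pws])
    b, bc = np.polyfit(pws, q, 1)
    if b <= 0 or bc <= 0:
        raise CalibrationError("Weiss fit produced non-positive rheobase or chronaxie")
    c = bc / b
    residuals = {float(pw): float(weiss_threshold(b, c, pw) - snap_thr[pw]) for pw in pws}

    # Between-subject amplitude variability is dominated by a gain shared
    # across conditions (electrode coupling, cortical responsiveness), with
    # only a small condition-specific part, so the within-subject ordering
    # of conditions is largely preserved across the cohort.
    p50 = dict(TABLE_P50_AMP)
    n70 = dict(TABLE_N70_AMP)
    snap_max, cmap_max = 50.0, 200.0
    if rng is not None:
        gain_p50 = max(0.2, 1 + amp_cv_between * rng.standard_normal())
        gain_n70 = max(0.2, 1 + amp_cv_between * rng.standard_normal())
        p50 = {pw: v * gain_p50 * max(0.5, 1 + 0.05 * rng.standard_normal())
               for pw, v in p50.items()}
        n70 = {pw: v * gain_n70 * max(0.5, 1 + 0.05 * rng.standard_normal())
               for pw, v in n70.items()}
        snap_max *= max(0.3, 1 + 0.15 * rng.standard_normal())
        cmap_max *= max(0.3, 1 + 0.15 * rng.standard_normal())

    params = dict(
        rheobase_snap=float(b), chronaxie_snap=float(c),
        rheobase_cmap=float(b * 1.02), chronaxie_cmap=float(c),
        snap_thresholds=snap_thr,
        cmap_thresholds={pw: thr + 0.2 for pw, thr in snap_thr.items()},
        p50_amp=p50, n70_amp=n70, snap_max=snap_max, cmap_max=cmap_max,
        weiss_residuals=residuals,
    )
    params.update(overrides)
    return SubjectParams(**params)


def sample_cohort(n_subjects: int,
                  mean_intensities: dict[float, float] | None = None,
                  seed=None, **overrides) -> list[SubjectParams]:
    """Draw a cohort of calibrated subjects.

    Per-subject random streams are spawned from one master seed, so subject
    ``k`` is identical regardless of cohort size.
    """
    if mean_intensities is None:
        mean_intensities = TABLE_TARGET_INTENSITY
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [calibrate_subject(mean_intensities, seed=np.random.default_rng(ss), **overrides)
            for ss in children]


def recruitment_amplitude(intensity, pulse_width: float, fiber: str,
                          subject: SubjectParams) -> float | np.ndarray:
    """Sigmoidal recruitment: amp = max / (1 + exp(-(I - I50)/slope)).

    I50 sits two sigmoid scales above the strength-duration threshold so
    that the first *detectable* response (roughly 10 % of maximum) appears
    near the threshold current.  Monotone non-decreasing in intensity.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be >= 0")
    thr = subject.threshold(fiber, pulse_width)
    max_amp = subject.snap_max if fiber == "snap" else subject.cmap_max
    i50 = thr + 2.0 * subject.recruit_slope
    with np.errstate(over="ignore"):
        amp = max_amp / (1.0 + np.exp(-(intensity - i50) / subject.recruit_slope))
    return float(amp) if amp.ndim == 0 else amp


def generate_isi_train(n: int, isi_mean: float = 2.0, isi_jitter_frac: float = 0.1,
                       seed=None) -> np.ndarray:
    """Stimulus onset times (s) with i.i.d. uniform inter-stimulus intervals.

    ISIs are uniform on [isi_mean*(1-jitter), isi_mean*(1+jitter)] — at the
    defaults 1.8–2.2 s, averaging to a 0.5 Hz stimulation rate.  Returns the
    cumulative onset times of ``n`` stimuli (first onset after one ISI).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isi_mean <= 0 or not (0 <= isi_jitter_frac < 1):
        raise ValueError("invalid ISI parameters")
    rng = _as_rng(seed)
    lo = isi_mean * (1.0 - isi_jitter_frac)
    hi = isi_mean * (1.0 + isi_jitter_frac)
    isis = rng.uniform(lo, hi, size=n)
    return np.cumsum(isis)


# ---------------------------------------------------------------------------
# EMG synthesis

def _wavelet(t_ms: np.ndarray, lat_ms: float, sigma_ms: float, carrier_hz: float) -> np.ndarray:
    """Gaussian-windowed cosine with unit peak at ``lat_ms`` (mildly biphasic)."""
    dt = t_ms - lat_ms
    return np.exp(-0.5 * (dt / sigma_ms) ** 2) * np.cos(2e-3 * math.pi * carrier_hz * dt)


def emg_time_base(fs: float = EMG_FS, window_ms: tuple[float, float] = EMG_WINDOW_MS) -> np.ndarray:
    """Sample times (ms) of one EMG sweep, half-open [start, stop)."""
    i0 = int(round(window_ms[0] * fs / 1000.0))
    i1 = int(round(window_ms[1] * fs / 1000.0))
    return np.arange(i0, i1) / fs * 1000.0


_EMG_HW_SOS = sps.butter(2, [10.0, 1000.0], btype="bandpass", fs=EMG_FS, output="sos")


def synth_emg_trial(intensity: float, pulse_width: float, subject: SubjectParams,
                    seed=None, noiseless: bool = False):
    """One EMG sweep pair (SNAP channel, CMAP channel) at 3200 Hz, [-50, 50) ms.

    The sweep contains a decaying stimulus-artifact transient at t=0, the
    SNAP/CMAP wavelets with sigmoidally recruited amplitudes and
    multiplicative trial-to-trial variability, and Gaussian background
    noise; the acquisition hardware band (10–1000 Hz) is emulated by
    zero-phase filtering before a small quantization-scale dither is added.
    In ``noiseless`` mode the pure components are returned and the truth
    dict carries their realized sampled peaks.

    Returns ``(snap_trace, cmap_trace, truth)``.
    """
    rng = _as_rng(seed)
    t = emg_time_base()
    snap_amp = recruitment_amplitude(intensity, pulse_width, "snap", subject)
    cmap_amp = recruitment_amplitude(intensity, pulse_width, "cmap", subject)
    if not noiseless:
        snap_amp *= max(0.05, 1.0 + subject.emg_amp_cv * rng.standard_normal())
        cmap_amp *= max(0.05, 1.0 + subject.emg_amp_cv * rng.standard_normal())

    snap_sig = snap_amp * _wavelet(t, subject.snap_lat, SNAP_SIGMA_MS, SNAP_CARRIER_HZ)
    cmap_sig = cmap_amp * _wavelet(t, subject.cmap_lat, CMAP_SIGMA_MS, CMAP_CARRIER_HZ)
    artifact = np.where(t >= 0, 0.5 * intensity * np.exp(-np.maximum(t, 0) / 0.25), 0.0)

    truth = {
        "snap_amp": snap_amp, "cmap_amp": cmap_amp,
        "snap_amp_realized": float(np.max(snap_sig[(t >= 2.0) & (t < 8.0)])),
        "snap_lat_realized": float(t[(t >= 2.0) & (t < 8.0)][
            np.argmax(snap_sig[(t >= 2.0) & (t < 8.0)])]),
        "cmap_amp_realized": float(np.max(cmap_sig[(t >= 3.0) & (t < 15.0)])),
        "cmap_lat_realized": float(t[(t >= 3.0) & (t < 15.0)][
            np.argmax(cmap_sig[(t >= 3.0) & (t < 15.0)])]),
    }
    if noiseless:
        return snap_sig, cmap_sig, truth

    noise_cmap_sd = subject.emg_noise_sd * subject.cmap_max / subject.snap_max
    snap_tr = snap_sig + artifact + rng.normal(0.0, subject.emg_noise_sd, t.size)
    cmap_tr = cmap_sig + artifact + rng.normal(0.0, noise_cmap_sd, t.size)
    snap_tr = sps.sosfiltfilt(_EMG_HW_SOS, snap_tr) + rng.normal(0.0, 0.01, t.size)
    cmap_tr = sps.sosfiltfilt(_EMG_HW_SOS, cmap_tr) + rng.normal(0.0, 0.01, t.size)
    return snap_tr, cmap_tr, truth


# ---------------------------------------------------------------------------
# EEG synthesis

def one_over_f_noise(n: int, rng: np.random.Generator, exponent: float = 1.0,
                     fs: float = EEG_FS) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f**exponent, unit SD."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    with np.errstate(divide="ignore"):
        gain = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spectrum * gain, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass
class SyntheticSession:
    """One synthetic assessment run: EEG record + per-trial EMG + ground truth."""

    eeg: EegRecording
    emg_snap: np.ndarray          # n_trials x n_emg_samples
    emg_cmap: np.ndarray
    emg_fs: float
    events: pd.DataFrame          # trial, onset_s, sample, intensity_mA, pulse_width_ms
    truth: pd.DataFrame           # one record per event
    subject: SubjectParams
    pulse_width: float
    focus_channel: str

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.events["onset_s"].to_numpy()) > 0):
            raise ValueError("event times must be strictly increasing")
        if len(self.truth) != len(self.events):
            raise ValueError("truth must have one record per event")


def _component_gains(focus: str) -> dict[str, float]:
    gains = {focus: 1.0}
    for nb in montage.NEIGHBORS[focus]:
        gains[nb] = NEIGHBOR_GAIN
    return gains


def _epoch_offsets(fs: float = EEG_FS):
    pre = int(round(0.050 * fs))
    post = int(round(0.300 * fs))
    offs = np.arange(-pre, post)
    return offs, offs / fs * 1000.0


def realized_sep_truth(p50_amp: float, n70_amp: float, p50_lat: float, n70_lat: float,
                       fs: float = EEG_FS) -> dict[str, float]:
    """Realized peaks of the noiseless component on the epoch grid.

    The component trace is evaluated on the [-50, 300) ms epoch grid,
    baseline-corrected over [-50, 0) exactly as the analysis does, and the
    P50/N70 peaks are read out in the [25, 65) / [55, 95) ms windows.
    """
    _, t = _epoch_offsets(fs)
    comp = (p50_amp * np.exp(-0.5 * ((t - p50_lat) / P50_SIGMA_MS) ** 2)
            + n70_amp * np.exp(-0.5 * ((t - n70_lat) / N70_SIGMA_MS) ** 2))
    comp = comp - comp[t < 0].mean()
    w50 = (t >= 25.0) & (t < 65.0)
    w70 = (t >= 55.0) & (t < 95.0)
    return {
        "p50_amp_realized": float(comp[w50].max()),
        "p50_lat_realized": float(t[w50][np.argmax(comp[w50])]),
        "n70_amp_realized": float(comp[w70].min()),
        "n70_lat_realized": float(t[w70][np.argmin(comp[w70])]),
    }


def synth_eeg_session(subject: SubjectParams,
                      protocol: StimulationProtocol,
                      pulse_width: float,
                      seed=None,
                      hand: str = "left",
                      intensity: float | None = None,
                      noiseless: bool = False,
                      zero_jitter: bool = False,
                      artifact_fraction: float = 0.0,
                      include_emg: bool = True) -> SyntheticSession:
    """Generate a complete assessment-run session at one pulse-width condition.

    For every stimulus event a positive Gaussian component at the P50
    latency and a negative one at the N70 latency are added to the
    contralateral central channel (C4 for left-hand stimulation) and, with
    attenuated gain, to its Hjorth neighbors.  Per-trial amplitudes are
    drawn with CV ``subject.amp_cv`` and latencies jittered with SD
    ``subject.lat_jitter_sd``.  Background is 1/f noise + 10 Hz alpha +
    60 Hz line activity, independent across channels.  Under the impaired
    profile the N70 focus moves to the parietal channel (P4) and its
    amplitude is scaled down.
    """
    if pulse_width not in subject.p50_amp:
        raise ValueError(f"pulse width {pulse_width} not among calibrated conditions")
    rng = _as_rng(protocol.seed if seed is None else seed)
    n_trials = protocol.n_trials
    if intensity is None:
        intensity = subject.threshold("snap", pulse_width)

    onsets = generate_isi_train(n_trials, protocol.isi_mean, protocol.isi_jitter_frac,
                                seed=rng)
    onsets = onsets - onsets[0] + 2.0          # 2 s lead-in before the first stimulus
    n_samples = int(math.ceil((onsets[-1] + 1.0) * EEG_FS))
    event_samples = np.round(onsets * EEG_FS).astype(int)
    onsets = event_samples / EEG_FS            # events live exactly on the EEG grid

    labels = list(montage.CHANNELS_19)
    data = np.zeros((len(labels), n_samples))
    t_rec = np.arange(n_samples) / EEG_FS
    if not noiseless:
        for ch in range(len(labels)):
            bg = subject.eeg_noise_sd * one_over_f_noise(n_samples, rng)
            bg += subject.alpha_amp * np.sin(
                2 * math.pi * 10.0 * t_rec + rng.uniform(0, 2 * math.pi))
            bg += subject.line_amp * np.sin(
                2 * math.pi * 60.0 * t_rec + rng.uniform(0, 2 * math.pi))
            data[ch] += bg

    # Under the impaired profile the whole response focus shifts posteriorly
    # to the parietal electrode (no distinguishable response remains at the
    # contralateral central site), with the N70 markedly reduced and the
    # P50 less affected.
    focus = montage.contralateral_channel(hand)
    if subject.impaired:
        focus = "P4"
    p50_gains = _component_gains(focus)
    n70_gains = _component_gains(focus)
    p50_scale = 0.8 if subject.impaired else 1.0
    n70_scale = 0.4 if subject.impaired else 1.0

    p50_mean = subject.p50_amp[pulse_width] * p50_scale
    n70_mean = subject.n70_amp[pulse_width] * n70_scale

    offs, t_ep = _epoch_offsets()
    ch_index = {ch: i for i, ch in enumerate(labels)}
    records = []
    is_artifact = (rng.uniform(size=n_trials) < artifact_fraction) if artifact_fraction else \
        np.zeros(n_trials, bool)
    for k in range(n_trials):
        if noiseless or zero_jitter:
            a50, a70 = p50_mean, n70_mean
            l50, l70 = subject.p50_lat, subject.n70_lat
        else:
            a50 = p50_mean * max(0.05, 1 + subject.amp_cv * rng.standard_normal())
            a70 = n70_mean * max(0.05, 1 + subject.amp_cv * rng.standard_normal())
            l50 = subject.p50_lat + subject.lat_jitter_sd * rng.standard_normal()
            l70 = subject.n70_lat + subject.lat_jitter_sd * rng.standard_normal()
        bump50 = a50 * np.exp(-0.5 * ((t_ep - l50) / P50_SIGMA_MS) ** 2)
        bump70 = a70 * np.exp(-0.5 * ((t_ep - l70) / N70_SIGMA_MS) ** 2)
        sl = slice(event_samples[k] + offs[0], event_samples[k] + offs[-1] + 1)
        for ch, g in p50_gains.items():
            data[ch_index[ch], sl] += g * bump50
        for ch, g in n70_gains.items():
            data[ch_index[ch], sl] += g * bump70
        if is_artifact[k]:
            blob = 30.0 * subject.eeg_noise_sd * np.exp(-0.5 * ((t_ep - 120) / 60.0) ** 2)
            data[:, sl] += blob
        rec = {"trial": k, "p50_amp": a50, "n70_amp": a70,
               "p50_lat": l50, "n70_lat": l70,
               "focus_channel": focus,
               "artifact": bool(is_artifact[k])}
        rec.update(realized_sep_truth(a50, a70, l50, l70))
        records.append(rec)
    truth = pd.DataFrame.from_records(records)

    emg_snap = emg_cmap = np.zeros((0, emg_time_base().size))
    if include_emg:
        snap_rows, cmap_rows = [], []
        for k in range(n_trials):
            s, c, emg_truth = synth_emg_trial(intensity, pulse_width, subject,
                                              seed=rng, noiseless=noiseless)
            snap_rows.append(s)
            cmap_rows.append(c)
            for key, val in emg_truth.items():
                truth.loc[k, key] = val
        emg_snap = np.asarray(snap_rows)
        emg_cmap = np.asarray(cmap_rows)

    events = pd.DataFrame({
        "trial": np.arange(n_trials),
        "onset_s": onsets,
        "sample": event_samples,
        "intensity_mA": float(intensity),
        "pulse_width_ms": float(pulse_width),
    })
    eeg = EegRecording(data=data, fs=EEG_FS, labels=labels, events=event_samples)
    return SyntheticSession(eeg=eeg, emg_snap=emg_snap, emg_cmap=emg_cmap,
                            emg_fs=EMG_FS, events=events, truth=truth,
                            subject=subject, pulse_width=pulse_width,
                            focus_channel=focus)
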