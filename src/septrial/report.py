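"""Study orchestration: simulate a cohort end-to-end and tabulate results.

``run_study`` reproduces the experiment structure on synthetic data: for
every subject, session and pulse width it acquires a SNAP/CMAP recruitment
curve, selects the target intensity, runs a closed-loop assessment with the
±20 % maintenance controller, simulates the EEG assessment run at the
target intensity, and applies both the averaged-SEP and single-trial
analyses.  Group statistics (Friedman + Kendall's w, Wilcoxon-Holm post
hocs, test-retest ICC) are then assembled into report tables shaped like
the study's printed summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import eeg as eeg_mod
from . import emg as emg_mod
from . import single_trial as st_mod
from . import stats as stats_mod
from . import synth

__all__ = ["StudyConfig", "StudyReport", "run_study", "normalized_intensity"]


@dataclass
class StudyConfig:
    """Study-level parameters; defaults mirror the healthy-cohort protocol."""

    n_subjects: int = 12
    n_sessions: int = 1
    pulse_widths: tuple[float, ...] = (0.1, 0.5, 1.0)
    n_trials_assessment: int = 70
    trials_per_step: int = 4
    intensity_step_recruit: float = 0.5      # mA
    intensity_step_assess: float = 0.1       # mA
    maintenance_band: float = 0.2            # +/- fraction of target CMAP
    hand: str = "left"
    session_cv: float = 0.12                 # between-session amplitude variability
    impaired: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("cohort and session counts must be >= 1")
        if not self.pulse_widths:
            raise ValueError("need at least one pulse width")


@dataclass
class StudyReport:
    """Tabulated outcome of one simulated study."""

    subject_table: pd.DataFrame          # one row per subject x session x pulse width
    table_intensity: pd.DataFrame        # target intensity, CV, normalized, charge
    table_sep: pd.DataFrame              # P50/N70 amplitude & latency per condition
    table_icc: pd.DataFrame | None       # ICC grid across sessions (None if 1 session)
    auc_table: pd.DataFrame              # per-subject and group AUC per condition
    stats: dict                          # named StatResult objects
    config: StudyConfig
    seed: int | None
    log: list[str] = field(default_factory=list)

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subject_table.to_csv(out / "subject_table.csv", index=False)
        self.table_intensity.to_csv(out / "table_intensity.csv", index=False)
        self.table_sep.to_csv(out / "table_sep.csv", index=False)
        if self.table_icc is not None:
            self.table_icc.to_csv(out / "table_icc.csv", index=False)
        self.auc_table.to_csv(out / "auc_table.csv", index=False)
        lines = [f"seed = {self.seed}", ""]
        for name, res in self.stats.items():
            lines.append(
                f"{name}: chi2/stat = {res.statistic:.2f}, p = {res.p_value:.4g}"
                + (f", w/ICC = {res.effect_size:.2f}" if res.effect_size is not None else ""))
        lines += ["", *self.log]
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        return out


def _session_subject(subject: synth.SubjectParams, session_cv: float,
                     rng: np.random.Generator) -> synth.SubjectParams:
    """Per-session copy of a subject with between-session amplitude variability."""
    if session_cv <= 0:
        return subject
    f_eeg = max(0.3, 1.0 + session_cv * rng.standard_normal())
    f_emg = max(0.3, 1.0 + session_cv * rng.standard_normal())
    return replace(
        subject,
        p50_amp={pw: v * f_eeg for pw, v in subject.p50_amp.items()},
        n70_amp={pw: v * f_eeg for pw, v in subject.n70_amp.items()},
        snap_max=subject.snap_max * f_emg,
        cmap_max=subject.cmap_max * f_emg,
    )


def _recruitment(subject: synth.SubjectParams, pulse_width: float,
                 config: StudyConfig, rng: np.random.Generator):
    """Acquire the SNAP/CMAP recruitment run and detect the target intensity.

    The ramp starts well below the subject's threshold and stops two steps
    after both responses are consistently discernible (or at the discomfort
    limit), mirroring how an experimenter would run it.
    """
    thr = subject.threshold("snap", pulse_width)
    step = config.intensity_step_recruit
    start = max(step, np.floor((thr - 4.0) / step) * step)
    snap_rows, cmap_rows, intensities = [], [], []
    level = start
    extra = 0
    while level <= subject.discomfort_limit:
        for _ in range(config.trials_per_step):
            s, c, _truth = synth.synth_emg_trial(level, pulse_width, subject, seed=rng)
            snap_rows.append(s)
            cmap_rows.append(c)
            intensities.append(level)
        if level >= thr + 0.5:
            extra += 1
            if extra >= 2:
                break
        level = round(level + step, 10)
    fs = synth.EMG_FS
    snap_ep = emg_mod.EmgEpochs(emg_mod.filter_emg(np.asarray(snap_rows), fs),
                                fs=fs, intensities=np.asarray(intensities))
    cmap_ep = emg_mod.EmgEpochs(emg_mod.filter_emg(np.asarray(cmap_rows), fs),
                                fs=fs, intensities=np.asarray(intensities))
    snap_curve = emg_mod.build_recruitment_curve(snap_ep, emg_mod.SNAP_WINDOW_MS,
                                                 trials_per_step=config.trials_per_step)
    cmap_curve = emg_mod.build_recruitment_curve(cmap_ep, emg_mod.CMAP_WINDOW_MS,
                                                 trials_per_step=config.trials_per_step)
    target = emg_mod.detect_target_intensity(snap_curve, cmap_curve)
    snap_curve.target_intensity = target
    cmap_curve.target_intensity = target
    return snap_curve, cmap_curve, target


def _assessment(subject: synth.SubjectParams, pulse_width: float, target: float,
                config: StudyConfig, rng: np.random.Generator):
    """Closed-loop assessment run against the subject's recruitment model."""
    t = synth.emg_time_base()
    snap_w = (t >= 2.0) & (t < 8.0)
    cmap_w = (t >= 3.0) & (t < 15.0)

    def respond(intensity: float, k: int) -> tuple[float, float]:
        s, c, _ = synth.synth_emg_trial(intensity, pulse_width, subject, seed=rng)
        fs = synth.EMG_FS
        s = emg_mod.filter_emg(s, fs)
        c = emg_mod.filter_emg(c, fs)
        return float(s[snap_w].max()), float(c[cmap_w].max())

    target_snap = synth.recruitment_amplitude(target, pulse_width, "snap", subject)
    target_cmap = synth.recruitment_amplitude(target, pulse_width, "cmap", subject)
    return emg_mod.monitor_assessment(
        respond, target_snap=target_snap, target_cmap=target_cmap,
        start_intensity=target, n_trials=config.n_trials_assessment,
        band=config.maintenance_band, step=config.intensity_step_assess,
        discomfort_limit=subject.discomfort_limit)


def _eeg_condition(subject: synth.SubjectParams, pulse_width: float, target: float,
                   config: StudyConfig, rng: np.random.Generator) -> dict:
    """Simulate one EEG assessment run and apply both analysis paths."""
    protocol = synth.StimulationProtocol(n_trials=config.n_trials_assessment)
    session = synth.synth_eeg_session(subject, protocol, pulse_width,
                                      seed=rng, hand=config.hand,
                                      intensity=target, include_emg=False)
    rec = eeg_mod.preprocess_eeg(session.eeg)
    rec = eeg_mod.laplacian_montage(rec)
    epochs = eeg_mod.epoch_and_baseline(rec)

    channel = session.focus_channel   # P4 under the impaired profile

    masked = eeg_mod.reject_bad_trials(epochs, channel)
    _avg, peaks = eeg_mod.average_sep(masked, channel)
    feats = st_mod.extract_features(epochs, channel)
    bg = feats.table["background_rms"].to_numpy()
    auc_p50 = st_mod.separability_auc(feats.table["p50_rms"].to_numpy(), bg, "p50").auc
    auc_n70 = st_mod.separability_auc(feats.table["n70_rms"].to_numpy(), bg, "n70").auc

    # Per-trial signed peaks on the analysis channel for the SNR summary.
    x = epochs.data[:, epochs.channel_index(channel), :]
    w50 = epochs.window_mask(eeg_mod.P50_WINDOW_MS)
    w70 = epochs.window_mask(eeg_mod.N70_WINDOW_MS)
    p50_trials = x[:, w50].max(axis=1)
    n70_trials = x[:, w70].min(axis=1)

    r2_n70 = eeg_mod.topography_r2(epochs, eeg_mod.N70_WINDOW_MS)
    return {
        "p50_amp": peaks.p50_amp, "n70_amp": peaks.n70_amp,
        "p50_lat": peaks.p50_lat, "n70_lat": peaks.n70_lat,
        "snr_p50": stats_mod.snr_mean_std(p50_trials),
        "snr_n70": stats_mod.snr_mean_std(n70_trials),
        "auc_p50": auc_p50, "auc_n70": auc_n70,
        "r2_n70_focus": r2_n70[channel],
        "r2_n70_argmax": max(r2_n70, key=r2_n70.get),
        "n_trials_masked": int(masked.mask.sum()),
    }


def normalized_intensity(table: pd.DataFrame, reference_pw: float = 1.0):
    """Per-subject target intensities normalized by the subject's 1 ms value.

    ``table`` needs columns subject, pulse_width_ms, target_intensity.
    Subjects without a reference-pulse-width entry are excluded and listed.
    Returns ``(normalized_table, excluded_subjects)``.
    """
    rows, excluded = [], []
    for subj, grp in table.groupby("subject"):
        ref = grp.loc[grp["pulse_width_ms"] == reference_pw, "target_intensity"]
        if ref.empty or not np.isfinite(ref.iloc[0]):
            excluded.append(subj)
            continue
        for _, r in grp.iterrows():
            rows.append({"subject": subj, "pulse_width_ms": r["pulse_width_ms"],
                         "normalized_intensity": r["target_intensity"] / ref.iloc[0]})
    return pd.DataFrame(rows), excluded


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    return float(v.mean()), float(se)


def run_study(config: StudyConfig | None = None, seed: int | None = None) -> StudyReport:
    """Simulate and analyze a full cohort; fully reproducible from (config, seed)."""
    config = config or StudyConfig()
    log: list[str] = []
    subjects = synth.sample_cohort(config.n_subjects, seed=seed,
                                   impaired=config.impaired)
    streams = np.random.SeedSequence(seed).spawn(
        config.n_subjects * config.n_sessions * len(config.pulse_widths) + 1)
    stream_iter = iter(streams[1:])

    rows = []
    for si, subject in enumerate(subjects):
        for sess in range(config.n_sessions):
            sess_rng = np.random.default_rng(next(stream_iter))
            sess_subject = _session_subject(subject, config.session_cv if sess else 0.0,
                                            sess_rng)
            for pw in config.pulse_widths:
                row = {"subject": si, "session": sess, "pulse_width_ms": pw,
                       "true_threshold": sess_subject.threshold("snap", pw)}
                try:
                    _snap_c, _cmap_c, target = _recruitment(sess_subject, pw, config,
                                                            sess_rng)
                    row["target_intensity"] = np.nan if target is None else target
                    if target is None:
                        raise RuntimeError("no discernible SNAP/CMAP level")
                    row["charge_C"] = emg_mod.compute_charge(target, pw)
                    assess = _assessment(sess_subject, pw, target, config, sess_rng)
                    row["n_adjustments"] = assess.n_adjustments
                    row.update(_eeg_condition(sess_subject, pw, target, config,
                                              sess_rng))
                except Exception as exc:  # stage failure: mark the gap, keep going
                    log.append(f"subject {si} session {sess} pw {pw}: {exc}")
                    row["failed"] = str(exc)
                rows.append(row)
    subject_table = pd.DataFrame(rows)

    first = subject_table[subject_table["session"] == 0]
    norm, excluded = normalized_intensity(first)
    if excluded:
        log.append(f"normalized intensity: excluded subjects {excluded}")

    t1_rows = []
    for pw in config.pulse_widths:
        sel = first[first["pulse_width_ms"] == pw]
        ti = sel["target_intensity"].to_numpy(dtype=float)
        m, se = _mean_se(ti)
        nv = norm.loc[norm["pulse_width_ms"] == pw, "normalized_intensity"].to_numpy()
        nm, nse = _mean_se(nv)
        cm, _cse = _mean_se(sel["charge_C"].to_numpy(dtype=float))
        t1_rows.append({
            "pulse_width_ms": pw,
            "target_intensity_mA": m, "target_intensity_se": se,
            "cv": stats_mod.coefficient_of_variation(ti[np.isfinite(ti)])
            if np.isfinite(ti).sum() > 1 else np.nan,
            "normalized_intensity": nm, "normalized_intensity_se": nse,
            "charge_C": cm,
        })
    table_intensity = pd.DataFrame(t1_rows)

    t2_rows = []
    for pw in config.pulse_widths:
        sel = first[first["pulse_width_ms"] == pw]
        entry = {"pulse_width_ms": pw}
        for meas in ("p50_amp", "n70_amp", "p50_lat", "n70_lat",
                     "snr_p50", "snr_n70"):
            if meas in sel:
                m, se = _mean_se(sel[meas].to_numpy(dtype=float))
                entry[meas], entry[meas + "_se"] = m, se
        t2_rows.append(entry)
    table_sep = pd.DataFrame(t2_rows)

    feats_cols = {"p50": "auc_p50", "n70": "auc_n70"}
    auc_rows = []
    for comp, col in feats_cols.items():
        if col not in first:
            continue
        for pw in config.pulse_widths:
            sel = first[first["pulse_width_ms"] == pw]
            m, se = _mean_se(sel[col].to_numpy(dtype=float))
            auc_rows.append({"component": comp, "pulse_width_ms": pw,
                             "auc_mean": m, "auc_se": se})
    auc_table = pd.DataFrame(auc_rows)

    stats: dict[str, stats_mod.StatResult] = {}
    if config.n_subjects >= 2 and len(config.pulse_widths) >= 2:
        for name, col, transform in (
                ("n70_amp", "n70_amp", np.abs), ("p50_amp", "p50_amp", None),
                ("snr_n70", "snr_n70", None), ("auc_n70", "auc_n70", None),
                ("target_intensity", "target_intensity", None)):
            if col not in first:
                continue
            wide = first.pivot(index="subject", columns="pulse_width_ms", values=col)
            wide = wide[list(config.pulse_widths)]
            mat = wide.to_numpy(dtype=float)
            mat = mat[~np.isnan(mat).any(axis=1)]
            if mat.shape[0] < 2:
                log.append(f"friedman {name}: fewer than 2 complete rows, skipped")
                continue
            if transform is not None:
                mat = transform(mat)
            stats[f"friedman_{name}"] = stats_mod.friedman(mat)
            if len(config.pulse_widths) >= 2 and mat.shape[0] >= 3:
                pvals, pairs = [], []
                for i in range(len(config.pulse_widths)):
                    for j in range(i + 1, len(config.pulse_widths)):
                        res = stats_mod.wilcoxon_signed_rank(mat[:, i], mat[:, j])
                        pvals.append(res.p_value)
                        pairs.append((config.pulse_widths[i], config.pulse_widths[j]))
                adj = stats_mod.holm_adjust(pvals)
                stats[f"friedman_{name}"].extras["posthoc_holm"] = dict(
                    zip(pairs, adj.tolist()))
    else:
        log.append("group tests skipped: fewer than 2 subjects or conditions")

    table_icc = None
    if config.n_sessions >= 2:
        icc_rows = []
        for meas in ("n70_amp", "p50_amp", "n70_lat", "p50_lat"):
            for pw in config.pulse_widths:
                sel = subject_table[subject_table["pulse_width_ms"] == pw]
                wide = sel.pivot(index="subject", columns="session", values=meas)
                mat = wide.to_numpy(dtype=float)
                mat = mat[~np.isnan(mat).any(axis=1)]
                if mat.shape[0] < 3:
                    log.append(f"icc {meas} pw {pw}: fewer than 3 complete subjects")
                    continue
                res = stats_mod.icc_21(mat)
                icc_rows.append({"measure": meas, "pulse_width_ms": pw,
                                 "icc": res.effect_size, "p_value": res.p_value,
                                 "ci_low": res.ci[0], "ci_high": res.ci[1],
                                 "n": res.n,
                                 "interpretation": res.extras["interpretation"]})
        table_icc = pd.DataFrame(icc_rows)

    return StudyReport(subject_table=subject_table, table_intensity=table_intensity,
                       table_sep=table_sep, table_icc=table_icc, auc_table=auc_table,
                       stats=stats, config=config, seed=seed, log=log)
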