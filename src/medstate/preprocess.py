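"""EEG preprocessing: re-reference, high-pass, bad channels, ICA, epoching.

The pipeline order mirrors standard ERP practice: common-average
re-reference, 1 Hz zero-phase high-pass, bad-channel detection and
inverse-distance interpolation, ICA-based ocular artifact removal scored
against the EOG channel, epoching to -200..+800 ms with pre-stimulus
baseline correction, and amplitude-threshold epoch rejection.  Every step
appends to ``Recording.history``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as spsig
from sklearn.decomposition import FastICA

from .containers import (
    CHANNEL_POSITIONS,
    EOG_LABEL,
    EpochSet,
    IcaReport,
    Recording,
)


class AllEpochsRejectedError(RuntimeError):
    """Raised when amplitude rejection leaves no usable trial."""


def read_events_tsv(path) -> pd.DataFrame:
    """Read a BIDS-style events.tsv (onset seconds from recording start)."""
    ev = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(ev.columns):
        raise ValueError(f"events table must contain columns {sorted(required)}")
    return ev


def rereference_common_average(rec: Recording, eog_label: str = EOG_LABEL) -> Recording:
    """Re-reference scalp channels to their common average (EOG untouched)."""
    eeg = rec.eeg_indices(eog_label)
    if eeg.size < 2:
        raise ValueError("common-average reference needs at least 2 EEG channels")
    data = rec.data.copy()
    data[eeg] -= data[eeg].mean(axis=0, keepdims=True)
    return rec.copy_with(data, "rereference_common_average",
                         reference="common_average")


def highpass(rec: Recording, cutoff_hz: float = 1.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth high-pass (applied forward-backward)."""
    if cutoff_hz >= rec.fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = spsig.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    data = spsig.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data, f"highpass[{cutoff_hz}Hz]")


def detect_bad_channels(rec: Recording, z_thresh: float = 5.0,
                        eog_label: str = EOG_LABEL) -> list[str]:
    """Flag flat channels (variance < 1e-12) and outliers in log-variance.

    The noisy-channel rule uses a robust z-score (median/MAD) of the
    log-variance across scalp channels, so a single wild channel cannot
    mask itself.
    """
    eeg = rec.eeg_indices(eog_label)
    if eeg.size < 4:
        raise ValueError("need at least 4 EEG channels for bad-channel detection")
    variances = rec.data[eeg].var(axis=1)
    flat = variances < 1e-12
    bads = set(np.asarray(rec.labels)[eeg[flat]])
    ok = ~flat
    if ok.sum() >= 4:
        logv = np.log(variances[ok])
        med = np.median(logv)
        mad = np.median(np.abs(logv - med))
        scale = 1.4826 * mad
        if scale > 0:
            z = np.abs(logv - med) / scale
            for idx, zi in zip(eeg[ok], z):
                if zi > z_thresh:
                    bads.add(rec.labels[idx])
    return sorted(bads, key=rec.labels.index)


def interpolate_channels(rec: Recording, bads: list[str],
                         eog_label: str = EOG_LABEL) -> Recording:
    """Replace bad channels by the inverse-squared-distance mean of good ones.

    Distances are chord lengths between unit-sphere 10-20 positions; weights
    are normalized to sum to one per interpolated channel.
    """
    if not bads:
        raise ValueError("no channels to interpolate")
    eeg_labels = [rec.labels[i] for i in rec.eeg_indices(eog_label)]
    good = [l for l in eeg_labels if l not in bads]
    if not good:
        raise ValueError("cannot interpolate: all EEG channels are bad")
    pos = {l: np.asarray(CHANNEL_POSITIONS[l]) for l in eeg_labels}
    data = rec.data.copy()
    for bad in bads:
        d = np.array([np.linalg.norm(pos[bad] - pos[g]) for g in good])
        d = np.maximum(d, 1e-6)
        w = 1.0 / d**2
        w /= w.sum()
        rows = [rec.labels.index(g) for g in good]
        data[rec.labels.index(bad)] = w @ data[rows]
    return rec.copy_with(data, f"interpolate[{','.join(bads)}]")


def _lowfreq_dominance(source: np.ndarray, fs: float, edge_hz: float = 4.0) -> float:
    """Fraction of Welch power below edge_hz; in [0, 1] by construction."""
    nper = min(len(source), int(4 * fs))
    f, p = spsig.welch(source, fs=fs, nperseg=nper)
    total = np.trapezoid(p, f)
    if total <= 0:
        return 0.0
    return float(np.trapezoid(p[f <= edge_hz], f[f <= edge_hz]) / total)


def ica_artifact_removal(
    rec: Recording,
    eog_label: str = EOG_LABEL,
    threshold: float = 0.9,
    seed: int = 0,
    max_iter: int = 1000,
) -> tuple[Recording, IcaReport]:
    """Remove ocular components by negentropy ICA (deflation) on scalp channels.

    Per-component artifact probability = max(|corr with EOG|, low-frequency
    dominance), both naturally in [0, 1]; components scoring at or above
    ``threshold`` are zeroed before back-projection.  The EOG channel itself
    is excluded from the decomposition and never modified.
    """
    if eog_label not in rec.labels:
        raise ValueError("EOG channel required for ICA artifact scoring")
    eeg = rec.eeg_indices(eog_label)
    X = rec.data[eeg].T  # samples x channels
    eog = rec.data[rec.labels.index(eog_label)]
    n_comp = eeg.size
    try:
        ica = FastICA(n_components=n_comp, algorithm="deflation", fun="logcosh",
                      whiten="unit-variance", max_iter=max_iter, random_state=seed)
        S = ica.fit_transform(X)
    except Exception as exc:  # non-convergence or degenerate input
        report = IcaReport(n_components=0, rejected=[], scores=np.array([]),
                           notes=f"decomposition failed: {exc}")
        return rec.copy_with(rec.data.copy(), "ica[failed]"), report

    scores = np.empty(n_comp)
    eog_sd = eog.std()
    for k in range(n_comp):
        s = S[:, k]
        if eog_sd > 0 and s.std() > 0:
            corr = abs(float(np.corrcoef(s, eog)[0, 1]))
        else:
            corr = 0.0
        scores[k] = max(corr, _lowfreq_dominance(s, rec.fs))
    rejected = [k for k in range(n_comp) if scores[k] >= threshold]

    S_clean = S.copy()
    S_clean[:, rejected] = 0.0
    X_clean = ica.inverse_transform(S_clean)
    data = rec.data.copy()
    data[eeg] = X_clean.T
    report = IcaReport(n_components=n_comp, rejected=rejected, scores=scores,
                       notes="score = max(|corr with EOG|, low-frequency dominance)")
    out = rec.copy_with(data, f"ica[rejected={rejected}]")
    return out, report


def epoch(
    rec: Recording,
    events: pd.DataFrame,
    window_ms: tuple[float, float] = (-200.0, 800.0),
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
) -> EpochSet:
    """Cut per-event epochs and baseline-correct each trial and channel.

    The window is sampled on the recording grid: pre = round(|w0| fs) and
    post = round(w1 fs) samples, both endpoints included, giving 257 samples
    for (-200, 800) ms at 256 Hz.  Events whose window exceeds the recording
    bounds are dropped and counted.
    """
    pre = int(round(abs(window_ms[0]) / 1000.0 * rec.fs))
    post = int(round(window_ms[1] / 1000.0 * rec.fs))
    times_ms = np.arange(-pre, post + 1) / rec.fs * 1000.0
    trials, conditions = [], []
    n_dropped = 0
    for onset, ttype in zip(events["onset"], events["trial_type"]):
        idx = int(round(onset * rec.fs))
        lo, hi = idx - pre, idx + post + 1
        if lo < 0 or hi > rec.n_samples:
            n_dropped += 1
            continue
        trials.append(rec.data[:, lo:hi])
        conditions.append(ttype)
    if not trials:
        raise ValueError("no usable events inside the recording")
    data = np.stack(trials)
    # half-sample tolerance: at rates where 200 ms is not an integer number
    # of samples the first epoch sample sits just outside the nominal
    # baseline edge but still belongs to the pre-stimulus interval
    half_step = 500.0 / rec.fs
    bmask = (times_ms >= baseline_ms[0] - half_step) & \
        (times_ms <= baseline_ms[1] + 1e-9)
    data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochSet(data=data, labels=list(rec.labels), fs=rec.fs,
                    times_ms=times_ms, condition=np.array(conditions),
                    baseline_window=baseline_ms, n_dropped=n_dropped)


def reject_epochs(ep: EpochSet, amp_thresh_uv: float = 100.0,
                  eog_label: str = EOG_LABEL) -> EpochSet:
    """Mask out trials whose scalp-channel amplitude exceeds the threshold.

    The EOG channel is excluded from the criterion (it carries the ocular
    reference signal by design); trial data are retained, only ``kept_mask``
    changes.  Raises if nothing survives.
    """
    scalp = [i for i, l in enumerate(ep.labels) if l != eog_label]
    peak = np.abs(ep.data[:, scalp, :]).max(axis=(1, 2))
    new_mask = ep.kept_mask & (peak <= amp_thresh_uv)
    if not new_mask.any():
        raise AllEpochsRejectedError(
            f"amplitude threshold {amp_thresh_uv} uV rejected all trials"
        )
    return EpochSet(data=ep.data, labels=ep.labels, fs=ep.fs, times_ms=ep.times_ms,
                    condition=ep.condition, baseline_window=ep.baseline_window,
                    kept_mask=new_mask, n_dropped=ep.n_dropped)


def preprocess_recording(
    rec: Recording,
    events: pd.DataFrame,
    highpass_hz: float = 1.0,
    ica_threshold: float = 0.9,
    amp_thresh_uv: float = 100.0,
    run_ica: bool = True,
    seed: int = 0,
) -> tuple[EpochSet, Recording, IcaReport | None]:
    """Run the full preprocessing chain in canonical order."""
    rec = rereference_common_average(rec)
    rec = highpass(rec, highpass_hz)
    bads = detect_bad_channels(rec)
    if bads and len(bads) < len(rec.eeg_indices()):
        rec = interpolate_channels(rec, bads)
    report = None
    if run_ica:
        rec, report = ica_artifact_removal(rec, threshold=ica_threshold, seed=seed)
    ep = epoch(rec, events)
    ep = reject_epochs(ep, amp_thresh_uv)
    return ep, rec, report
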