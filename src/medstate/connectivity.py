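"""Signal complexity and functional connectivity: spectral entropy,
magnitude-squared coherence, phase-locking value, and the two-level
repeated-measures ANOVA used for state comparisons."""

from __future__ import annotations

import numpy as np
from scipy import signal as spsig
from scipy import stats as sps

from .containers import BANDS, EpochSet, StatTestResult


def normalized_entropy(in_band_psd) -> float:
    """Shannon entropy of PSD bins normalized by ln K, so the result lies in
    [0, 1]: 1 for a flat spectrum, 0 for a single spectral line."""
    p = np.asarray(in_band_psd, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 PSD bins")
    if np.any(p < 0):
        raise ValueError("PSD bins must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("zero in-band power: entropy undefined")
    p = p / total
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return float(h / np.log(p.size))


def spectral_entropy(signal, fs: float, band: tuple[float, float],
                     seg_len_s: float = 2.0) -> float:
    """Normalized Shannon entropy of the in-band Welch spectrum, in [0, 1]."""
    x = np.asarray(signal, dtype=float)
    nperseg = min(len(x), int(round(seg_len_s * fs)))
    freqs, psd = spsig.welch(x, fs=fs, window="hann", nperseg=nperseg)
    lo, hi = band
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError("need at least 2 PSD bins inside the band")
    return normalized_entropy(psd[mask])


def coherence(x, y, fs: float, band: tuple[float, float],
              seg_len_s: float = 2.0, overlap: float = 0.5) -> float:
    """Magnitude-squared coherence |Sxy|^2 / (Sxx Syy), averaged over the band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    nperseg = int(round(seg_len_s * fs))
    step = nperseg - int(round(nperseg * overlap))
    n_segments = max(0, 1 + (len(x) - nperseg) // step)
    if n_segments < 8:
        raise ValueError("coherence needs at least 8 Welch segments")
    freqs, coh = spsig.coherence(x, y, fs=fs, window="hann", nperseg=nperseg,
                                 noverlap=int(round(nperseg * overlap)))
    lo, hi = band
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError("band outside the coherence frequency axis")
    return float(coh[mask].mean())


def plv(ep: EpochSet, pair: tuple[str, str], band: tuple[float, float],
        window_ms: tuple[float, float] = (0.0, 800.0)) -> float:
    """Phase-locking value between two channels across trials.

    Each kept trial is band-passed (4th-order zero-phase Butterworth), the
    analytic phase extracted per channel, and PLV computed across trials at
    every time sample, then averaged over the post-stimulus window.  1 means
    a perfectly reproducible phase difference (constant lags included),
    roughly sqrt(pi)/2/sqrt(N) for independent phases.
    """
    if band[1] >= ep.fs / 2:
        raise ValueError("band upper edge must be below Nyquist")
    kept = ep.kept()
    if kept.sum() < 2:
        raise ValueError("PLV requires at least two kept trials")
    ia, ib = ep.channel_index(pair[0]), ep.channel_index(pair[1])
    data = ep.data[kept][:, [ia, ib], :]  # trials x 2 x time
    sos = spsig.butter(4, band, btype="bandpass", fs=ep.fs, output="sos")
    filtered = spsig.sosfiltfilt(sos, data, axis=2)
    phase = np.angle(spsig.hilbert(filtered, axis=2))
    dphi = phase[:, 0, :] - phase[:, 1, :]
    plv_t = np.abs(np.exp(1j * dphi).mean(axis=0))  # per time sample
    tmask = (ep.times_ms >= window_ms[0] - 1e-9) & (ep.times_ms <= window_ms[1] + 1e-9)
    return float(plv_t[tmask].mean())


def rm_anova_2level(values_a, values_b) -> StatTestResult:
    """One within-factor, two-level repeated-measures ANOVA.

    Computed from the classical decomposition (SS_condition over SS_error
    after removing subject means); algebraically F(1, n-1) equals the square
    of the paired t statistic on the same data.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    n = a.size
    data = np.stack([a, b])  # condition x subject
    grand = data.mean()
    cond_means = data.mean(axis=1)
    subj_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    residual = data - cond_means[:, None] - subj_means[None, :] + grand
    ss_err = np.sum(residual**2)
    df_cond, df_err = 1, n - 1
    if ss_err == 0:
        f = np.inf if ss_cond > 0 else 0.0
        p = 0.0 if ss_cond > 0 else 1.0
        return StatTestResult(statistic=float(f), df=df_err, p_value=float(p),
                              test_name="rm-ANOVA (2 level)", capped=ss_cond > 0)
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(sps.f.sf(f, df_cond, df_err))
    return StatTestResult(statistic=float(f), df=df_err, p_value=p,
                          test_name="rm-ANOVA (2 level)")


#: Default electrode pairs for the connectivity summaries.
COHERENCE_PAIR = ("Fz", "Pz")
PLV_PAIRS = (("Fz", "Cz"), ("F3", "C3"), ("F4", "C4"))


def mean_plv(ep: EpochSet, band_name: str,
             pairs=PLV_PAIRS) -> float:
    """PLV averaged over the frontal-central pairs present in the montage."""
    band = BANDS[band_name]
    vals = [plv(ep, p, band) for p in pairs
            if p[0] in ep.labels and p[1] in ep.labels]
    if not vals:
        raise ValueError("none of the requested pairs exist in the montage")
    return float(np.mean(vals))
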