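"""Welch power spectral density and band-power condition contrasts."""

from __future__ import annotations

import numpy as np
from scipy import signal as spsig

from .containers import BANDS, Psd, Recording, SITES, StatTestResult


def welch_psd(data, fs: float, seg_len_s: float = 2.0, overlap: float = 0.5,
              labels=None) -> Psd:
    """Hann-windowed averaged periodogram, one-sided density in uV^2/Hz.

    ``data`` may be a 1-D signal or a channels x samples matrix.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    nperseg = int(round(seg_len_s * fs))
    if x.shape[1] < nperseg:
        raise ValueError("signal shorter than one Welch segment")
    noverlap = int(round(nperseg * overlap))
    freqs, power = spsig.welch(x, fs=fs, window="hann", nperseg=nperseg,
                               noverlap=noverlap, axis=1)
    if labels is None:
        labels = [f"ch{i}" for i in range(x.shape[0])]
    return Psd(freqs=freqs, power=power, labels=list(labels),
               seg_len_s=seg_len_s, overlap=overlap)


def psd_of_recording(rec: Recording, seg_len_s: float = 2.0,
                     overlap: float = 0.5) -> Psd:
    return welch_psd(rec.data, rec.fs, seg_len_s, overlap, labels=rec.labels)


def band_power(psd: Psd, band: tuple[float, float], channel=None) -> float | np.ndarray:
    """Trapezoidal integral of the PSD over [lo, hi] Hz (returns uV^2).

    With ``channel`` given (label or index) a scalar is returned, otherwise
    one value per PSD row.
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError("band edges must satisfy lo < hi")
    if lo < psd.freqs[0] - 1e-9 or hi > psd.freqs[-1] + 1e-9:
        raise ValueError("band lies outside the PSD frequency range")
    mask = (psd.freqs >= lo - 1e-9) & (psd.freqs <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError("band spans fewer than two PSD bins")
    values = np.trapezoid(psd.power[:, mask], psd.freqs[mask], axis=1)
    if channel is None:
        return values if values.size > 1 else float(values[0])
    idx = psd.labels.index(channel) if isinstance(channel, str) else channel
    return float(values[idx])


def site_band_power(psd: Psd, band_name: str, site_name: str) -> float:
    """Band power averaged over the channels of a scalp region."""
    band = BANDS[band_name]
    chans = [c for c in SITES[site_name] if c in psd.labels]
    if not chans:
        raise ValueError(f"no channels of site {site_name!r} in the PSD")
    return float(np.mean([band_power(psd, band, c) for c in chans]))


def band_power_contrast(values_a, values_b) -> StatTestResult:
    """Two-level repeated-measures ANOVA on paired per-subject band powers.

    Thin wrapper over connectivity.rm_anova_2level; the sign of the effect
    (mean of a - b) is carried in ``effect_size``.
    """
    from .connectivity import rm_anova_2level

    res = rm_anova_2level(values_a, values_b)
    diff = np.mean(np.asarray(values_a, float) - np.asarray(values_b, float))
    res.effect_size = float(diff)
    return res
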