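"""Morlet wavelet time-frequency analysis: ERSP, ITC, permutation-FDR maps.

Frequencies run 3-40 Hz in logarithmic steps (25 by default).  The number of
wavelet cycles grows linearly with frequency from 3 at the lowest frequency:
n_cycles(f) = 3 + 0.5 * (f / f_min - 1), about 9.2 cycles at 40 Hz, trading
temporal for spectral resolution as frequency rises.  Wavelets are
energy-normalized (unit L2 norm) and truncated at +/-2.5 temporal standard
deviations; samples closer to an epoch edge than the wavelet half-length are
flagged invalid.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as spsig

from .containers import EpochSet, TFResult
from .stats import bh_fdr

F_MIN_DEFAULT = 3.0
F_MAX_DEFAULT = 40.0
N_FREQS_DEFAULT = 25
CYCLES_BASE = 3.0
CYCLES_EXPANSION = 0.5
WAVELET_TRUNCATION_SD = 2.5


def log_freqs(fmin: float = F_MIN_DEFAULT, fmax: float = F_MAX_DEFAULT,
              n: int = N_FREQS_DEFAULT) -> np.ndarray:
    """Logarithmically spaced analysis frequencies."""
    return np.geomspace(fmin, fmax, n)


def n_cycles(freqs: np.ndarray, f0: float | None = None) -> np.ndarray:
    """Linear cycle growth: CYCLES_BASE at f0, + CYCLES_EXPANSION per (f/f0 - 1)."""
    freqs = np.asarray(freqs, dtype=float)
    f0 = float(freqs.min()) if f0 is None else f0
    return CYCLES_BASE + CYCLES_EXPANSION * (freqs / f0 - 1.0)


def morlet_wavelet(freq: float, cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, unit energy, truncated at +/-2.5 sigma_t."""
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(WAVELET_TRUNCATION_SD * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-0.5 * (t / sigma_t) ** 2)
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_coefficients(
    ep: EpochSet,
    freqs: np.ndarray | None = None,
    channels: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complex Morlet coefficients for the kept trials of an epoch set.

    Returns (coefs, freqs, valid): coefs is trials x freqs x times x channels,
    valid is freqs x times and is False where the wavelet support overlaps an
    epoch edge (the whole row may be False for very low frequencies on short
    epochs).
    """
    freqs = log_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.max() >= ep.fs / 2:
        raise ValueError("maximum analysis frequency must be below Nyquist")
    if channels is None:
        channels = list(ep.labels)
    ch_idx = [ep.channel_index(c) for c in channels]
    kept = ep.kept()
    data = ep.data[kept][:, ch_idx, :]  # trials x channels x time
    n_t = data.shape[2]
    cycles = n_cycles(freqs)
    coefs = np.empty((data.shape[0], freqs.size, n_t, len(ch_idx)), dtype=complex)
    valid = np.zeros((freqs.size, n_t), dtype=bool)
    for fi, (f, c) in enumerate(zip(freqs, cycles)):
        w = morlet_wavelet(f, c, ep.fs)
        half = (len(w) - 1) // 2
        conv = spsig.fftconvolve(data, w[None, None, :], mode="same", axes=2)
        coefs[:, fi, :, :] = np.moveaxis(conv, 1, 2)
        if n_t > 2 * half:
            valid[fi, half:n_t - half] = True
    return coefs, freqs, valid


def ersp(
    coefs: np.ndarray,
    times_ms: np.ndarray,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-related spectral perturbation in dB.

    ERSP(f, t, ch) = 10 log10( mean_trials |W|^2 / baseline(f, ch) ) where the
    baseline is the mean trial-mean power over pre-stimulus samples.  Edge-
    valid baseline samples are used when any exist at a given frequency;
    otherwise all baseline samples are used and that frequency is flagged in
    the returned ``degraded`` vector.  Frequencies with zero baseline power
    come back as NaN.
    """
    power = np.mean(np.abs(coefs) ** 2, axis=0)  # freq x time x ch
    bmask = (times_ms >= baseline_ms[0] - 1e-9) & (times_ms <= baseline_ms[1] + 1e-9)
    if not bmask.any():
        raise ValueError("baseline window outside the epoch")
    n_f = power.shape[0]
    degraded = np.zeros(n_f, dtype=bool)
    out = np.full_like(power, np.nan)
    for fi in range(n_f):
        use = bmask.copy()
        if valid is not None:
            if (bmask & valid[fi]).any():
                use = bmask & valid[fi]
            else:
                degraded[fi] = True
        base = power[fi][use].mean(axis=0)  # per channel
        ok = base > 0
        out[fi][:, ok] = 10.0 * np.log10(power[fi][:, ok] / base[ok])
    return out, degraded


def itc(coefs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inter-trial coherence: |trial mean of unit-normalized coefficients|.

    Zero-magnitude coefficients are excluded bin-wise; bins where every trial
    is zero come back NaN.  Returns (itc_map, n_excluded_per_bin).
    """
    if coefs.shape[0] < 2:
        raise ValueError("ITC requires at least two trials")
    mag = np.abs(coefs)
    nonzero = mag > 0
    unit = np.zeros_like(coefs)
    np.divide(coefs, mag, out=unit, where=nonzero)
    counts = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore"):
        itc_map = np.abs(unit.sum(axis=0)) / counts
    itc_map[counts == 0] = np.nan
    n_excluded = coefs.shape[0] - counts
    return itc_map, n_excluded


def permutation_significance(
    power_a: np.ndarray,
    power_b: np.ndarray,
    n_perm: int = 500,
    q: float = 0.05,
    seed: int = 0,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Condition-difference significance mask via label permutation + BH-FDR.

    Inputs are trial-level power maps (trials x freq x time [...]).  Per bin,
    the statistic is the difference of trial means; the two-sided permutation
    p (add-one convention) is corrected across bins with Benjamini-Hochberg
    at level ``q``.  Deterministic given ``seed``.
    """
    if power_a.shape[0] < 2 or power_b.shape[0] < 2:
        raise ValueError("need at least two trials per condition")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value grid", stacklevel=2)
    map_shape = power_a.shape[1:]
    a = power_a.reshape(power_a.shape[0], -1)
    b = power_b.reshape(power_b.shape[0], -1)
    n_a = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    observed = np.abs(a.mean(axis=0) - b.mean(axis=0))
    rng = np.random.default_rng(seed)
    count = np.zeros(pooled.shape[1], dtype=int)
    for _ in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        diff = pooled[idx[:n_a]].mean(axis=0) - pooled[idx[n_a:]].mean(axis=0)
        count += np.abs(diff) >= observed
    pvals = (1 + count) / (1 + n_perm)

    if valid is not None:
        flat_valid = np.broadcast_to(
            valid.reshape(valid.shape + (1,) * (len(map_shape) - valid.ndim)),
            map_shape,
        ).reshape(-1)
    else:
        flat_valid = np.ones(pvals.size, dtype=bool)
    mask = np.zeros(pvals.size, dtype=bool)
    if flat_valid.any():
        fdr = bh_fdr(pvals[flat_valid], q=q)
        mask[np.nonzero(flat_valid)[0]] = fdr.reject
    return mask.reshape(map_shape)


def compute_tf(
    ep: EpochSet,
    channels: list[str],
    freqs: np.ndarray | None = None,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
) -> TFResult:
    """ERSP and ITC maps for the requested channels of an epoch set."""
    coefs, freqs, valid = morlet_coefficients(ep, freqs, channels)
    ersp_map, degraded = ersp(coefs, ep.times_ms, baseline_ms, valid)
    itc_map, _ = itc(coefs)
    return TFResult(freqs=freqs, times_ms=ep.times_ms, ersp=ersp_map,
                    itc=itc_map, labels=list(channels), valid=valid,
                    n_trials=int(ep.kept().sum()), baseline_degraded=degraded)
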