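"""Event-related potentials: condition averages, P300 peaks, paired statistics."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .containers import EpochSet, ErpSummary, PeakMeasure, StatTestResult
from .stats import paired_t, t_quantile


def average_erp(ep: EpochSet, conditions=None) -> ErpSummary:
    """Trial-mean waveform per condition, using kept trials only."""
    if conditions is None:
        conditions = list(dict.fromkeys(ep.condition.tolist()))
    waveforms, counts = {}, {}
    for cond in conditions:
        mask = ep.kept(cond)
        if not mask.any():
            raise ValueError(f"no kept trials in condition {cond!r}")
        waveforms[cond] = ep.data[mask].mean(axis=0)
        counts[cond] = int(mask.sum())
    return ErpSummary(waveforms=waveforms, n_trials=counts,
                      labels=list(ep.labels), times_ms=ep.times_ms)


def measure_p300(
    erp: ErpSummary,
    condition: str,
    channel: str = "Pz",
    window_ms: tuple[float, float] = (250.0, 500.0),
) -> PeakMeasure:
    """Largest positive deflection at ``channel`` inside the search window.

    The peak is a simple maximum (ties resolved to the earliest sample); a
    strictly negative window still returns its maximum, flagged as
    low-amplitude.
    """
    t = erp.times_ms
    mask = (t >= window_ms[0] - 1e-9) & (t <= window_ms[1] + 1e-9)
    if not mask.any():
        raise ValueError("search window lies outside the epoch time axis")
    wave = erp.waveforms[condition][erp.labels.index(channel)][mask]
    idx = int(np.argmax(wave))  # argmax returns the first maximum
    return PeakMeasure(
        amplitude=float(wave[idx]),
        latency_ms=float(t[mask][idx]),
        channel=channel,
        window_ms=window_ms,
        low_amplitude=bool(wave[idx] <= 0),
    )


def paired_compare(values_a, values_b, level: float = 0.95) -> StatTestResult:
    """Paired t-test with Cohen's d = mean(diff)/sd(diff) and a CI of the mean
    difference.  Zero-variance differences give a capped infinite t."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    t, df, p = paired_t(a, b)
    diff = a - b
    sd = diff.std(ddof=1)
    n = diff.size
    d = diff.mean() / sd if sd > 0 else (0.0 if diff.mean() == 0 else np.inf)
    capped = not np.isfinite(t)
    if sd > 0:
        half = t_quantile((1 + level) / 2, df) * sd / np.sqrt(n)
        ci = (diff.mean() - half, diff.mean() + half)
    else:
        ci = (diff.mean(), diff.mean())
    return StatTestResult(statistic=t, df=df, p_value=p, effect_size=float(d),
                          ci_low=float(ci[0]), ci_high=float(ci[1]),
                          test_name="paired t-test", capped=capped)


def ci_mean(values, level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval for a sample mean: m +/- t * sd / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("confidence interval requires n >= 2")
    m, sd, n = x.mean(), x.std(ddof=1), x.size
    if sd == 0:
        return float(m), float(m)
    half = t_quantile((1 + level) / 2, n - 1) * sd / np.sqrt(n)
    return float(m - half), float(m + half)


def ci_mean_from_summary(mean: float, sd: float, n: int,
                         level: float = 0.95) -> tuple[float, float]:
    """Same t-interval computed from summary statistics (mean, sd, n)."""
    if n < 2:
        raise ValueError("confidence interval requires n >= 2")
    half = t_quantile((1 + level) / 2, n - 1) * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def topo_snapshot(erp: ErpSummary, condition: str, t_ms: float) -> dict[str, float]:
    """Per-channel amplitude map at the sample nearest to ``t_ms``.

    Ties between two equidistant samples resolve toward the earlier one.
    The map is returned as a plain channel -> microvolt table.
    """
    t = erp.times_ms
    if t_ms < t[0] - 1e-9 or t_ms > t[-1] + 1e-9:
        raise ValueError("requested time lies outside the epoch")
    dist = np.abs(t - t_ms)
    idx = int(np.argmin(dist))  # argmin picks the first (earlier) of a tie
    wave = erp.waveforms[condition]
    return {label: float(wave[i, idx]) for i, label in enumerate(erp.labels)}


def correlation_with_experience(x, y) -> StatTestResult:
    """Pearson correlation with the exact t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return StatTestResult(statistic=float(r), df=x.size - 2, p_value=float(p),
                          test_name="pearson r")
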