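"""Synthetic auditory-oddball EEG with meditation/task state structure.

Emulates the structure of a 13-participant oddball study: three 13-minute
sessions per recording with 750 tones (standard / oddball / white-noise
distractor), 10-20 scalp EEG plus an ocular channel, 1/f background noise,
band-limited oscillators whose power depends on cognitive state (frontal
alpha/beta up and central theta down during meditation), a parietal-dominant
P300-like deflection that is larger for oddball tones, an across-subject
coupling between meditation experience and alpha amplitude, and blink
artifacts mirrored on the EOG channel.

Every component of the forward model is exposed (``return_parts=True``) so
white-box tests can verify that the emitted signal is exactly the sum of its
generative parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .containers import (
    BANDS,
    DEFAULT_MONTAGE,
    EOG_LABEL,
    EVENT_TYPES,
    Recording,
    events_dataframe,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ParadigmConfig:
    """Auditory oddball paradigm: 3 sessions x 250 tones, jittered ~3 s SOA.

    The standard/oddball/distractor split (70/15/15) and the stimulus-onset
    asynchrony are conventions chosen so 250 tones fit a 13-minute session;
    the source protocol does not state them.
    """

    n_sessions: int = 3
    session_minutes: float = 13.0
    tones_per_session: int = 250
    proportions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    soa_mean: float = 3.0
    soa_jitter: float = 0.3
    start_offset: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("tone-type proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be non-negative")
        if self.soa_mean - self.soa_jitter <= 0:
            raise ValueError("jitter would allow a non-positive SOA")
        if self.n_sessions < 1 or self.tones_per_session < 1:
            raise ValueError("need at least one session and one tone")

    @property
    def session_seconds(self) -> float:
        return self.session_minutes * 60.0


@dataclass
class SubjectProfile:
    """One participant: meditation experience and their trait alpha gain.

    ``alpha_gain`` multiplies the alpha-band oscillator amplitude and is
    constructed as base + slope * experience_years + noise, which plants the
    positive experience-alpha coupling the analysis is meant to recover.
    """

    subject_id: str
    experience_years: float
    alpha_gain: float
    seed: int

    @property
    def experience_level(self) -> str:
        if self.experience_years < 1.0:
            return "novice"
        if self.experience_years < 5.0:
            return "intermediate"
        return "experienced"


#: Parietal-dominant topography of the stimulus-evoked positivity.
ERP_TOPOGRAPHY: dict[str, float] = {
    "Pz": 1.0, "P3": 0.8, "P4": 0.8, "Cz": 0.7, "C3": 0.5, "C4": 0.5,
    "Fz": 0.4, "F3": 0.3, "F4": 0.3, "Oz": 0.5, EOG_LABEL: 0.0,
}

#: Frontal-dominant scalp projection of ocular (blink) activity.
BLINK_TOPOGRAPHY: dict[str, float] = {
    "Fz": 0.50, "F3": 0.40, "F4": 0.40, "Cz": 0.20, "C3": 0.15, "C4": 0.15,
    "Pz": 0.05, "P3": 0.05, "P4": 0.05, "Oz": 0.02, EOG_LABEL: 1.0,
}


@dataclass
class SignalModelConfig:
    """Forward model parameters (amplitudes in microvolts RMS unless noted)."""

    fs: float = 256.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    noise_exponent: float = 1.0  # 1/f^beta slope of the background
    noise_scale: float = 10.0  # RMS of the 1/f background per channel
    sensor_noise: float = 1.0  # white sensor noise RMS
    background_scale: float = 1.0  # global multiplier on all non-ERP parts
    band_amplitudes: dict = field(
        default_factory=lambda: {"theta": 3.0, "alpha": 4.0, "beta": 2.0}
    )
    p300_amp_oddball: float = 10.0
    p300_amp_standard: float = 2.0
    p300_amp_distractor: float = 1.0
    p300_latency_ms: float = 350.0
    p300_width_ms: float = 120.0  # full width at half maximum
    meditation_alpha_boost: float = 1.5
    meditation_beta_boost: float = 1.3
    meditation_theta_drop: float = 0.7
    coherence_alpha_uv: float = 5.0  # shared Fz/Pz alpha source, meditation only
    task_theta_burst_uv: float = 3.0  # Cz theta burst, task state only
    task_theta_burst_window_ms: tuple[float, float] = (150.0, 300.0)
    blink_rate_per_min: float = 4.0
    blink_amp_uv: float = 120.0

    def validate(self) -> None:
        if self.fs <= 2 * BANDS["beta"][1]:
            raise ValueError("fs must exceed twice the beta-band upper edge")
        if self.p300_amp_oddball <= self.p300_amp_standard:
            raise ValueError("oddball P300 amplitude must exceed standard")
        for label in self.montage:
            if label != EOG_LABEL and label not in ERP_TOPOGRAPHY:
                raise ValueError(f"unknown channel label {label!r}")


# ---------------------------------------------------------------------------
# Paradigm
# ---------------------------------------------------------------------------


def largest_remainder_counts(proportions, total: int) -> list[int]:
    """Integer counts by the largest-remainder method.

    Ties in the fractional remainders are broken by position (earlier entry
    wins), so with (0.70, 0.15, 0.15) and 250 tones the leftover tone goes to
    the second entry: 175/38/37.
    """
    raw = [p * total for p in proportions]
    counts = [math.floor(r) for r in raw]
    shortfall = total - sum(counts)
    remainders = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def generate_paradigm(cfg: ParadigmConfig) -> pd.DataFrame:
    """Generate the event table: one row per tone, onsets in seconds.

    Onsets are global (session k is offset by k session lengths); types are a
    seeded shuffle of the per-session largest-remainder counts; consecutive
    onsets differ by soa_mean + U(-jitter, +jitter).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    onsets, types, sessions = [], [], []
    counts = largest_remainder_counts(cfg.proportions, cfg.tones_per_session)
    for sess in range(cfg.n_sessions):
        seq = np.repeat(EVENT_TYPES, counts)
        rng.shuffle(seq)
        soas = cfg.soa_mean + rng.uniform(
            -cfg.soa_jitter, cfg.soa_jitter, size=cfg.tones_per_session - 1
        )
        rel = cfg.start_offset + np.concatenate([[0.0], np.cumsum(soas)])
        if rel[-1] + 1.0 > cfg.session_seconds:
            raise ValueError("tones do not fit inside the session length")
        onsets.extend(rel + sess * cfg.session_seconds)
        types.extend(seq.tolist())
        sessions.extend([sess] * cfg.tones_per_session)
    return events_dataframe(onsets, types, sessions)


# ---------------------------------------------------------------------------
# Signal components
# ---------------------------------------------------------------------------


def powerlaw_noise(n: int, beta: float, rng: np.random.Generator,
                   size: int = 1) -> np.ndarray:
    """1/f^beta noise via spectral shaping, unit RMS per row (size x n)."""
    white = rng.standard_normal((size, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms


def _narrowband(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Band-limited Gaussian noise, unit RMS per row."""
    white = rng.standard_normal((size, n))
    sos = spsig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    out = spsig.sosfiltfilt(sos, white, axis=1)
    rms = out.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return out / rms


def _gaussian_kernel(t: np.ndarray, center_s: float, fwhm_s: float) -> np.ndarray:
    sigma = fwhm_s / 2.3548200450309493
    return np.exp(-0.5 * ((t - center_s) / sigma) ** 2)


def generate_recording(
    profile: SubjectProfile,
    events: pd.DataFrame,
    state: str,
    sig: SignalModelConfig | None = None,
    duration_s: float | None = None,
    return_parts: bool = False,
):
    """Simulate one continuous recording for a subject in one state.

    state is "meditation" or "task".  The same tone stream is presented in
    both states; what differs is the oscillatory regime (frontal alpha/beta
    boosted and central theta suppressed in meditation, plus a shared Fz/Pz
    alpha source driving inter-site coherence) and a task-only central theta
    burst after each tone.  Deterministic given (profile.seed, state).
    """
    if state not in ("meditation", "task"):
        raise ValueError("state must be 'meditation' or 'task'")
    sig = sig or SignalModelConfig()
    sig.validate()
    if duration_s is None:
        duration_s = float(events["onset"].max()) + 2.0
    n = int(round(duration_s * sig.fs))
    labels = list(sig.montage)
    n_ch = len(labels)
    t = np.arange(n) / sig.fs
    state_code = 1 if state == "meditation" else 0
    root = np.random.default_rng(
        np.random.SeedSequence(entropy=int(profile.seed) % (2**31),
                               spawn_key=(state_code,))
    )
    noise_rng, osc_rng, shared_rng, burst_rng, blink_rng, sensor_rng = root.spawn(6)

    eeg_mask = np.array([l != EOG_LABEL for l in labels])

    # 1/f background + white sensor noise
    noise = sig.noise_scale * powerlaw_noise(n, sig.noise_exponent, noise_rng, n_ch)
    noise[~eeg_mask] *= 0.2  # ocular channel is dominated by ocular activity
    noise += sig.sensor_noise * sensor_rng.standard_normal((n_ch, n))

    # band-limited oscillators with site/state/trait amplitude structure
    frontal = {"Fz", "F3", "F4"}
    central = {"Cz", "C3", "C4"}
    osc = np.zeros((n_ch, n))
    for band_name in ("theta", "alpha", "beta"):  # fixed draw order
        base = sig.band_amplitudes[band_name]
        comp = _narrowband(n, sig.fs, BANDS[band_name], osc_rng, n_ch)
        amp = np.full(n_ch, base)
        for i, label in enumerate(labels):
            if label == EOG_LABEL:
                amp[i] = 0.3 * base
                continue
            if band_name == "alpha":
                amp[i] *= profile.alpha_gain
                if state == "meditation" and label in frontal:
                    amp[i] *= sig.meditation_alpha_boost
            elif band_name == "beta":
                if state == "meditation" and label in frontal:
                    amp[i] *= sig.meditation_beta_boost
            elif band_name == "theta":
                if state == "meditation" and label in central:
                    amp[i] *= sig.meditation_theta_drop
        osc += amp[:, None] * comp

    # shared alpha source into Fz and Pz (meditation only); always drawn so
    # the downstream random streams do not depend on the state
    shared = _narrowband(n, sig.fs, BANDS["alpha"], shared_rng, 1)[0]
    if state == "meditation" and sig.coherence_alpha_uv > 0:
        for label in ("Fz", "Pz"):
            if label in labels:
                osc[labels.index(label)] += sig.coherence_alpha_uv * shared

    # stimulus-evoked positivity: Gaussian-windowed, parietal-dominant
    amp_by_type = {
        "standard": sig.p300_amp_standard,
        "oddball": sig.p300_amp_oddball,
        "distractor": sig.p300_amp_distractor,
    }
    erp_single = np.zeros(n)
    for onset, ttype in zip(events["onset"], events["trial_type"]):
        center = onset + sig.p300_latency_ms / 1000.0
        lo = int((center - 0.4) * sig.fs)
        hi = int((center + 0.4) * sig.fs)
        lo, hi = max(lo, 0), min(hi, n)
        if hi <= lo:
            continue
        erp_single[lo:hi] += amp_by_type[ttype] * _gaussian_kernel(
            t[lo:hi], center, sig.p300_width_ms / 1000.0
        )
    topo = np.array([ERP_TOPOGRAPHY[l] for l in labels])
    erp = topo[:, None] * erp_single[None, :]

    # transient central theta burst after each tone (task state only)
    burst_phases = burst_rng.uniform(0, 2 * np.pi, size=len(events))
    burst = np.zeros((n_ch, n))
    if state == "task" and sig.task_theta_burst_uv > 0:
        w_lo, w_hi = sig.task_theta_burst_window_ms
        center_off = (w_lo + w_hi) / 2000.0
        fwhm = (w_hi - w_lo) / 1000.0
        f_theta = float(np.mean(BANDS["theta"]))
        single = np.zeros(n)
        for onset, phase in zip(events["onset"], burst_phases):
            center = onset + center_off
            lo = int((center - 0.3) * sig.fs)
            hi = int((center + 0.3) * sig.fs)
            lo, hi = max(lo, 0), min(hi, n)
            if hi <= lo:
                continue
            env = _gaussian_kernel(t[lo:hi], center, fwhm)
            single[lo:hi] += np.sin(2 * np.pi * f_theta * t[lo:hi] + phase) * env
        site_w = {"Cz": 1.0, "C3": 0.5, "C4": 0.5}
        for label, w in site_w.items():
            if label in labels:
                burst[labels.index(label)] = sig.task_theta_burst_uv * w * single

    # blink artifacts: Poisson train of smooth positive transients
    blinks = np.zeros((n_ch, n))
    n_blinks = blink_rng.poisson(sig.blink_rate_per_min * duration_s / 60.0)
    blink_times = np.sort(blink_rng.uniform(0.3, duration_s - 0.3, size=n_blinks))
    if n_blinks:
        single = np.zeros(n)
        for bt in blink_times:
            lo = int((bt - 0.3) * sig.fs)
            hi = int((bt + 0.3) * sig.fs)
            lo, hi = max(lo, 0), min(hi, n)
            # ~120 ms full width at half maximum, the speed of a real blink
            single[lo:hi] += _gaussian_kernel(t[lo:hi], bt, 0.12)
        proj = np.array([BLINK_TOPOGRAPHY[l] for l in labels])
        blinks = sig.blink_amp_uv * proj[:, None] * single[None, :]

    parts = {
        "noise": sig.background_scale * noise,
        "oscillations": sig.background_scale * osc,
        "erp": erp,
        "theta_burst": sig.background_scale * burst,
        "blinks": sig.background_scale * blinks,
    }
    data = sum(parts.values())
    rec = Recording(labels=labels, fs=sig.fs, data=data,
                    history=[f"simulate[{profile.subject_id},{state}]"])
    if return_parts:
        return rec, parts
    return rec


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

#: Years of regular practice for the default 13-subject cohort
#: (5 experienced, 3 intermediate, 5 novice; novices coded as 0.5 y).
DEFAULT_EXPERIENCE_YEARS: tuple[float, ...] = (
    8, 0.5, 3, 6, 10, 0.5, 2, 5, 0.5, 0.5, 15, 3, 0.5,
)

ALPHA_GAIN_BASE = 1.0
ALPHA_GAIN_SLOPE = 0.02
ALPHA_GAIN_NOISE_SD = 0.15


def make_profiles(
    n_subjects: int = 13,
    master_seed: int = 0,
    experience_years=None,
    alpha_slope: float = ALPHA_GAIN_SLOPE,
    alpha_noise_sd: float = ALPHA_GAIN_NOISE_SD,
) -> list[SubjectProfile]:
    """Build subject profiles with the planted experience-alpha coupling."""
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(master_seed) % (2**31), spawn_key=(101,)))
    if experience_years is None:
        if n_subjects == 13:
            experience_years = list(DEFAULT_EXPERIENCE_YEARS)
        else:
            experience_years = rng.choice(
                DEFAULT_EXPERIENCE_YEARS, size=n_subjects, replace=True
            ).tolist()
    profiles = []
    for i, years in enumerate(experience_years):
        gain = ALPHA_GAIN_BASE + alpha_slope * years + alpha_noise_sd * rng.standard_normal()
        gain = max(gain, 0.1)
        profiles.append(
            SubjectProfile(
                subject_id=f"sub-{i + 1:03d}",
                experience_years=float(years),
                alpha_gain=float(gain),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


@dataclass
class CohortBundle:
    """Everything the analysis consumes: profiles, events, both-state recordings."""

    profiles: list[SubjectProfile]
    events: dict[str, pd.DataFrame]
    recordings: dict[tuple[str, str], Recording]
    paradigm: ParadigmConfig
    signal: SignalModelConfig

    @property
    def states(self) -> tuple[str, str]:
        return ("meditation", "task")


def generate_cohort(
    n_subjects: int = 13,
    paradigm: ParadigmConfig | None = None,
    signal_cfg: SignalModelConfig | None = None,
    master_seed: int = 0,
    experience_years=None,
) -> CohortBundle:
    """Simulate the full cohort: per-subject events and both-state recordings."""
    paradigm = paradigm or ParadigmConfig()
    signal_cfg = signal_cfg or SignalModelConfig()
    profiles = make_profiles(n_subjects, master_seed, experience_years)
    events: dict[str, pd.DataFrame] = {}
    recordings: dict[tuple[str, str], Recording] = {}
    duration = paradigm.n_sessions * paradigm.session_seconds
    for i, prof in enumerate(profiles):
        pcfg = ParadigmConfig(**{**asdict(paradigm),
                                 "seed": (paradigm.seed + 7919 * (i + 1)) % (2**31)})
        ev = generate_paradigm(pcfg)
        events[prof.subject_id] = ev
        for state in ("meditation", "task"):
            recordings[(prof.subject_id, state)] = generate_recording(
                prof, ev, state, signal_cfg, duration_s=duration
            )
    return CohortBundle(profiles=profiles, events=events, recordings=recordings,
                        paradigm=paradigm, signal=signal_cfg)


# ---------------------------------------------------------------------------
# Writers (BIDS-style events.tsv + JSON sidecars)
# ---------------------------------------------------------------------------


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def write_profiles_json(profiles: list[SubjectProfile], path) -> None:
    payload = [
        {
            "subject_id": p.subject_id,
            "experience_years": p.experience_years,
            "experience_level": p.experience_level,
            "alpha_gain": p.alpha_gain,
            "seed": p.seed,
        }
        for p in profiles
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
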