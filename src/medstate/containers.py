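"""Shared domain containers for the EEG analysis pipeline.

The containers are deliberately thin: numpy arrays with labelled axes and a
little bookkeeping (processing history, kept-trial masks), in the spirit of
an EEGLAB EEG struct rather than a full-blown framework object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Default 10-20 montage used throughout: ten EEG sites plus one ocular channel.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fz", "Cz", "Pz", "F3", "F4", "C3", "C4", "P3", "P4", "Oz", "EOG",
)

EOG_LABEL = "EOG"

#: Approximate unit-sphere positions (x = right, y = anterior, z = superior)
#: for the 10-20 sites of the default montage.  Only relative distances matter
#: (bad-channel interpolation); these are the textbook spherical placements.
CHANNEL_POSITIONS: dict[str, tuple[float, float, float]] = {
    "Cz": (0.0, 0.0, 1.0),
    "Fz": (0.0, 0.5878, 0.8090),
    "Pz": (0.0, -0.5878, 0.8090),
    "Oz": (0.0, -0.9511, 0.3090),
    "C3": (-0.5878, 0.0, 0.8090),
    "C4": (0.5878, 0.0, 0.8090),
    "F3": (-0.5450, 0.6730, 0.5000),
    "F4": (0.5450, 0.6730, 0.5000),
    "P3": (-0.5450, -0.6730, 0.5000),
    "P4": (0.5450, -0.6730, 0.5000),
    "EOG": (0.0, 0.9511, -0.3090),
}

#: Canonical EEG frequency bands in Hz (gamma is deliberately excluded).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

#: Scalp-region groupings used for band-power and entropy summaries.
SITES: dict[str, tuple[str, ...]] = {
    "frontal": ("Fz", "F3", "F4"),
    "central": ("Cz", "C3", "C4"),
    "parietal": ("Pz", "P3", "P4"),
}

EVENT_TYPES = ("standard", "oddball", "distractor")


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts.

    ``data`` is channels x samples; ``labels`` names the rows.  ``history``
    is append-only and records every processing step applied.
    """

    labels: list[str]
    fs: float
    data: np.ndarray
    reference: str = "raw"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be channels x samples matching labels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def eeg_indices(self, eog_label: str = EOG_LABEL) -> np.ndarray:
        """Indices of scalp EEG channels (everything except the EOG)."""
        return np.array([i for i, l in enumerate(self.labels) if l != eog_label])

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def copy_with(self, data: np.ndarray, step: str, **kw) -> "Recording":
        rec = Recording(
            labels=list(self.labels),
            fs=self.fs,
            data=data,
            reference=kw.get("reference", self.reference),
            history=self.history + [step],
        )
        return rec


@dataclass
class EpochSet:
    """Trials x channels x time epochs on a -200..+800 ms axis."""

    data: np.ndarray
    labels: list[str]
    fs: float
    times_ms: np.ndarray
    condition: np.ndarray
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    kept_mask: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def kept(self, condition: str | None = None) -> np.ndarray:
        """Boolean mask of kept trials, optionally restricted to a condition."""
        mask = self.kept_mask.copy()
        if condition is not None:
            mask &= self.condition == condition
        return mask

    def channel_index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class IcaReport:
    n_components: int
    rejected: list[int]
    scores: np.ndarray
    notes: str = ""


@dataclass
class ErpSummary:
    """Per-condition trial-mean waveforms (channels x time, microvolts)."""

    waveforms: dict[str, np.ndarray]
    n_trials: dict[str, int]
    labels: list[str]
    times_ms: np.ndarray


@dataclass
class PeakMeasure:
    amplitude: float
    latency_ms: float
    channel: str
    window_ms: tuple[float, float]
    low_amplitude: bool = False


@dataclass
class StatTestResult:
    statistic: float
    df: float
    p_value: float
    effect_size: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    test_name: str = ""
    capped: bool = False

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": None if self.statistic is None else float(self.statistic),
            "df": float(self.df),
            "p_value": float(self.p_value),
            "effect_size": None if self.effect_size is None else float(self.effect_size),
            "ci_low": None if self.ci_low is None else float(self.ci_low),
            "ci_high": None if self.ci_high is None else float(self.ci_high),
        }


@dataclass
class Psd:
    freqs: np.ndarray
    power: np.ndarray  # channels x freqs (or 1 x freqs), uV^2/Hz
    labels: list[str]
    seg_len_s: float
    overlap: float
    window: str = "hann"


@dataclass
class TFResult:
    """Morlet ERSP/ITC maps over a log-spaced 3-40 Hz axis."""

    freqs: np.ndarray
    times_ms: np.ndarray
    ersp: np.ndarray  # freq x time x channel, dB
    itc: np.ndarray  # freq x time x channel, [0, 1]
    labels: list[str]
    valid: np.ndarray  # freq x time, False inside wavelet edge regions
    sig_mask: np.ndarray | None = None
    n_trials: int = 0
    baseline_degraded: np.ndarray | None = None  # per-freq flag


@dataclass
class FdrResult:
    pvals: np.ndarray
    q: float
    reject: np.ndarray
    p_threshold: float


@dataclass
class CvReport:
    scheme: str
    accuracy: float
    f1: float
    roc_auc: float
    per_fold: list[dict]
    selected_features: list[list[str]]
    importance: list[tuple[str, float]]
    seed: int

    def as_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "accuracy": float(self.accuracy),
            "f1": float(self.f1),
            "roc_auc": float(self.roc_auc),
            "per_fold": self.per_fold,
            "selected_features": self.selected_features,
            "importance": [[n, float(v)] for n, v in self.importance],
            "seed": int(self.seed),
        }


def events_dataframe(onsets: Sequence[float], types: Sequence[str],
                     sessions: Sequence[int], duration: float = 0.1) -> pd.DataFrame:
    """Assemble a BIDS-style events table (onset/duration/trial_type/session)."""
    return pd.DataFrame(
        {
            "onset": np.asarray(onsets, dtype=float),
            "duration": float(duration),
            "trial_type": list(types),
            "session": np.asarray(sessions, dtype=int),
        }
    )
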