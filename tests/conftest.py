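import warnings

import numpy as np
import pytest

import medstate as m

warnings.filterwarnings("ignore", message=".*did not converge.*")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_paradigm() -> m.ParadigmConfig:
    """One 3-minute session of 50 tones: enough oddballs for stable averages."""
    return m.ParadigmConfig(n_sessions=1, session_minutes=3.0,
                            tones_per_session=50, seed=11)


@pytest.fixture(scope="session")
def small_events(small_paradigm):
    return m.generate_paradigm(small_paradigm)


@pytest.fixture(scope="session")
def profile():
    return m.SubjectProfile(subject_id="sub-001", experience_years=3.0,
                            alpha_gain=1.0, seed=424242)


@pytest.fixture(scope="session")
def task_recording(profile, small_events):
    sig = m.SignalModelConfig(fs=128.0)
    return m.generate_recording(profile, small_events, "task", sig,
                                duration_s=180.0)


@pytest.fixture(scope="session")
def task_epochs(task_recording, small_events):
    from medstate.preprocess import epoch

    return epoch(task_recording, small_events)


def scaled_run_config(seed: int) -> "m.RunConfig":
    """Desk-scale pipeline configuration: 13 subjects, one 90-second session
    of 26 tones at 128 Hz.  Generator effect sizes stay at their defaults;
    only recording length, sampling rate and per-run extras (ICA, the
    single-subject time-frequency maps, importance repeats) are reduced so
    repeated seeded runs fit the compute budget.  The classifier protocol
    itself (100 trees, depth 10, RFE to 10, grouped fivefold + LOSO) is
    untouched."""
    return m.RunConfig(
        n_subjects=13, n_sessions=1, session_minutes=1.5,
        tones_per_session=26, fs=128.0, n_freqs=15, n_perm=200,
        run_ica=False, run_timefreq=False, importance_repeats=2, seed=seed,
    )
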