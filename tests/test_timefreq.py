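"""Morlet decomposition, ERSP/ITC maps, permutation-FDR significance."""

import numpy as np
import pytest

from medstate.containers import EpochSet
from medstate.timefreq import (
    ersp,
    itc,
    log_freqs,
    morlet_coefficients,
    n_cycles,
    permutation_significance,
)

FS = 128.0
N_T = 129  # -200..+800 ms at 128 Hz


def make_epochs(trials):
    trials = np.asarray(trials, float)
    if trials.ndim == 2:
        trials = trials[:, None, :]
    times = (np.arange(trials.shape[2]) - int(0.2 * FS)) / FS * 1000.0
    return EpochSet(data=trials, labels=[f"ch{i}" for i in range(trials.shape[1])],
                    fs=FS, times_ms=times,
                    condition=np.array(["oddball"] * trials.shape[0]))


def sinusoid_trials(freq, n_trials, phases=None, rng=None):
    t = np.arange(N_T) / FS
    if phases is None:
        phases = np.zeros(n_trials)
    return np.stack([np.sin(2 * np.pi * freq * t + ph) for ph in phases])


class TestMorlet:
    def test_frequency_axis_is_log_spaced(self):
        f = log_freqs()
        assert f[0] == pytest.approx(3.0) and f[-1] == pytest.approx(40.0)
        ratios = f[1:] / f[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-9)

    def test_cycle_count_grows_linearly_from_three(self):
        f = log_freqs()
        c = n_cycles(f)
        assert c[0] == pytest.approx(3.0)
        assert c[-1] == pytest.approx(3.0 + 0.5 * (40.0 / 3.0 - 1.0))
        assert np.all(np.diff(c) > 0)

    def test_pure_tone_peaks_at_nearest_frequency_bin(self):
        ep = make_epochs(sinusoid_trials(10.0, 1))
        coefs, freqs, valid = morlet_coefficients(ep)
        mid = N_T // 2
        profile = np.abs(coefs[0, :, mid, 0])
        assert np.argmax(profile) == np.argmin(np.abs(freqs - 10.0))

    def test_zero_signal_gives_zero_coefficients(self):
        ep = make_epochs(np.zeros((2, N_T)))
        coefs, _, _ = morlet_coefficients(ep)
        assert np.all(coefs == 0)

    def test_linearity_under_amplitude_doubling(self):
        base = sinusoid_trials(10.0, 1)
        c1, _, _ = morlet_coefficients(make_epochs(base))
        c2, _, _ = morlet_coefficients(make_epochs(2 * base))
        assert np.allclose(np.abs(c2), 2 * np.abs(c1))

    def test_supra_nyquist_frequency_rejected(self):
        ep = make_epochs(np.zeros((1, N_T)))
        with pytest.raises(ValueError):
            morlet_coefficients(ep, np.array([80.0]))


class TestErsp:
    def test_stationary_trials_stay_within_one_db(self):
        # enough trials (relative SE of the trial-mean power ~ 1/sqrt(n)) and
        # a long baseline so the whole map stays inside +/-1 dB
        rng = np.random.default_rng(0)
        n_t = 2 * N_T - 1
        trials = rng.normal(size=(512, n_t))
        times = (np.arange(n_t) - 64) / FS * 1000.0
        ep = EpochSet(data=trials[:, None, :], labels=["ch0"], fs=FS,
                      times_ms=times,
                      condition=np.array(["oddball"] * trials.shape[0]))
        coefs, freqs, valid = morlet_coefficients(ep, log_freqs(8, 30, 6))
        emap, degraded = ersp(coefs, ep.times_ms, baseline_ms=(-500.0, 0.0),
                              valid=valid)
        assert np.nanmax(np.abs(emap[valid])) < 1.0

    def test_injected_burst_produces_localized_positive_ersp(self):
        rng = np.random.default_rng(1)
        t = np.arange(N_T) / FS - 0.2
        burst_win = (t >= 0.3) & (t <= 0.6)
        trials = rng.normal(0, 0.5, size=(40, N_T))
        for k in range(40):
            trials[k, burst_win] += 3 * np.sin(
                2 * np.pi * 10 * t[burst_win] + rng.uniform(0, 2 * np.pi))
        ep = make_epochs(trials)
        freqs = log_freqs(6, 20, 7)
        coefs, freqs, valid = morlet_coefficients(ep, freqs)
        emap, _ = ersp(coefs, ep.times_ms, valid=valid)
        fi = int(np.argmin(np.abs(freqs - 10)))
        in_win = (ep.times_ms >= 350) & (ep.times_ms <= 550)
        pre_win = (ep.times_ms >= -100) & (ep.times_ms <= 100)
        assert np.nanmean(emap[fi, in_win, 0]) > 3.0
        assert np.nanmean(emap[fi, in_win, 0]) > np.nanmean(emap[fi, pre_win, 0]) + 3.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        trials = rng.normal(size=(20, N_T))
        ep1, ep2 = make_epochs(trials), make_epochs(5 * trials)
        f = log_freqs(8, 20, 5)
        c1, _, v = morlet_coefficients(ep1, f)
        c2, _, _ = morlet_coefficients(ep2, f)
        e1, _ = ersp(c1, ep1.times_ms, valid=v)
        e2, _ = ersp(c2, ep2.times_ms, valid=v)
        assert np.allclose(e1, e2, atol=1e-9, equal_nan=True)

    def test_low_frequency_baseline_fallback_is_flagged(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.normal(size=(10, N_T)))
        coefs, freqs, valid = morlet_coefficients(ep, np.array([3.0, 20.0]))
        _, degraded = ersp(coefs, ep.times_ms, valid=valid)
        assert degraded[0]  # 3 Hz wavelet support swallows the baseline
        assert not degraded[1]


class TestEnergyProperties:
    def test_wavelet_energy_tracks_signal_power_across_trials(self):
        # Parseval-style: per-trial total wavelet energy correlates with
        # per-trial narrowband signal power
        rng = np.random.default_rng(11)
        t = np.arange(N_T) / FS
        amps = rng.uniform(0.5, 3.0, size=30)
        trials = np.stack([a * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 6))
                           for a in amps])
        ep = make_epochs(trials)
        coefs, _, valid = morlet_coefficients(ep, log_freqs(8, 12, 5))
        energy = np.abs(coefs[:, :, valid.all(axis=0), 0] ** 2).sum(axis=(1, 2))
        power = (trials**2).mean(axis=1)
        assert np.corrcoef(energy, power)[0, 1] > 0.9

    def test_summed_independent_bursts_keep_each_ersp_peak(self):
        # monotone energy: the ERSP of a sum of independent bursts is at
        # least each burst's own ERSP at its time-frequency bin
        rng = np.random.default_rng(12)
        t = np.arange(N_T) / FS - 0.2
        base = rng.normal(0, 0.5, size=(40, N_T))
        w1 = (t >= 0.1) & (t <= 0.3)
        w2 = (t >= 0.5) & (t <= 0.7)
        b1 = np.zeros_like(base)
        b2 = np.zeros_like(base)
        for k in range(40):
            b1[k, w1] = 2 * np.sin(2 * np.pi * 8 * t[w1] + rng.uniform(0, 6))
            b2[k, w2] = 2 * np.sin(2 * np.pi * 16 * t[w2] + rng.uniform(0, 6))
        freqs = np.array([8.0, 16.0])

        def ersp_of(trials):
            ep = make_epochs(trials)
            coefs, _, valid = morlet_coefficients(ep, freqs)
            emap, _ = ersp(coefs, ep.times_ms, valid=valid)
            return emap, ep.times_ms

        e1, times = ersp_of(base + b1)
        e2, _ = ersp_of(base + b2)
        esum, _ = ersp_of(base + b1 + b2)
        m1 = (times >= 150) & (times <= 250)
        m2 = (times >= 550) & (times <= 650)
        assert np.nanmean(esum[0, m1, 0]) >= np.nanmean(e1[0, m1, 0]) - 0.5
        assert np.nanmean(esum[1, m2, 0]) >= np.nanmean(e2[1, m2, 0]) - 0.5


class TestItc:
    def test_identical_trials_lock_to_one(self):
        ep = make_epochs(np.repeat(sinusoid_trials(10.0, 1), 8, axis=0))
        coefs, _, valid = morlet_coefficients(ep, np.array([10.0]))
        imap, _ = itc(coefs)
        assert np.allclose(imap[0, valid[0], 0], 1.0, atol=1e-9)

    def test_random_phases_match_unit_vector_oracle(self):
        rng = np.random.default_rng(4)
        n = 100
        ep = make_epochs(sinusoid_trials(10.0, n, rng.uniform(0, 2 * np.pi, n)))
        coefs, _, valid = morlet_coefficients(ep, np.array([10.0]))
        imap, _ = itc(coefs)
        observed = np.nanmean(imap[0, valid[0], 0])
        # Monte-Carlo oracle for E|mean of N random unit vectors|
        oracle = np.mean([
            np.abs(np.mean(np.exp(1j * np.random.default_rng(s).uniform(
                0, 2 * np.pi, n)))) for s in range(500)])
        assert observed == pytest.approx(oracle, abs=0.02)

    def test_phase_locked_burst_raises_band_itc(self):
        # long epochs so the theta wavelet has edge-valid samples well away
        # from the burst
        rng = np.random.default_rng(5)
        n_t = 2 * N_T
        t = np.arange(n_t) / FS - 0.2
        win = (t >= 0.8) & (t <= 1.0)
        trials = rng.normal(0, 0.5, size=(40, n_t))
        trials[:, win] += 2 * np.sin(2 * np.pi * 5.5 * t[win])  # same phase
        ep = make_epochs(trials)
        coefs, freqs, valid = morlet_coefficients(ep, np.array([5.5]))
        imap, _ = itc(coefs)
        in_win = (ep.times_ms >= 850) & (ep.times_ms <= 950) & valid[0]
        out_win = (ep.times_ms >= 200) & (ep.times_ms <= 450) & valid[0]
        assert np.nanmean(imap[0, in_win, 0]) > np.nanmean(imap[0, out_win, 0]) + 0.3

    def test_itc_lies_in_unit_interval(self):
        rng = np.random.default_rng(6)
        ep = make_epochs(rng.normal(size=(15, N_T)))
        coefs, _, _ = morlet_coefficients(ep, log_freqs(5, 30, 6))
        imap, _ = itc(coefs)
        assert np.nanmin(imap) >= 0.0 and np.nanmax(imap) <= 1.0

    def test_single_trial_rejected(self):
        ep = make_epochs(np.zeros((1, N_T)))
        coefs, _, _ = morlet_coefficients(ep, np.array([10.0]))
        with pytest.raises(ValueError):
            itc(coefs)


class TestPermutationSignificance:
    def _power_maps(self, rng, n_trials, shift=0.0, block=None):
        maps = rng.normal(size=(n_trials, 6, 20))
        if block is not None:
            maps[:, block[0], block[1]] += shift
        return maps

    def test_planted_block_recovered_and_elsewhere_sparse(self):
        rng = np.random.default_rng(7)
        a = self._power_maps(rng, 30, shift=3.0,
                             block=(slice(1, 3), slice(5, 10)))
        b = self._power_maps(rng, 30)
        mask = permutation_significance(a, b, n_perm=300, seed=0)
        assert mask[1:3, 5:10].mean() > 0.9
        outside = mask.copy()
        outside[1:3, 5:10] = False
        assert outside.mean() < 0.05

    def test_same_seed_same_mask(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(12, 4, 8)), rng.normal(size=(12, 4, 8))
        m1 = permutation_significance(a, b, n_perm=200, seed=5)
        m2 = permutation_significance(a, b, n_perm=200, seed=5)
        assert np.array_equal(m1, m2)

    def test_low_permutation_count_warns(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(5, 2, 3)), rng.normal(size=(5, 2, 3))
        with pytest.warns(UserWarning):
            permutation_significance(a, b, n_perm=50, seed=0)

    def test_single_trial_condition_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            permutation_significance(rng.normal(size=(1, 2, 2)),
                                     rng.normal(size=(5, 2, 2)), seed=0)
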