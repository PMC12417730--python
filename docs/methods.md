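# Methods

`medstate` analyzes EEG recorded in two cognitive states — focused meditation
and an active auditory-oddball task — and asks three questions: does the rare
("oddball") tone evoke a larger P300 than the frequent standard tone; how do
theta/alpha/beta band power, spectral entropy, inter-site coherence and
phase-locking differ between states; and can a classifier tell the states
apart from those features in held-out subjects.  Because the original
recordings are an external download, the package ships a synthetic cohort
generator that plants exactly the effect structure the analysis is meant to
recover, making every stage testable offline.

## The synthetic cohort

Each of 13 subjects (5 experienced, 3 intermediate, 5 novice meditators,
following the study's composition; novices are coded 0.5 years of practice)
is simulated in both states with the same stimulus stream: by default 3
sessions of 13 minutes, 250 tones per session (750 total), 70/15/15
standard/oddball/distractor with largest-remainder per-session rounding, and
a 3.0 ± 0.3 s jittered stimulus-onset asynchrony.  The tone-type ratio and
SOA are conventions — the source protocol states only the totals — and are
configurable.

Per channel the signal is an explicit sum of parts (exposed to white-box
tests, so `sum(parts) == signal` exactly):

- **1/f background**, spectrally shaped Gaussian noise with slope β = 1
  (checked to recover β ± 0.2 from 60-s Welch fits), 10 μV RMS, plus 1 μV
  white sensor noise.
- **Band oscillators** (theta 4–7, alpha 8–12, beta 13–30 Hz): band-passed
  Gaussian noise at 3/4/2 μV RMS.  State structure: meditation multiplies
  frontal alpha amplitude by 1.5 and frontal beta by 1.3, and central theta
  by 0.7.  A subject's trait `alpha_gain` multiplies alpha everywhere; it is
  constructed as 1 + 0.02·years + N(0, 0.15), calibrated so the sample
  correlation between practice years and alpha gain at n = 13 has median
  ≈ 0.5 (the study reports r = 0.45 for years vs. frontal alpha power).
- **A shared alpha source** (5 μV RMS) mixed into Fz and Pz during meditation
  only, which is what makes Fz–Pz alpha coherence state-dependent.
- **A stimulus-evoked positivity**: Gaussian envelope (350 ms latency,
  120 ms FWHM), parietal-maximal topography (Pz = 1.0), amplitude 10 μV for
  oddballs, 2 μV for standards, 1 μV for distractors.
- **A task-only central theta burst** (150–300 ms, Cz-maximal, 3 μV) after
  each tone, mirroring the transient frontocentral theta reported for
  oddball detection.
- **Blinks**: a Poisson train (4/min) of smooth positive transients
  (~120 ms FWHM — the speed of a real blink, which matters because a 1 Hz
  high-pass removes most of the energy of anything slower), amplitude
  120 μV on the EOG channel with a frontal-dominant scalp projection.

What the generator does *not* emulate: volume-conducted spatial correlation
of the background (each channel's noise is independent), muscle/cardiac
artifacts, non-stationary drowsiness, or latency/amplitude variability of
the evoked response across trials.  A green test therefore establishes that
the pipeline recovers effects *of the planted kind and size* from realistic
noise levels — not that it would survive every pathology of real scalp EEG.
One consequence is worth knowing: with spatially independent background the
blind-source separation problem is harder than on real EEG, so at the
default blink rate ICA often (correctly, per its ≥ 0.9 threshold) rejects
nothing; the dedicated artifact-removal test uses a frequent, large-blink
configuration where the ocular source is dominant enough to isolate.

## Preprocessing

Common-average reference over scalp channels (EOG excluded) → 1 Hz
high-pass (4th-order Butterworth, forward–backward so zero phase; the
realization is unstated in the protocol and this is standard ERP practice)
→ bad-channel detection (robust z > 5 on log-variance, or variance
< 1e-12) with inverse-squared-distance interpolation on the unit-sphere
10–20 layout → ICA artifact removal → epoching to −200..+800 ms with
−200..0 ms baseline subtraction → rejection of trials exceeding ±100 μV on
any scalp channel.

ICA is FastICA (negentropy, deflation, seeded).  The published workflow used
ICLabel probabilities; here the per-component artifact score is
max(|correlation with EOG|, low-frequency spectral dominance), both naturally
in [0, 1], with the same ≥ 0.9 rejection threshold.  Non-convergence returns
the recording unmodified with an empty rejection, reported in the ICA record.

Epoch sampling: pre = round(0.2·fs) and post = round(0.8·fs) samples, both
endpoints kept — 257 samples at 256 Hz.  At rates where 200 ms is not an
integer sample count the first sample may sit a fraction of a sample outside
−200 ms; the baseline mask allows half a sample of tolerance so the
pre-stimulus interval is always non-empty.

## Spectral, time–frequency and connectivity measures

PSDs are Hann-windowed Welch estimates (2 s segments, 50% overlap — a
variance/bias compromise at 256 Hz); band power is the trapezoidal integral
of the density, averaged over frontal {Fz,F3,F4}, central {Cz,C3,C4} or
parietal {Pz,P3,P4} sites.

The time–frequency transform uses complex Morlet wavelets on 25
log-spaced frequencies from 3 to 40 Hz.  Cycles grow linearly:
n(f) = 3 + 0.5·(f/f_min − 1), i.e. 3 cycles at 3 Hz and ≈ 9.2 at 40 Hz.
Wavelets are unit-energy and truncated at ±2.5 temporal standard deviations;
samples closer to an epoch edge than the wavelet half-length are flagged
invalid.  ERSP is 10·log10 of trial-mean power over the mean pre-stimulus
baseline; at frequencies whose wavelet support swallows the whole baseline,
the baseline falls back to all pre-stimulus samples and the frequency is
flagged (`baseline_degraded`) — the same pragmatic choice EEGLAB makes.  ITC
is the magnitude of the trial-mean unit-normalized coefficient (expected
level √π/2/√N ≈ 0.089 for N = 100 random phases).  Condition contrasts use
label permutation of trial-mean differences per bin (500 permutations by
default, add-one p-values so p is never zero) with Benjamini–Hochberg FDR at
q = 0.05 across bins; BH rather than BY because the protocol says only
"FDR" and the bins are positively dependent.

Spectral entropy is the Shannon entropy of in-band Welch bins normalized by
ln K (flat spectrum → 1, single line → 0).  Coherence is magnitude-squared
coherence averaged over the band for the Fz–Pz pair (alpha and beta).  PLV
band-passes each trial (4th-order zero-phase Butterworth), extracts analytic
phases, computes |mean over trials of exp(iΔφ)| per time sample and averages
over the post-stimulus window; "frontal–central pairs" defaults to Fz–Cz,
F3–C3, F4–C4, averaged.  State comparisons use a one-within-factor,
two-level repeated-measures ANOVA whose F(1, n−1) equals the squared paired
t (asserted to 1e-9 in the tests).

## Classification

One row per subject × state, 24 features: P300 amplitude/latency (oddball
trials, Pz, 250–500 ms search window — the canonical P3b range; the peak is
a plain maximum with ties to the earliest sample), 9 site×band powers, 9
site×band entropies, Fz–Pz coherence (alpha, beta) and frontal–central PLV
(theta, alpha).  The classifier is a 100-tree, depth-10, Gini random forest.
Fivefold CV groups both rows of a subject into the same fold (with one row
per class per subject, ungrouped folds would leak subject identity);
leave-one-subject-out uses one fold per subject.  Recursive feature
elimination (drop the single lowest-impurity-importance feature until 10
remain) runs inside each training fold only, and a deliberate-leak test
(RFE fitted on all rows) verifies the shipped pipeline does not inherit the
leak's optimism.  Metrics are pooled over folds; ROC-AUC uses the forest's
class-vote probabilities.  Feature importance is permutation importance
(mean held-out accuracy drop per shuffled column, ties to the earlier
column), averaged across folds.

Cohen's d for paired contrasts is mean(diff)/sd(diff); the source does not
define its d.  The experience–alpha association is a Pearson r with the
exact t-based two-sided p; note that r = 0.45 at n = 13 gives p ≈ 0.12, not
the p = 0.03 printed alongside it in the study — the package reports the
correctly computed p.

## Orchestration, seeds and scaling

`run_all` derives per-stage seeds from the master seed via SeedSequence
spawn keys, so stages are independently re-runnable and two runs with the
same config produce byte-identical JSON summaries (timings go to the log
only).  The summary has six blocks: erp, band_power, connectivity,
correlation, classification, timefreq.

Repeated-seed tests and `scripts/acceptance.py` run a scaled cohort — 13
subjects, one 90-second session of 26 tones at 128 Hz, ICA and the
single-subject time-frequency maps switched off, 2 importance repeats —
because the full 3×13-minute cohort at 256 Hz costs minutes per seed.
Effect sizes, noise levels, thresholds and the classifier protocol are
never changed for these runs; only data volume and per-run extras are.

Known limitations: no gamma band (excluded at the source for muscle-artifact
reasons); no EDF/BDF I/O (no EDF library in the supported environment;
signals live in memory, events/profiles serialize to TSV/JSON); no
spherical-spline interpolation, multitaper spectra, cluster-based
permutation or imaginary-coherence variants; the "two-fold diagnosis /
two-fold age group" sentence in the source protocol is unintelligible and
only the fivefold and LOSO schemes it goes on to describe are implemented.
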