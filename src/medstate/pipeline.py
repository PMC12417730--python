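"""End-to-end orchestration: simulate -> preprocess -> analyze -> classify.

A single master seed deterministically derives per-stage seeds (via
numpy SeedSequence spawn keys), so any stage can be re-run in isolation and
two runs with the same config produce identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import features as fml
from . import preprocess as pp
from .connectivity import rm_anova_2level
from .containers import BANDS
from .erp import average_erp, ci_mean, measure_p300, paired_compare
from .synthetic import (
    CohortBundle,
    ParadigmConfig,
    SignalModelConfig,
    generate_cohort,
    write_events_tsv,
    write_profiles_json,
)
from .timefreq import compute_tf, log_freqs, morlet_coefficients, permutation_significance

logger = logging.getLogger("medstate")

_STAGE_KEYS = {"cohort": 1, "preprocess": 2, "timefreq": 3, "classify": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed (always below 2**31)."""
    ss = np.random.SeedSequence(entropy=int(master_seed) % (2**31),
                                spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All pipeline parameters with defaults mirroring the analysis protocol:
    1 Hz high-pass, -200..+800 ms epochs with a -200..0 ms baseline, 3-40 Hz
    log-spaced wavelets, q = 0.05 FDR, a 100-tree depth-10 Gini forest with
    RFE to 10 features, and the theta/alpha/beta band definitions."""

    n_subjects: int = 13
    n_sessions: int = 3
    session_minutes: float = 13.0
    tones_per_session: int = 250
    fs: float = 256.0
    highpass_hz: float = 1.0
    ica_threshold: float = 0.9
    run_ica: bool = True
    amp_thresh_uv: float = 100.0
    epoch_window_ms: tuple = (-200.0, 800.0)
    baseline_ms: tuple = (-200.0, 0.0)
    n_freqs: int = 25
    n_perm: int = 200
    fdr_q: float = 0.05
    trees: int = 100
    depth: int = 10
    rfe_k: int = 10
    importance_repeats: int = 20
    timefreq_channels: tuple = ("Fz", "Cz", "Pz")
    run_timefreq: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        for key in ("epoch_window_ms", "baseline_ms", "timefreq_channels"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        for key in ("epoch_window_ms", "baseline_ms", "timefreq_channels"):
            payload[key] = list(payload[key])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _simulate(cfg: RunConfig) -> CohortBundle:
    paradigm = ParadigmConfig(
        n_sessions=cfg.n_sessions, session_minutes=cfg.session_minutes,
        tones_per_session=cfg.tones_per_session,
        seed=stage_seed(cfg.seed, "cohort"),
    )
    signal_cfg = SignalModelConfig(fs=cfg.fs)
    return generate_cohort(cfg.n_subjects, paradigm, signal_cfg,
                           master_seed=stage_seed(cfg.seed, "cohort"))


def run_all(cfg: RunConfig, out_dir=None) -> dict:
    """Run the whole pipeline; returns (and optionally writes) the summary.

    The summary holds six result blocks: erp, band_power, connectivity,
    correlation, classification and timefreq.  Stage timings go to the log
    only, keeping the JSON summary byte-identical across repeat runs.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    bundle = _simulate(cfg)
    timings["simulate"] = time.perf_counter() - t0
    logger.info("simulated %d subjects (%.1fs)", len(bundle.profiles),
                timings["simulate"])

    t0 = time.perf_counter()
    pp_seed = stage_seed(cfg.seed, "preprocess")
    processed: dict[tuple[str, str], tuple] = {}
    peaks = []
    for (subject, state), rec in bundle.recordings.items():
        ep, rec_clean, _ = pp.preprocess_recording(
            rec, bundle.events[subject], highpass_hz=cfg.highpass_hz,
            ica_threshold=cfg.ica_threshold, amp_thresh_uv=cfg.amp_thresh_uv,
            run_ica=cfg.run_ica, seed=pp_seed,
        )
        processed[(subject, state)] = (ep, rec_clean)
        summ = average_erp(ep, ["oddball", "standard"])
        for cond in ("oddball", "standard"):
            pk = measure_p300(summ, cond)
            peaks.append({"subject": subject, "state": state, "condition": cond,
                          "amplitude": pk.amplitude, "latency_ms": pk.latency_ms})
    timings["preprocess"] = time.perf_counter() - t0

    # --- ERP block: oddball vs standard P300 in the task state -------------
    t0 = time.perf_counter()
    odd = [p["amplitude"] for p in peaks
           if p["state"] == "task" and p["condition"] == "oddball"]
    std = [p["amplitude"] for p in peaks
           if p["state"] == "task" and p["condition"] == "standard"]
    erp_test = paired_compare(odd, std)
    erp_block = {
        "oddball_vs_standard_amplitude": erp_test.as_dict(),
        "oddball_amplitude_mean": float(np.mean(odd)),
        "oddball_amplitude_ci95": list(ci_mean(odd)),
        "n_subjects": len(odd),
    }

    # --- band-power and connectivity blocks (meditation vs task) -----------
    table = fml.build_feature_table(processed)
    med = table[table["state"] == "meditation"].sort_values("subject")
    task = table[table["state"] == "task"].sort_values("subject")

    def contrast(column: str) -> dict:
        res = rm_anova_2level(med[column].to_numpy(), task[column].to_numpy())
        out = res.as_dict()
        out["mean_difference"] = float(
            (med[column].to_numpy() - task[column].to_numpy()).mean())
        return out

    band_block = {
        "frontal_alpha": contrast("alpha_power_frontal"),
        "frontal_beta": contrast("beta_power_frontal"),
        "central_theta": contrast("theta_power_central"),
    }
    conn_block = {
        "fzpz_alpha_coherence": contrast("coherence_fzpz_alpha"),
        "theta_plv": contrast("plv_theta"),
        "frontal_alpha_entropy": contrast("entropy_alpha_frontal"),
    }
    corr = fml.experience_alpha_correlation(bundle.profiles, table)
    corr_block = corr.as_dict()
    timings["stats"] = time.perf_counter() - t0

    # --- classification ----------------------------------------------------
    t0 = time.perf_counter()
    clf_seed = stage_seed(cfg.seed, "classify")
    reports = {
        scheme: fml.cross_validate(table, scheme=scheme, trees=cfg.trees,
                                   depth=cfg.depth, rfe_k=cfg.rfe_k,
                                   seed=clf_seed,
                                   importance_repeats=cfg.importance_repeats)
        for scheme in ("fivefold", "loso")
    }
    clf_block = {scheme: rep.as_dict() for scheme, rep in reports.items()}
    timings["classify"] = time.perf_counter() - t0

    # --- time-frequency maps for the first subject -------------------------
    t0 = time.perf_counter()
    first = bundle.profiles[0].subject_id
    tf, mask = None, None
    if cfg.run_timefreq:
        ep_task, _ = processed[(first, "task")]
        freqs = log_freqs(n=cfg.n_freqs)
        tf = compute_tf(ep_task, list(cfg.timefreq_channels), freqs,
                        baseline_ms=cfg.baseline_ms)
        coefs, _, valid = morlet_coefficients(ep_task, freqs,
                                              list(cfg.timefreq_channels))
        power = np.abs(coefs) ** 2
        kept_cond = ep_task.condition[ep_task.kept()]
        mask = permutation_significance(
            power[kept_cond == "oddball"], power[kept_cond == "standard"],
            n_perm=cfg.n_perm, q=cfg.fdr_q,
            seed=stage_seed(cfg.seed, "timefreq"), valid=valid,
        )
        tf_block = {
            "subject": first,
            "channels": list(cfg.timefreq_channels),
            "n_trials": tf.n_trials,
            "ersp_max_db": float(np.nanmax(tf.ersp)),
            "itc_max": float(np.nanmax(tf.itc)),
            "significant_bin_fraction": float(mask.mean()),
        }
    else:
        tf_block = {"skipped": True}
    timings["timefreq"] = time.perf_counter() - t0

    summary = {
        "config": dataclasses.asdict(cfg) | {
            k: list(v) for k, v in
            (("epoch_window_ms", cfg.epoch_window_ms),
             ("baseline_ms", cfg.baseline_ms),
             ("timefreq_channels", cfg.timefreq_channels))
        },
        "erp": erp_block,
        "band_power": band_block,
        "connectivity": conn_block,
        "correlation": corr_block,
        "classification": clf_block,
        "timefreq": tf_block,
    }
    for stage, dt in timings.items():
        logger.info("stage %s: %.2fs", stage, dt)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        table.to_csv(out / "features.tsv", sep="\t", index=False)
        (out / "features.schema.json").write_text(json.dumps({
            "subject": "subject identifier",
            "state": "meditation | task",
            "p300_amplitude": "uV, oddball trial-average peak at Pz, 250-500 ms",
            "p300_latency": "ms post-stimulus",
            "*_power_*": "band power (uV^2), trapezoidal PSD integral, site mean",
            "entropy_*": "normalized spectral entropy in [0, 1]",
            "coherence_fzpz_*": "magnitude-squared coherence in [0, 1]",
            "plv_*": "phase-locking value in [0, 1], frontal-central pair mean",
        }, indent=2))
        import pandas as pd

        long = table.melt(id_vars=["subject", "state"], var_name="metric",
                          value_name="value")
        long.to_csv(out / "features_long.tsv", sep="\t", index=False)
        pd.DataFrame(peaks).to_csv(out / "peaks.tsv", sep="\t", index=False)
        write_profiles_json(bundle.profiles, out / "profiles.json")
        write_events_tsv(bundle.events[first], out / f"{first}_events.tsv")
        if tf is not None:
            np.savez(out / "timefreq_maps.npz", freqs=tf.freqs,
                     times_ms=tf.times_ms, ersp=tf.ersp, itc=tf.itc,
                     sig_mask=mask, valid=tf.valid)
        (out / "run.log").write_text(
            "\n".join(f"{k}: {v:.3f}s" for k, v in timings.items()) + "\n")
    return summary
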