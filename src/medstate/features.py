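"""Feature assembly and the state-classification protocol.

One row per subject x state; a Random Forest (100 trees, depth 10, Gini)
evaluated under subject-grouped fivefold and leave-one-subject-out
cross-validation, with recursive feature elimination to the top 10 features
fitted inside each training fold and permutation importance measured on the
held-out rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, roc_auc_score

from .connectivity import COHERENCE_PAIR, coherence, mean_plv, spectral_entropy
from .containers import BANDS, CvReport, EpochSet, Recording, SITES, StatTestResult
from .erp import average_erp, correlation_with_experience, measure_p300
from .spectral import psd_of_recording, site_band_power

POSITIVE_CLASS = "meditation"

#: Deterministic feature column order (units: uV, ms, uV^2, unitless [0,1]).
FEATURE_COLUMNS: tuple[str, ...] = (
    ("p300_amplitude", "p300_latency")
    + tuple(f"{band}_power_{site}" for band in BANDS for site in SITES)
    + tuple(f"entropy_{band}_{site}" for band in BANDS for site in SITES)
    + tuple(f"coherence_fzpz_{band}" for band in ("alpha", "beta"))
    + tuple(f"plv_{band}" for band in ("theta", "alpha"))
)


def subject_state_features(ep: EpochSet, rec: Recording,
                           seg_len_s: float = 2.0) -> dict[str, float]:
    """All classifier features for one preprocessed subject-state recording."""
    feats: dict[str, float] = {}
    erp_summary = average_erp(ep, ["oddball"])
    peak = measure_p300(erp_summary, "oddball")
    feats["p300_amplitude"] = peak.amplitude
    feats["p300_latency"] = peak.latency_ms

    psd = psd_of_recording(rec, seg_len_s=seg_len_s)
    for band in BANDS:
        for site in SITES:
            feats[f"{band}_power_{site}"] = site_band_power(psd, band, site)
    for band, edges in BANDS.items():
        for site, chans in SITES.items():
            vals = [spectral_entropy(rec.channel(c), rec.fs, edges, seg_len_s)
                    for c in chans if c in rec.labels]
            feats[f"entropy_{band}_{site}"] = float(np.mean(vals))
    for band in ("alpha", "beta"):
        feats[f"coherence_fzpz_{band}"] = coherence(
            rec.channel(COHERENCE_PAIR[0]), rec.channel(COHERENCE_PAIR[1]),
            rec.fs, BANDS[band], seg_len_s=seg_len_s,
        )
    for band in ("theta", "alpha"):
        feats[f"plv_{band}"] = mean_plv(ep, band)
    return feats


def build_feature_table(per_state_inputs: dict) -> pd.DataFrame:
    """Assemble the subject x state feature table.

    ``per_state_inputs`` maps (subject_id, state) to a preprocessed
    (EpochSet, Recording) pair.  Missing values are an error, never imputed;
    every subject must contribute exactly two rows (one per state).
    """
    rows = []
    for (subject, state), (ep, rec) in per_state_inputs.items():
        feats = subject_state_features(ep, rec)
        rows.append({"subject": subject, "state": state, **feats})
    table = pd.DataFrame(rows, columns=["subject", "state", *FEATURE_COLUMNS])
    if table[list(FEATURE_COLUMNS)].isna().any().any():
        raise ValueError("feature table contains missing values")
    counts = table.groupby("subject").size()
    if not (counts == 2).all():
        raise ValueError("every subject must have exactly two rows (one per state)")
    return table


def _make_rf(trees: int, depth: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=trees, max_depth=depth,
                                  criterion="gini", random_state=seed)


def rfe_select(X: np.ndarray, y: np.ndarray, feature_names: list[str],
               k: int = 10, trees: int = 100, depth: int = 10,
               seed: int = 0) -> list[str]:
    """Recursive feature elimination down to ``k`` features.

    Repeatedly fits the forest and drops the single feature with the lowest
    impurity importance.  Call this on training rows only; it never sees the
    evaluation data.
    """
    if k >= len(feature_names):
        if k == len(feature_names):
            return list(feature_names)
        raise ValueError("k must not exceed the number of features")
    remaining = list(feature_names)
    name_to_col = {n: i for i, n in enumerate(feature_names)}
    while len(remaining) > k:
        cols = [name_to_col[n] for n in remaining]
        rf = _make_rf(trees, depth, seed)
        rf.fit(X[:, cols], y)
        worst = int(np.argmin(rf.feature_importances_))
        remaining.pop(worst)
    return remaining


def permutation_importance(model, X_test: np.ndarray, y_test: np.ndarray,
                           feature_names: list[str], n_repeats: int = 20,
                           seed: int = 0) -> list[tuple[str, float]]:
    """Mean test-accuracy drop per shuffled column, ranked descending.

    Ties break toward the earlier column.  Requires n_repeats >= 2.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rng = np.random.default_rng(seed)
    base = float(np.mean(model.predict(X_test) == y_test))
    drops = []
    for j, name in enumerate(feature_names):
        acc = []
        for _ in range(n_repeats):
            Xp = X_test.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            acc.append(float(np.mean(model.predict(Xp) == y_test)))
        drops.append(base - float(np.mean(acc)))
    order = sorted(range(len(feature_names)), key=lambda i: (-drops[i], i))
    return [(feature_names[i], drops[i]) for i in order]


def _fold_subject_lists(subjects: np.ndarray, scheme: str, n_splits: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    uniq = np.array(sorted(set(subjects)))
    if scheme == "loso":
        return [np.array([s]) for s in uniq]
    if scheme == "fivefold":
        shuffled = rng.permutation(uniq)
        return [f for f in np.array_split(shuffled, n_splits) if f.size]
    raise ValueError("scheme must be 'fivefold' or 'loso'")


def cross_validate(
    table: pd.DataFrame,
    scheme: str = "fivefold",
    trees: int = 100,
    depth: int = 10,
    rfe_k: int = 10,
    seed: int = 0,
    n_splits: int = 5,
    importance_repeats: int = 20,
) -> CvReport:
    """Subject-grouped cross-validation of the meditation/task classifier.

    Both rows of a subject always land in the same fold (with one row per
    class per subject this is automatically stratified); LOSO uses one fold
    per subject.  RFE and the forest are fitted inside each training fold.
    Metrics are pooled over folds; ROC-AUC uses the forest's class-vote
    probabilities.  Permutation importances are averaged across folds.
    """
    y_all = table["state"].to_numpy()
    if len(set(y_all)) < 2:
        raise ValueError("both classes must be present")
    X_all = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    subjects = table["subject"].to_numpy()
    rng = np.random.default_rng(seed)
    folds = _fold_subject_lists(subjects, scheme, n_splits, rng)

    names = list(FEATURE_COLUMNS)
    pooled_true, pooled_pred, pooled_proba = [], [], []
    per_fold, selections = [], []
    importance_acc: dict[str, list[float]] = {n: [] for n in names}
    for fold_i, test_subjects in enumerate(folds):
        test_mask = np.isin(subjects, test_subjects)
        X_tr, y_tr = X_all[~test_mask], y_all[~test_mask]
        X_te, y_te = X_all[test_mask], y_all[test_mask]
        fold_seed = int(rng.integers(0, 2**31 - 1))
        if len(set(y_tr)) < 2:
            per_fold.append({"fold": fold_i, "error": "single class in training"})
            continue
        k = min(rfe_k, len(names))
        selected = rfe_select(X_tr, y_tr, names, k=k, trees=trees,
                              depth=depth, seed=fold_seed)
        cols = [names.index(n) for n in selected]
        rf = _make_rf(trees, depth, fold_seed)
        rf.fit(X_tr[:, cols], y_tr)
        pred = rf.predict(X_te[:, cols])
        proba = rf.predict_proba(X_te[:, cols])[:, list(rf.classes_).index(POSITIVE_CLASS)] \
            if POSITIVE_CLASS in rf.classes_ else np.zeros(len(y_te))
        pooled_true.extend(y_te.tolist())
        pooled_pred.extend(pred.tolist())
        pooled_proba.extend(proba.tolist())
        selections.append(selected)
        ranking = permutation_importance(rf, X_te[:, cols], y_te, selected,
                                         n_repeats=importance_repeats,
                                         seed=fold_seed)
        for name, drop in ranking:
            importance_acc[name].append(drop)
        per_fold.append({
            "fold": fold_i,
            "test_subjects": [str(s) for s in test_subjects],
            "accuracy": float(np.mean(pred == y_te)),
        })

    y_true = np.asarray(pooled_true)
    y_pred = np.asarray(pooled_pred)
    accuracy = float(np.mean(y_pred == y_true))
    f1 = float(f1_score(y_true, y_pred, pos_label=POSITIVE_CLASS, zero_division=0))
    if len(set(y_true)) == 2:
        auc = float(roc_auc_score((y_true == POSITIVE_CLASS).astype(int),
                                  np.asarray(pooled_proba)))
    else:
        auc = float("nan")
    mean_importance = [(n, float(np.mean(v))) for n, v in importance_acc.items() if v]
    mean_importance.sort(key=lambda t: (-t[1], names.index(t[0])))
    return CvReport(scheme=scheme, accuracy=accuracy, f1=f1, roc_auc=auc,
                    per_fold=per_fold, selected_features=selections,
                    importance=mean_importance, seed=seed)


def experience_alpha_correlation(profiles, table: pd.DataFrame) -> StatTestResult:
    """Pearson correlation between practice years and meditation-state
    frontal alpha power."""
    med = table[table["state"] == POSITIVE_CLASS].set_index("subject")
    years, alpha = [], []
    for p in profiles:
        if p.subject_id in med.index:
            years.append(p.experience_years)
            alpha.append(float(med.loc[p.subject_id, "alpha_power_frontal"]))
    return correlation_with_experience(years, alpha)
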