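"""Feature table assembly, RFE, grouped cross-validation, importances."""

import numpy as np
import pandas as pd
import pytest

import medstate as m
from medstate.features import (
    FEATURE_COLUMNS,
    build_feature_table,
    cross_validate,
    experience_alpha_correlation,
    permutation_importance,
    rfe_select,
)
from sklearn.ensemble import RandomForestClassifier


def synthetic_table(seed, n_subjects=13, informative=None):
    """Pure-noise feature table, optionally with one label-copy column."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for state in ("meditation", "task"):
            feats = {c: rng.normal() for c in FEATURE_COLUMNS}
            if informative is not None:
                feats[informative] = 1.0 if state == "meditation" else 0.0
            rows.append({"subject": f"s{i:02d}", "state": state, **feats})
    return pd.DataFrame(rows, columns=["subject", "state", *FEATURE_COLUMNS])


@pytest.fixture(scope="module")
def small_feature_table(small_paradigm):
    """Real features from a 6-subject cohort (ICA skipped: its behavior is
    covered separately and the generator injects sub-threshold blinks)."""
    from medstate.preprocess import preprocess_recording

    sig = m.SignalModelConfig(fs=128.0)
    bundle = m.generate_cohort(6, small_paradigm, sig, master_seed=3)
    processed = {}
    for key, rec in bundle.recordings.items():
        ep, clean, _ = preprocess_recording(rec, bundle.events[key[0]],
                                            run_ica=False)
        processed[key] = (ep, clean)
    return bundle, build_feature_table(processed)


class TestBuildFeatureTable:
    def test_two_rows_per_subject_and_schema(self, small_feature_table):
        _, table = small_feature_table
        assert len(table) == 12
        assert list(table.columns) == ["subject", "state", *FEATURE_COLUMNS]
        assert table.groupby("subject").size().eq(2).all()
        assert not table[list(FEATURE_COLUMNS)].isna().any().any()

    def test_meditation_rows_show_higher_frontal_alpha(self, small_feature_table):
        _, table = small_feature_table
        med = table[table["state"] == "meditation"]["alpha_power_frontal"]
        task = table[table["state"] == "task"]["alpha_power_frontal"]
        assert med.mean() > task.mean()

    def test_missing_subject_row_rejected(self, small_feature_table):
        bundle, _ = small_feature_table
        from medstate.preprocess import preprocess_recording

        sub = bundle.profiles[0].subject_id
        rec = bundle.recordings[(sub, "task")]
        ep, clean, _ = preprocess_recording(rec, bundle.events[sub],
                                            run_ica=False)
        with pytest.raises(ValueError):
            build_feature_table({(sub, "task"): (ep, clean)})


class TestRfe:
    def test_identity_when_k_equals_feature_count(self):
        tb = synthetic_table(0)
        X = tb[list(FEATURE_COLUMNS)].to_numpy()
        y = tb["state"].to_numpy()
        assert rfe_select(X, y, list(FEATURE_COLUMNS),
                          k=len(FEATURE_COLUMNS)) == list(FEATURE_COLUMNS)

    def test_label_copy_feature_survives_elimination(self):
        tb = synthetic_table(1, informative="plv_theta")
        X = tb[list(FEATURE_COLUMNS)].to_numpy()
        y = tb["state"].to_numpy()
        kept = rfe_select(X, y, list(FEATURE_COLUMNS), k=5, trees=30, seed=0)
        assert "plv_theta" in kept

    def test_deterministic_given_seed(self):
        tb = synthetic_table(2)
        X = tb[list(FEATURE_COLUMNS)].to_numpy()
        y = tb["state"].to_numpy()
        s1 = rfe_select(X, y, list(FEATURE_COLUMNS), k=10, trees=30, seed=7)
        s2 = rfe_select(X, y, list(FEATURE_COLUMNS), k=10, trees=30, seed=7)
        assert s1 == s2

    def test_k_above_feature_count_rejected(self):
        tb = synthetic_table(3)
        with pytest.raises(ValueError):
            rfe_select(tb[list(FEATURE_COLUMNS)].to_numpy(),
                       tb["state"].to_numpy(), list(FEATURE_COLUMNS), k=30)


class TestCrossValidate:
    def test_label_copy_features_classify_perfectly(self):
        tb = synthetic_table(4, informative="p300_amplitude")
        for scheme in ("fivefold", "loso"):
            rep = cross_validate(tb, scheme, trees=30, seed=0,
                                 importance_repeats=2)
            assert rep.accuracy == 1.0
            assert rep.f1 == 1.0
            assert rep.roc_auc == 1.0

    def test_shuffled_labels_sit_at_chance(self):
        accs = []
        for rep_i in range(20):
            rng = np.random.default_rng(100 + rep_i)
            tb = synthetic_table(rep_i)
            tb["state"] = rng.permutation(tb["state"].to_numpy())
            if len(set(tb["state"])) < 2:
                continue
            rep = cross_validate(tb, "fivefold", trees=30,
                                 rfe_k=len(FEATURE_COLUMNS), seed=rep_i,
                                 importance_repeats=2)
            accs.append(rep.accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.2

    def test_subject_grouping_keeps_pairs_together(self):
        tb = synthetic_table(5)
        rep = cross_validate(tb, "fivefold", trees=30, seed=1,
                             importance_repeats=2)
        seen = [s for fold in rep.per_fold for s in fold["test_subjects"]]
        assert sorted(seen) == sorted(tb["subject"].unique())

    def test_loso_produces_one_fold_per_subject(self):
        tb = synthetic_table(6, n_subjects=5)
        rep = cross_validate(tb, "loso", trees=30, seed=2,
                             importance_repeats=2)
        assert len(rep.per_fold) == 5
        assert all(len(f["test_subjects"]) == 1 for f in rep.per_fold)

    def test_deterministic_given_seed(self):
        tb = synthetic_table(7)
        r1 = cross_validate(tb, "fivefold", trees=30, seed=3,
                            importance_repeats=2)
        r2 = cross_validate(tb, "fivefold", trees=30, seed=3,
                            importance_repeats=2)
        assert r1.as_dict() == r2.as_dict()

    def test_rfe_leak_inflates_noise_accuracy(self):
        """Fitting RFE on all rows (a leak) must beat the shipped
        train-fold-only pipeline on pure-noise features."""
        shipped, leaky = [], []
        for seed in range(6):
            tb = synthetic_table(50 + seed)
            rep = cross_validate(tb, "fivefold", trees=20, depth=5, rfe_k=8,
                                 seed=seed, importance_repeats=2)
            shipped.append(rep.accuracy)
            X = tb[list(FEATURE_COLUMNS)].to_numpy()
            y = tb["state"].to_numpy()
            sel = rfe_select(X, y, list(FEATURE_COLUMNS), k=8, trees=20,
                             depth=5, seed=seed)
            leaked = tb.copy()
            for c in FEATURE_COLUMNS:
                if c not in sel:
                    leaked[c] = 0.0
            rep2 = cross_validate(leaked, "fivefold", trees=20, depth=5,
                                  rfe_k=8, seed=seed, importance_repeats=2)
            leaky.append(rep2.accuracy)
        assert np.mean(leaky) > np.mean(shipped)
        assert abs(np.mean(shipped) - 0.5) < 0.2  # shipped stays at chance


class TestPermutationImportance:
    @pytest.fixture()
    def fitted(self):
        tb = synthetic_table(8, informative="coherence_fzpz_beta")
        X = tb[list(FEATURE_COLUMNS)].to_numpy()
        y = tb["state"].to_numpy()
        rf = RandomForestClassifier(n_estimators=50, max_depth=10,
                                    random_state=0).fit(X, y)
        return rf, X, y

    def test_label_copy_ranks_first(self, fitted):
        rf, X, y = fitted
        ranking = permutation_importance(rf, X, y, list(FEATURE_COLUMNS),
                                         n_repeats=10, seed=0)
        assert ranking[0][0] == "coherence_fzpz_beta"
        assert ranking[0][1] > 0.2

    def test_noise_features_have_near_zero_importance(self, fitted):
        rf, X, y = fitted
        ranking = permutation_importance(rf, X, y, list(FEATURE_COLUMNS),
                                         n_repeats=10, seed=0)
        noise = [v for n, v in ranking if n != "coherence_fzpz_beta"]
        assert max(np.abs(noise)) < 0.05

    def test_deterministic_and_validates_repeats(self, fitted):
        rf, X, y = fitted
        r1 = permutation_importance(rf, X, y, list(FEATURE_COLUMNS), 5, seed=1)
        r2 = permutation_importance(rf, X, y, list(FEATURE_COLUMNS), 5, seed=1)
        assert r1 == r2
        with pytest.raises(ValueError):
            permutation_importance(rf, X, y, list(FEATURE_COLUMNS), 1, seed=1)


class TestExperienceCorrelation:
    def test_planted_coupling_recovered_from_features(self, small_feature_table):
        bundle, table = small_feature_table
        res = experience_alpha_correlation(bundle.profiles, table)
        assert -1.0 <= res.statistic <= 1.0
        assert 0.0 <= res.p_value <= 1.0

    def test_perfect_coupling(self):
        tb = synthetic_table(9, n_subjects=5)
        profiles = m.make_profiles(5, master_seed=0,
                                   experience_years=[1, 2, 3, 4, 5])
        ids = {old: p.subject_id
               for old, p in zip(sorted(tb["subject"].unique()), profiles)}
        tb["subject"] = tb["subject"].map(ids)
        med = tb["state"] == "meditation"
        tb.loc[med, "alpha_power_frontal"] = [2.0, 4.0, 6.0, 8.0, 10.0]
        res = experience_alpha_correlation(profiles, tb)
        assert res.statistic == pytest.approx(1.0)
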