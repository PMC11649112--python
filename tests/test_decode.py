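"""BNA tables, label schemes, group statistics, and condition decoding."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from modbrain.decode import (
    BNATable,
    OrdinalLogisticAT,
    bna_table,
    classify_conditions,
    learning_curve_duration,
    pairwise_group_tests,
    permutation_importance,
    relabel,
)
from modbrain.mha import MHAModel, RunLatent, LoadingMatrix


def _toy_model(G_list, run_ids):
    k = G_list[0].shape[0]
    p = k + 1
    W = np.zeros((p, k))
    W[:k, :k] = np.eye(k)
    latents = [RunLatent(G=G, v=0.1, run_id=rid) for G, rid in zip(G_list, run_ids)]
    return MHAModel(loading=LoadingMatrix(W), run_latents=latents,
                    objective_trace=[0.0], seed=0, converged=True, run_ids=run_ids)


def _separable_table(rng, sep=5.0, n_per_subject=10, k=3):
    """Two conditions separated by `sep` pooled sd in network 0."""
    rows, subjects, conditions = [], [], []
    for s in "AJKLR":
        for r in range(n_per_subject):
            cond = "awake" if r % 2 == 0 else "propofol-deep"
            mu = np.full(k, 2.0)
            mu[0] = 2.0 + sep if cond == "awake" else 2.0
            rows.append(np.clip(rng.normal(mu, 1.0), 0, None))
            subjects.append(s)
            conditions.append(cond)
    n = len(rows)
    return BNATable(np.array(rows), [f"r{i}" for i in range(n)], subjects,
                    conditions, [f"BN{j + 1}" for j in range(k)])


class TestBNATable:
    def test_row_is_diagonal_of_G(self):
        G = np.array([[3.0, 1.0], [1.0, 2.0]])
        model = _toy_model([G], ["r0"])
        meta = pd.DataFrame([{"run_id": "r0", "subject": "A", "condition": "awake"}])
        table = bna_table(model, meta)
        np.testing.assert_allclose(table.values[0], [3.0, 2.0])

    def test_shape_and_order_follow_metadata(self, rng):
        Gs = [np.diag(rng.uniform(0, 3, size=2)) for _ in range(6)]
        model = _toy_model(Gs, [f"r{i}" for i in range(6)])
        meta = pd.DataFrame([{"run_id": f"r{i}", "subject": "A", "condition": "awake"}
                             for i in reversed(range(6))])
        table = bna_table(model, meta)
        assert table.values.shape == (6, 2)
        np.testing.assert_allclose(table.values[0], np.diag(Gs[5]))

    def test_missing_run_raises(self):
        model = _toy_model([np.eye(2)], ["r0"])
        meta = pd.DataFrame([{"run_id": "r9", "subject": "A", "condition": "awake"}])
        with pytest.raises(KeyError):
            bna_table(model, meta)


class TestRelabel:
    @pytest.mark.parametrize("cond,scheme,expected", [
        ("sevoflurane-moderate", "Anesthesia", 1),
        ("propofol-deep", "DeepModerate", 2),
        ("ketamine-deep", "DeepModerate", 2),
        ("propofol-moderate", "DeepModerate", 1),
        ("awake", "Anesthesia", 0),
        ("awake", "DeepModerate", 0),
        ("awake", "All", 0),
    ])
    def test_scheme_mappings(self, cond, scheme, expected):
        labels, _ = relabel(["awake", cond], scheme)
        assert labels[1] == expected
        assert labels[0] == 0

    def test_all_scheme_distinct_classes(self):
        conds = ["awake", "ketamine-deep", "propofol-moderate", "propofol-deep",
                 "sevoflurane-moderate", "sevoflurane-deep"]
        labels, mapping = relabel(conds, "All")
        assert len(set(labels)) == 6
        assert mapping["awake"] == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            relabel(["awake", "nitrous-light"], "DeepModerate")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            relabel(["awake"], "Everything")


class TestGroupTests:
    def test_strong_shift_reaches_four_stars(self, rng):
        rows, conds = [], []
        for _ in range(30):
            rows.append([rng.normal(0.0, 1.0)])
            conds.append("awake")
        for _ in range(30):
            rows.append([rng.normal(3.0, 1.0)])  # 3 pooled sd shift
            conds.append("propofol-deep")
        table = BNATable(np.abs(rows), [f"r{i}" for i in range(60)],
                         ["A"] * 60, conds, ["BN1"])
        report = pairwise_group_tests(table)
        assert report.tests["p_adj"].iloc[0] <= 1e-4
        assert report.tests["annotation"].iloc[0] == "****"

    def test_annotation_thresholds(self):
        from modbrain.decode import _annotate

        assert _annotate(0.005) == "**"
        assert _annotate(5e-4) == "***"
        assert _annotate(5e-5) == "****"
        assert _annotate(0.02) == "ns"

    def test_adjusted_p_at_least_raw_and_bh(self, rng):
        rows = rng.uniform(0, 3, size=(40, 3))
        conds = (["awake"] * 14 + ["propofol-deep"] * 13 + ["ketamine-deep"] * 13)
        table = BNATable(rows, [f"r{i}" for i in range(40)], ["A"] * 40,
                         conds, ["BN1", "BN2", "BN3"])
        report = pairwise_group_tests(table)
        raw = report.tests["p_raw"].to_numpy()
        adj = report.tests["p_adj"].to_numpy()
        assert np.all(adj >= raw - 1e-15)
        bh = multipletests(raw, method="fdr_bh")[1]
        assert np.all(adj >= bh - 1e-15)
        # monotone: sorting by raw p sorts adjusted p
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_small_conditions_skipped_with_warning(self, rng):
        rows = rng.uniform(0, 3, size=(23, 2))
        conds = ["awake"] * 10 + ["propofol-deep"] * 11 + ["ketamine-deep"] * 2
        table = BNATable(rows, [f"r{i}" for i in range(23)], ["A"] * 23,
                         conds, ["BN1", "BN2"])
        with pytest.warns(UserWarning, match="skipped"):
            report = pairwise_group_tests(table)
        assert report.skipped_conditions == ["ketamine-deep"]
        assert set(report.tests["cond_a"]) | set(report.tests["cond_b"]) == {
            "awake", "propofol-deep"}

    def test_normality_diagnostic_reported_not_gating(self, rng):
        table = _separable_table(rng)
        report = pairwise_group_tests(table)
        assert set(report.normality) == set(table.network_labels)
        assert all(0 <= v <= 1 for v in report.normality.values())


class TestOrdinalLogistic:
    def test_recovers_ordered_classes_on_separable_data(self, rng):
        X = np.sort(rng.uniform(0, 9, size=(90, 1)), axis=0)
        y = (X[:, 0] // 3).astype(int)  # 0, 1, 2 ordered by the feature
        clf = OrdinalLogisticAT(alpha=1.0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.9
        assert np.all(np.diff(clf.theta_) > 0)  # thresholds come out ordered

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = OrdinalLogisticAT(alpha=2.0)
        assert clone(clf).alpha == 2.0


class TestClassifyConditions:
    def test_separable_bnas_decode_above_090(self, rng):
        table = _separable_table(rng)
        report = classify_conditions(table, "Anesthesia", "J", seed=0)
        assert report.test_bacc >= 0.9
        assert report.chance_level == pytest.approx(0.5)

    def test_no_subject_leakage(self, rng):
        table = _separable_table(rng)
        report = classify_conditions(table, "Anesthesia", "J", seed=0)
        assert report.n_test == sum(s == "J" for s in table.subjects)
        assert report.n_train == table.n - report.n_test

    def test_shuffled_labels_decode_at_chance(self, rng):
        table = _separable_table(rng)
        shuffled = list(rng.permutation(table.conditions))
        t2 = BNATable(table.values, table.run_ids, table.subjects, shuffled,
                      table.network_labels)
        scores = [classify_conditions(t2, "Anesthesia", "J", seed=s).test_bacc
                  for s in range(3)]
        assert abs(np.mean(scores) - 0.5) < 0.2

    def test_reports_reproducible_under_fixed_seed(self, rng):
        table = _separable_table(rng)
        r1 = classify_conditions(table, "Anesthesia", "J", seed=3)
        r2 = classify_conditions(table, "Anesthesia", "J", seed=3)
        assert r1.test_bacc == r2.test_bacc
        assert r1.validation_bacc_mean == r2.validation_bacc_mean

    def test_ordinal_classifier_on_ordered_scheme(self, rng):
        rows, subjects, conditions = [], [], []
        for s in "AJKLR":
            for r in range(12):
                cond = ["awake", "propofol-moderate", "propofol-deep"][r % 3]
                level = {"awake": 6.0, "propofol-moderate": 3.0, "propofol-deep": 0.5}[cond]
                rows.append(np.clip(rng.normal([level, 2.0], 0.4), 0, None))
                subjects.append(s)
                conditions.append(cond)
        table = BNATable(np.array(rows), [f"r{i}" for i in range(60)], subjects,
                         conditions, ["BN1", "BN2"])
        report = classify_conditions(table, "DeepModerate", "J", seed=0,
                                     classifier="ordinal")
        assert report.test_bacc >= 0.9
        assert report.chance_level == pytest.approx(1 / 3)

    def test_missing_test_class_warns_in_report(self, rng):
        table = _separable_table(rng)
        # subject J's ketamine runs exist only for J: absent from training
        conds = list(table.conditions)
        for i, s in enumerate(table.subjects):
            if s == "J" and conds[i] == "propofol-deep":
                conds[i] = "ketamine-deep"
        t2 = BNATable(table.values, table.run_ids, table.subjects, conds,
                      table.network_labels)
        report = classify_conditions(t2, "All", "J", seed=0)
        assert any("absent from training" in w for w in report.warnings)

    def test_unknown_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            classify_conditions(_separable_table(rng), "Anesthesia", "Z", seed=0)


class TestPermutationImportance:
    def test_informative_network_ranks_first(self, rng):
        table = _separable_table(rng, k=4)
        y, _ = relabel(table.conditions, "Anesthesia")
        report = classify_conditions(table, "Anesthesia", "J", seed=0)
        imp = permutation_importance(report._estimator, table, y,
                                     n_repeats=10, seed=0)
        assert imp["importance_mean"].idxmax() == 0  # network 0 carries the signal

    def test_constant_column_has_zero_importance(self, rng):
        table = _separable_table(rng)
        values = table.values.copy()
        values[:, 2] = 1.0
        t2 = BNATable(values, table.run_ids, table.subjects, table.conditions,
                      table.network_labels)
        y, _ = relabel(t2.conditions, "Anesthesia")
        report = classify_conditions(t2, "Anesthesia", "J", seed=0)
        imp = permutation_importance(report._estimator, t2, y, n_repeats=5, seed=0)
        assert imp["importance_mean"].iloc[2] == 0.0

    def test_too_few_repeats_rejected(self, rng):
        table = _separable_table(rng)
        report = classify_conditions(table, "Anesthesia", "J", seed=0)
        y, _ = relabel(table.conditions, "Anesthesia")
        with pytest.raises(ValueError):
            permutation_importance(report._estimator, table, y, n_repeats=1)


class TestLearningCurve:
    def test_full_duration_matches_standard_decoding(self, sim_dataset):
        from modbrain.mha import fit_mha
        from modbrain.preprocess import empirical_covariance

        runs, truth, covs = sim_dataset
        model = fit_mha(covs, 4, seed=0, n_restarts=2,
                        run_ids=[r.run_id for r in runs])
        meta = pd.DataFrame([{"run_id": r.run_id, "subject": r.subject,
                              "condition": r.condition} for r in runs])
        table = bna_table(model, meta)
        standard = classify_conditions(table, "Anesthesia", "J", seed=0)
        curve = learning_curve_duration(runs, model, "Anesthesia",
                                        durations=[runs[0].t], heldout_subject="J",
                                        seed=0, denoise=False)
        assert curve["test_bacc"].iloc[0] == standard.test_bacc

    def test_short_durations_recorded_as_missing(self, sim_dataset):
        from modbrain.mha import fit_mha

        runs, _, covs = sim_dataset
        model = fit_mha(covs, 4, seed=0, n_restarts=2,
                        run_ids=[r.run_id for r in runs])
        curve = learning_curve_duration(runs, model, "Anesthesia",
                                        durations=[5, 100], heldout_subject="J",
                                        seed=0, denoise=True)
        assert np.isnan(curve["test_bacc"].iloc[0])  # too short to filter
        assert not np.isnan(curve["test_bacc"].iloc[1])


def test_balanced_accuracy_of_constant_predictor_is_chance():
    from sklearn.metrics import balanced_accuracy_score

    y_true = np.array([0] * 30 + [1] * 10 + [2] * 5)
    y_pred = np.zeros_like(y_true)
    assert balanced_accuracy_score(y_true, y_pred) == pytest.approx(1 / 3)
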