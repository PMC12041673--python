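"""Validation protocols: stratified partitioning, MCCV bookkeeping,
leakage tripwires, and the encoding comparison."""

import numpy as np
import pytest

from diatraj import (EvalConfig, Gender, MinMaxNormalizer, ModelSpec,
                     compare_encodings, run_mccv, run_partitioned_validation,
                     stratified_partition)
from diatraj.endpoints import EndpointDataset, LabeledInstance
from diatraj.evaluate import METRIC_COLUMNS
from diatraj.records import Visit


def _inst(pid, label, pairs, endpoint="910", gender=Gender.MALE):
    visits = [Visit(a, [c]) for a, c in pairs]
    return LabeledInstance(pid, gender, visits, label, endpoint)


def _separable_dataset(n=200):
    """Positives carry the (1060, 913) pair; negatives never do."""
    instances = []
    for i in range(n):
        label = i % 2
        pairs = [("1050", "401")]
        pairs.append(("1060", "913") if label else ("1060", "402"))
        instances.append(_inst(i, label, pairs))
    return EndpointDataset("910", instances, 0, n // 2, n // 2, n // 2)


def _noisy_dataset(n, seed, signal=0.85):
    """Signal pair present with asymmetric probability per class."""
    rng = np.random.default_rng(seed)
    instances = []
    fillers = [("1050", "402"), ("1060", "914"), ("1070", "1302")]
    for i in range(n):
        label = i % 2
        pairs = [("1050", "401")]
        p = signal if label else 1 - signal
        if rng.random() < p:
            pairs.append(("1060", "913"))
        for f in fillers:
            if rng.random() < 0.3:
                pairs.append(f)
        gender = Gender.MALE if rng.random() < 0.5 else Gender.FEMALE
        instances.append(_inst(i, label, pairs, gender=gender))
    return EndpointDataset("910", instances, 0, n // 2, n // 2, n // 2)


class TestStratifiedPartition:
    def test_small_exact_case(self):
        y = np.r_[np.ones(100), np.zeros(100)].astype(int)
        train, subsets = stratified_partition(y, seed=4)
        assert len(train) == 150
        seen = set(train.tolist())
        for s in subsets:
            assert len(s) == 10
            assert y[s].sum() == 5  # stratified: 5 per class
            assert not seen & set(s.tolist())
            seen |= set(s.tolist())
        assert len(seen) == 200

    def test_deterministic_given_seed(self):
        y = np.r_[np.ones(60), np.zeros(140)].astype(int)
        a = stratified_partition(y, seed=9)
        b = stratified_partition(y, seed=9)
        assert np.array_equal(a[0], b[0])
        assert all(np.array_equal(x, z) for x, z in zip(a[1], b[1]))

    def test_zero_subset_size_errors(self):
        with pytest.raises(ValueError):
            stratified_partition(np.array([0, 1] * 5), seed=0)

    def test_imbalanced_counts_proportional(self):
        y = np.r_[np.ones(30), np.zeros(170)].astype(int)
        _, subsets = stratified_partition(y, seed=2)
        for s in subsets:
            assert len(s) == 10
            assert y[s].sum() in (1, 2)  # 15% of 10 with remainder rounding


class TestMCCV:
    def test_single_run_summary_equals_run_metrics(self):
        ds = _separable_dataset()
        cfg = EvalConfig(k_repeats=1, repetitions=1,
                         feature_subset_sizes=("all",), seed=1)
        report = run_mccv(ds, [ModelSpec("decision_tree")], cfg)
        assert len(report.runs) == 1
        summary = report.summary()
        for m in METRIC_COLUMNS:
            assert summary[m].iloc[0] == report.runs[m].iloc[0]

    def test_summary_reconciles_with_run_log(self):
        ds = _noisy_dataset(200, seed=3)
        cfg = EvalConfig(k_repeats=3, repetitions=1,
                         feature_subset_sizes=(2, "all"), seed=5)
        report = run_mccv(ds, [ModelSpec("decision_tree"),
                               ModelSpec("xgboost")], cfg)
        summary = report.summary().set_index(["family", "subset_size"])
        manual = report.runs.groupby(["family", "subset_size"])["auc"].mean()
        for key, val in manual.items():
            assert summary.loc[key, "auc"] == pytest.approx(val)

    def test_perfectly_separable_data_scores_one(self):
        ds = _separable_dataset()
        cfg = EvalConfig(k_repeats=2, repetitions=1,
                         feature_subset_sizes=("all",), seed=2)
        report = run_mccv(ds, [ModelSpec("random_forest")], cfg)
        assert (report.runs["auc"] == 1.0).all()
        assert (report.runs["accuracy"] == 1.0).all()

    def test_subset_size_capped_with_warning(self):
        ds = _separable_dataset(60)
        cfg = EvalConfig(k_repeats=1, repetitions=1,
                         feature_subset_sizes=(500,), seed=0)
        with pytest.warns(UserWarning, match="capped"):
            report = run_mccv(ds, [ModelSpec("decision_tree")], cfg)
        assert report.runs["n_features"].iloc[0] <= 500


def test_normalizer_state_ignores_evaluation_rows():
    """Mutating evaluation rows must not change the fitted scaler."""
    rng = np.random.default_rng(0)
    X = rng.random((50, 4))
    train = np.arange(30)
    a = MinMaxNormalizer().fit(X, train)
    X_mut = X.copy()
    X_mut[30:] *= 100
    b = MinMaxNormalizer().fit(X_mut, train)
    assert np.array_equal(a.col_min, b.col_min)
    assert np.array_equal(a.col_max, b.col_max)


class TestPartitionedValidation:
    def test_perfect_separability_all_subsets_one(self):
        ds = _separable_dataset(200)
        cfg = EvalConfig(protocol="partitioned", seed=3)
        report = run_partitioned_validation(ds, [ModelSpec("random_forest")], cfg)
        assert len(report.runs) == 5
        assert (report.runs["auc"] == 1.0).all()
        assert (report.runs["accuracy"] == 1.0).all()
        assert list(report.runs["subset"]) == ["v1", "v2", "v3", "v4", "v5"]

    def test_subset_dispersion_shrinks_with_dataset_size(self):
        """Per-subset AUC spread is wider on a small dataset than on a
        large one drawn from the same process."""
        cfg = EvalConfig(protocol="partitioned", seed=8)
        small = run_partitioned_validation(
            _noisy_dataset(300, seed=1, signal=0.75),
            [ModelSpec("random_forest")], cfg)
        large = run_partitioned_validation(
            _noisy_dataset(3000, seed=1, signal=0.75),
            [ModelSpec("random_forest")], cfg)
        assert large.runs["auc"].std() < small.runs["auc"].std()


class TestCompareEncodings:
    def test_report_shape(self):
        ds = _noisy_dataset(200, seed=6)
        cfg = EvalConfig(k_repeats=2, repetitions=1, seed=4)
        table = compare_encodings(ds, cfg)
        assert list(table["fs_model"]) == [
            "BoF (all features)", "Proposed (all features)",
            "Proposed + XGB FS"]
        assert set(METRIC_COLUMNS) <= set(table.columns)

    def test_code_only_signal_gives_similar_encodings(self, codebook):
        """When the outcome depends on codes alone (no age interaction),
        the pair encoding and BoF land within 0.03 AUC of each other."""
        from diatraj import (EndpointHazard, SimConfig,
                             build_endpoint_dataset, generate_cohort,
                             preprocess_cohort)

        pairs = {(a, "913"): 1.5 for a in codebook.age_labels}
        hz = {ep: EndpointHazard(intercept=-1e9)
              for ep in codebook.endpoint_codes}
        hz["910"] = EndpointHazard(intercept=-4.0, coefficients=pairs)
        cohort, _ = generate_cohort(
            SimConfig(n_patients=2500, seed=15, endpoint_hazard=hz))
        records, _ = preprocess_cohort(cohort, codebook)
        ds, _ = build_endpoint_dataset(records, "910", seed=1)
        cfg = EvalConfig(k_repeats=10, repetitions=1, seed=7)
        table = compare_encodings(ds, cfg).set_index("fs_model")
        bof = table.loc["BoF (all features)", "auc"]
        proposed = table.loc["Proposed (all features)", "auc"]
        assert abs(proposed - bof) <= 0.03
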