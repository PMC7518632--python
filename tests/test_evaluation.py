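import itertools

import numpy as np
import pytest

from metabrand.cohort import CohortTable, ParticipantRecord
from metabrand.evaluation import (
    EvaluationReport,
    aggregate_cv,
    confusion_metrics,
    stratified_holdout,
    stratified_kfold,
)


def make_cohort(n_amci=61, n_control=59):
    records = []
    for i in range(n_amci + n_control):
        records.append(ParticipantRecord(
            participant_id=f"P{i:04d}", age=60 + (i % 20), gender="Female",
            education_years=12, marital_status="Married", apoe4="Negative",
            label="aMCI" if i < n_amci else "Control",
        ))
    return CohortTable(records=tuple(records))


class TestHoldout:
    def test_published_style_split_sizes(self):
        cohort = make_cohort(61, 59)
        plan = stratified_holdout(cohort, 21 / 120, seed=0)
        assert len(plan.train_ids) == 99
        assert len(plan.test_ids) == 21
        assert sum(plan.test_class_counts.values()) == 21
        assert all(v > 0 for v in plan.test_class_counts.values())

    def test_deterministic(self):
        cohort = make_cohort()
        a = stratified_holdout(cohort, 0.25, seed=5)
        b = stratified_holdout(cohort, 0.25, seed=5)
        assert a == b
        c = stratified_holdout(cohort, 0.25, seed=6)
        assert a.test_ids != c.test_ids

    def test_partition_properties(self):
        cohort = make_cohort(30, 20)
        plan = stratified_holdout(cohort, 0.3, seed=1)
        assert not set(plan.train_ids) & set(plan.test_ids)
        assert set(plan.train_ids) | set(plan.test_ids) == set(cohort.ids)
        assert all(v > 0 for v in plan.train_class_counts.values())

    def test_stratification_bound(self):
        cohort = make_cohort(40, 60)
        plan = stratified_holdout(cohort, 0.25, seed=2)
        for lab, total in (("aMCI", 40), ("Control", 60)):
            frac = plan.test_class_counts[lab] / total
            assert abs(frac - 0.25) < 1 / total + 1e-9

    def test_single_class_rejected(self):
        cohort = make_cohort(10, 0)
        with pytest.raises(ValueError, match="single class"):
            stratified_holdout(cohort, 0.2, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_holdout(make_cohort(), 1.5, seed=0)


class TestKFold:
    def test_fold_sizes_for_99(self):
        cohort = make_cohort(51, 48)
        folds = stratified_kfold(cohort.ids, cohort.labels, k=5, seed=0)
        sizes = sorted(len(val) for _, val in folds)
        assert sizes == [19, 20, 20, 20, 20]
        all_val = [pid for _, val in folds for pid in val]
        assert sorted(all_val) == sorted(cohort.ids)

    def test_every_fold_contains_both_classes(self):
        cohort = make_cohort(51, 48)
        labels = dict(zip(cohort.ids, cohort.labels))
        for train, val in stratified_kfold(cohort.ids, cohort.labels, k=5, seed=3):
            for part in (train, val):
                assert {labels[p] for p in part} == {"aMCI", "Control"}

    def test_k_boundaries(self):
        cohort = make_cohort(10, 10)
        with pytest.raises(ValueError):
            stratified_kfold(cohort.ids, cohort.labels, k=1)
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold(cohort.ids, cohort.labels, k=11)


class TestConfusionMetrics:
    def test_hand_counted_example(self):
        y_true = ["aMCI", "aMCI", "aMCI", "Control", "Control"]
        y_pred = ["aMCI", "Control", "aMCI", "Control", "aMCI"]
        r = confusion_metrics(y_true, y_pred)
        assert (r.tp, r.fn, r.tn, r.fp) == (2, 1, 1, 1)
        assert r.sensitivity == pytest.approx(2 / 3, abs=1e-3)
        assert r.specificity == pytest.approx(0.5)
        assert r.accuracy == pytest.approx(0.6)
        assert r.f1 == pytest.approx(2 / 3, abs=1e-3)

    def test_perfect_prediction(self):
        y = ["aMCI", "Control", "aMCI"]
        r = confusion_metrics(y, y)
        assert r.sensitivity == r.specificity == r.accuracy == r.f1 == 1.0

    def test_all_predicted_positive(self):
        r = confusion_metrics(["aMCI", "Control"], ["aMCI", "aMCI"])
        assert r.sensitivity == 1.0 and r.specificity == 0.0

    def test_undefined_ratios_are_none_not_zero(self):
        r = confusion_metrics(["Control", "Control"], ["Control", "Control"])
        assert r.sensitivity is None
        assert r.precision is None
        assert r.specificity == 1.0

    def test_length_mismatch_and_bad_labels(self):
        with pytest.raises(ValueError, match="length"):
            confusion_metrics(["aMCI"], ["aMCI", "Control"])
        with pytest.raises(ValueError, match="unknown label"):
            confusion_metrics(["MCI"], ["aMCI"])
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    def test_exhaustive_oracle_up_to_length_4(self):
        """Agree with a brute-force recount over all label vectors."""
        labels = ("aMCI", "Control")
        for n in (1, 2, 3, 4):
            for y_true in itertools.product(labels, repeat=n):
                for y_pred in itertools.product(labels, repeat=n):
                    r = confusion_metrics(list(y_true), list(y_pred))
                    tp = sum(t == p == "aMCI" for t, p in zip(y_true, y_pred))
                    tn = sum(t == p == "Control" for t, p in zip(y_true, y_pred))
                    assert r.tp == tp and r.tn == tn
                    assert r.total == n
                    if r.accuracy is not None:
                        assert r.accuracy == pytest.approx((tp + tn) / n)


class TestAggregate:
    def _report(self, tp, fp, tn, fn):
        return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn)

    def test_identical_reports_zero_sd(self):
        reports = [self._report(3, 1, 4, 2)] * 5
        agg = aggregate_cv(reports)
        for mean, sd in agg.values():
            assert sd == 0.0

    def test_mean_accuracy(self):
        # accuracies 0.6, 0.7, 0.8 over 10 each
        reports = [
            self._report(3, 2, 3, 2),
            self._report(4, 2, 3, 1),
            self._report(4, 1, 4, 1),
        ]
        mean, sd = aggregate_cv(reports)["accuracy"]
        assert mean == pytest.approx(0.7)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        reports = [
            self._report(*rng.integers(1, 10, size=4)) for _ in range(5)
        ]
        agg = aggregate_cv(reports, ddof=1)
        accs = [r.accuracy for r in reports]
        assert agg["accuracy"][0] == pytest.approx(sum(accs) / 5)
        mean = sum(accs) / 5
        var = sum((a - mean) ** 2 for a in accs) / 4
        assert agg["accuracy"][1] == pytest.approx(var ** 0.5)

    def test_requires_at_least_two(self):
        with pytest.raises(ValueError):
            aggregate_cv([self._report(1, 1, 1, 1)])
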