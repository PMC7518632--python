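"""Splits, cross-validation, confusion metrics, and the ablation runner.

aMCI is the positive class everywhere: sensitivity is the true-positive
rate on aMCI, specificity the true-negative rate on controls.  Ratios
with a zero denominator are reported as ``None`` ("undefined"), never
silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable, LABELS, Scheme, VARIABLE_ORDER, bin_record
from .branding import MarkerSet
from .enhancement import ClaheParams, NlMeansParams, PreparedVolume
from .features import Backbone, FeatureSequence, enhance_volume, scan_to_sequence
from . import classifier as clf

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "stratified_holdout",
    "stratified_kfold",
    "confusion_metrics",
    "aggregate_cv",
    "run_ablation",
    "ABLATION_CONTEXTS",
]

#: Ablation contexts: the full marker set first, then each variable
#: omitted in turn.
ABLATION_CONTEXTS = ("none",) + VARIABLE_ORDER


@dataclass(frozen=True)
class SplitPlan:
    """A train/test partition of participant ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_class_counts: dict[str, int]
    test_class_counts: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def stratified_holdout(
    cohort: CohortTable, test_fraction: float, seed: int = 0
) -> SplitPlan:
    """Class-wise random train/test split.

    The test-set size is ``round(test_fraction * n)``, allocated across
    classes proportionally (largest-remainder rounding), then sampled
    without replacement within each class.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    counts = cohort.class_counts()
    present = [lab for lab in LABELS if counts[lab] > 0]
    if len(present) < 2:
        raise ValueError(f"cohort contains a single class: {counts}")
    n = len(cohort)
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ValueError(f"test_fraction {test_fraction} yields test size {n_test}")

    # proportional allocation with largest remainders
    quotas = {lab: test_fraction * counts[lab] for lab in present}
    alloc = {lab: int(math.floor(q)) for lab, q in quotas.items()}
    short = n_test - sum(alloc.values())
    for lab in sorted(present, key=lambda l: quotas[l] - alloc[l], reverse=True)[:short]:
        alloc[lab] += 1

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for lab in present:
        ids = [r.participant_id for r in cohort if r.label == lab]
        take = min(alloc[lab], len(ids) - 1)  # keep both classes in train
        chosen = rng.choice(len(ids), size=take, replace=False)
        test_ids.extend(ids[i] for i in sorted(chosen))
    test_set = set(test_ids)
    train_ids = [pid for pid in cohort.ids if pid not in test_set]
    by_id = {r.participant_id: r.label for r in cohort}
    return SplitPlan(
        train_ids=tuple(train_ids),
        test_ids=tuple(test_ids),
        train_class_counts={lab: sum(by_id[i] == lab for i in train_ids) for lab in LABELS},
        test_class_counts={lab: sum(by_id[i] == lab for i in test_ids) for lab in LABELS},
        seed=int(seed),
    )


def stratified_kfold(
    ids: Sequence[str], labels: Sequence[str], k: int = 5, seed: int = 0
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """k class-wise partitions: (train_ids, validation_ids) pairs.

    Every id appears in exactly one validation fold; folds are near
    equal in size and each preserves the class mix.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    labels = list(labels)
    ids = list(ids)
    if len(ids) != len(labels):
        raise ValueError("ids and labels length mismatch")
    for lab in set(labels):
        if labels.count(lab) < k:
            raise ValueError(
                f"class {lab!r} has {labels.count(lab)} members, fewer than k={k}"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    y = np.array(labels)
    for train_idx, val_idx in splitter.split(np.zeros(len(ids)), y):
        folds.append(
            (tuple(ids[i] for i in train_idx), tuple(ids[i] for i in val_idx))
        )
    return folds


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and derived metrics for one evaluation.

    ``context`` records what was evaluated: the fold or test set, the
    input mode, and (for ablations) the omitted variable or "none".
    """

    tp: int
    fp: int
    tn: int
    fn: int
    context: str = "test"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def accuracy(self) -> float | None:
        return _ratio(self.tp + self.tn, self.total)

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.sensitivity
        if p is None or r is None or (p + r) == 0:
            return None
        return 2.0 * p * r / (p + r)

    def metrics(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "precision": self.precision,
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], context: str = "test"
) -> EvaluationReport:
    """Confusion counts and metrics with aMCI as the positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    for lab in list(y_true) + list(y_pred):
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}; expected one of {LABELS}")
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == "aMCI" and p == "aMCI")
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == "aMCI" and p == "Control")
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == "Control" and p == "Control")
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == "Control" and p == "aMCI")
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn, context=context)


def aggregate_cv(
    reports: Sequence[EvaluationReport], ddof: int = 1
) -> dict[str, tuple[float, float]]:
    """Per-metric mean and standard deviation across folds.

    ``ddof=1`` (sample convention) by default; pass ``ddof=0`` for the
    population convention.  Undefined metric values are excluded from a
    metric's aggregate.
    """
    if len(reports) < 2:
        raise ValueError("aggregation needs at least two fold reports")
    out: dict[str, tuple[float, float]] = {}
    for name in ("sensitivity", "specificity", "f1", "accuracy", "precision"):
        values = [r.metrics()[name] for r in reports if r.metrics()[name] is not None]
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
        out[name] = (float(arr.mean()), sd)
    return out


def run_ablation(
    cohort: CohortTable,
    volumes: Mapping[str, PreparedVolume],
    markers: MarkerSet,
    backbone: Backbone,
    config: "clf.ClassifierConfig",
    test_fraction: float = 0.25,
    split_seed: int = 0,
    clahe_params: ClaheParams | None = None,
    nlm_params: NlMeansParams | None = None,
    contexts: Sequence[str] = ABLATION_CONTEXTS,
    enhanced_cache: Mapping[str, Sequence] | None = None,
    split: SplitPlan | None = None,
) -> list[EvaluationReport]:
    """Covariate-omission study on one fixed test split.

    Runs the branded pipeline once with all five markers and once per
    omitted variable — six evaluations on the identical train/test
    split with identical seeds, so the only difference between runs is
    the omitted marker.  Per participant, the original-mode enhanced
    slices are computed once and every branded variant's enhancement is
    derived from them exactly (branding only edits the top band).
    """
    if split is None:
        split = stratified_holdout(cohort, test_fraction, split_seed)
    by_id = {r.participant_id: r for r in cohort}
    include_sets = {
        ctx: tuple(v for v in VARIABLE_ORDER if v != ctx) for ctx in contexts
    }

    # features per context, keyed by participant id
    feats: dict[str, dict[str, FeatureSequence]] = {ctx: {} for ctx in contexts}
    for pid in cohort.ids:
        record = by_id[pid]
        meta = bin_record(record, cohort.scheme)
        volume = volumes[pid]
        if enhanced_cache is not None and pid in enhanced_cache:
            enhanced = enhanced_cache[pid]
        else:
            enhanced = enhance_volume(volume, clahe_params, nlm_params)
        for ctx in contexts:
            feats[ctx][pid] = scan_to_sequence(
                volume, backbone, mode="branded", meta=meta, markers=markers,
                include=include_sets[ctx], clahe_params=clahe_params,
                nlm_params=nlm_params, participant_id=pid,
                enhanced_original=enhanced,
            )

    reports = []
    for ctx in contexts:
        X_train = np.stack([feats[ctx][pid].matrix for pid in split.train_ids])
        y_train = [by_id[pid].label for pid in split.train_ids]
        X_test = np.stack([feats[ctx][pid].matrix for pid in split.test_ids])
        y_test = [by_id[pid].label for pid in split.test_ids]
        model = clf.build_classifier(config)
        clf.fit(model, X_train, y_train)
        y_pred = list(model.predict(X_test))
        label = "all_variables" if ctx == "none" else f"without_{ctx}"
        reports.append(confusion_metrics(y_test, y_pred, context=label))
    return reports
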