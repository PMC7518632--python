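"""End-to-end orchestration: configuration, runs, and provenance.

A run executes: simulate or load → brand → enhance → extract → train
(k-fold cross-validation on the training portion) → evaluate on the
held-out test portion → optional covariate ablation.  All randomness
flows from three named seeds (``marker_seed``, ``split_seed``,
``train_seed``); a run manifest records the configuration snapshot,
package version, input/output digests and timestamps so a run can be
reproduced bit-identically on one platform.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .branding import build_marker_set
from .classifier import (
    ClassifierConfig,
    build_classifier,
    encode_clinical,
    fit,
    wide_deep_fuse,
)
from .cohort import CohortTable, Scheme, bin_record, read_cohort_table
from .enhancement import ClaheParams, NlMeansParams, PreparedVolume, load_volume
from .evaluation import (
    EvaluationReport,
    aggregate_cv,
    confusion_metrics,
    run_ablation,
    stratified_holdout,
    stratified_kfold,
)
from .features import FeatureSequence, enhance_volume, scan_to_sequence, surrogate_backbone
from .synthetic import (
    CohortParams,
    PhantomParams,
    mechanism_cohort_params,
    simulate_cohort,
)

logger = logging.getLogger("metabrand")

__all__ = ["RunConfig", "RunManifest", "run_experiment", "PRESETS"]

#: Named synthetic presets: (cohort params factory, image signal, metadata signal)
PRESETS = ("smoke", "null", "metadata-only")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; serializable to/from YAML or JSON."""

    mode: str = "branded"  # original | branded | widedeep
    scheme: str = "HNR"
    include: tuple[str, ...] | None = None
    marker_seed: int = 42
    split_seed: int = 0
    train_seed: int = 0
    test_fraction: float = 0.25
    k: int = 5
    backbone: str = "surrogate"
    clahe: ClaheParams = field(default_factory=ClaheParams)
    nlmeans: NlMeansParams = field(default_factory=NlMeansParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    # inputs: either a named synthetic preset, or cohort CSV + volume dir
    preset: str | None = None
    preset_n: int = 20
    cohort_csv: str | None = None
    volumes_dir: str | None = None
    out_dir: str | None = None
    with_ablation: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("clahe", ClaheParams), ("nlmeans", NlMeansParams),
                         ("classifier", ClassifierConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in data[key].items()
                })
        if "include" in data and data["include"] is not None:
            data["include"] = tuple(data["include"])
        return cls(**data)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))


@dataclass
class RunManifest:
    """Provenance of one run."""

    config: dict
    package_version: str
    started: str
    finished: str = ""
    digests: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def _digest_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.preset is not None:
        n = config.preset_n
        if config.preset == "smoke":
            cohort_params = mechanism_cohort_params(n, 10.0)
            image, meta_sig = True, True
        elif config.preset == "null":
            cohort_params = mechanism_cohort_params(n, 1.0)
            image, meta_sig = False, False
        elif config.preset == "metadata-only":
            cohort_params = mechanism_cohort_params(n, 10.0)
            image, meta_sig = False, True
        else:
            raise ValueError(f"unknown preset {config.preset!r}; known: {PRESETS}")
        return simulate_cohort(
            cohort_params, PhantomParams(), image_signal=image,
            metadata_signal=meta_sig, seed=config.split_seed,
        )
    if config.cohort_csv is None or config.volumes_dir is None:
        raise ValueError("either a preset or cohort_csv + volumes_dir is required")
    cohort = read_cohort_table(config.cohort_csv, config.scheme)
    volumes_dir = Path(config.volumes_dir)
    if not volumes_dir.exists():
        raise FileNotFoundError(f"volume directory not found: {volumes_dir}")
    volumes = {}
    for record in cohort:
        pid = record.participant_id
        for candidate in (
            volumes_dir / f"{pid}.nii.gz",
            volumes_dir / f"{pid}.nii",
            volumes_dir / pid,
        ):
            if candidate.exists():
                volumes[pid] = load_volume(candidate)
                break
        else:
            raise FileNotFoundError(f"no volume found for participant {pid!r} in {volumes_dir}")
    return cohort, volumes


def run_experiment(config: RunConfig):
    """Execute a full run; returns (reports dict, manifest).

    ``reports`` maps ``"cv"`` to the per-fold reports and their
    mean ± sd aggregate, ``"test"`` to the held-out test report, and
    (if requested) ``"ablation"`` to the six covariate-omission
    reports.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    t0 = time.time()
    manifest = RunManifest(config=config.to_dict(), package_version=__version__,
                           started=started)
    stage = "load"
    try:
        cohort, volumes = _load_inputs(config)
        logger.info("stage=load n=%d elapsed=%.1fs", len(cohort), time.time() - t0)

        stage = "markers"
        markers = build_marker_set(config.marker_seed, cohort.scheme)

        stage = "extract"
        if config.backbone != "surrogate":
            from .features import pretrained_backbone

            backbone = pretrained_backbone(config.backbone)
        else:
            backbone = surrogate_backbone()
        feats: dict[str, np.ndarray] = {}
        enhanced_cache: dict[str, list] = {}
        by_id = {r.participant_id: r for r in cohort}
        for pid in cohort.ids:
            volume = volumes[pid]
            enhanced = enhance_volume(volume, config.clahe, config.nlmeans)
            enhanced_cache[pid] = enhanced
            meta = bin_record(by_id[pid], cohort.scheme)
            if config.mode == "branded":
                seq = scan_to_sequence(
                    volume, backbone, mode="branded", meta=meta, markers=markers,
                    include=config.include, clahe_params=config.clahe,
                    nlm_params=config.nlmeans, participant_id=pid,
                    enhanced_original=enhanced,
                )
            else:
                seq = scan_to_sequence(
                    volume, backbone, mode="original", participant_id=pid,
                    clahe_params=config.clahe, nlm_params=config.nlmeans,
                    enhanced_original=enhanced,
                )
                if config.mode == "widedeep":
                    seq = wide_deep_fuse(
                        seq, encode_clinical(meta, cohort.scheme),
                        projection_seed=config.train_seed,
                    )
            feats[pid] = seq.matrix
        manifest.digests["features"] = _digest_array(
            np.stack([feats[pid] for pid in cohort.ids])
        )
        logger.info("stage=extract elapsed=%.1fs", time.time() - t0)

        stage = "split"
        split = stratified_holdout(cohort, config.test_fraction, config.split_seed)
        labels = {r.participant_id: r.label for r in cohort}

        stage = "cross-validation"
        folds = stratified_kfold(
            split.train_ids, [labels[p] for p in split.train_ids],
            k=config.k, seed=config.split_seed,
        )
        cv_reports = []
        for fold_idx, (fold_train, fold_val) in enumerate(folds):
            cfg = replace(config.classifier, seed=config.train_seed + fold_idx)
            model = build_classifier(cfg)
            fit(model, np.stack([feats[p] for p in fold_train]),
                [labels[p] for p in fold_train])
            y_pred = list(model.predict(np.stack([feats[p] for p in fold_val])))
            cv_reports.append(
                confusion_metrics([labels[p] for p in fold_val], y_pred,
                                  context=f"fold{fold_idx}/{config.mode}")
            )
        cv_aggregate = aggregate_cv(cv_reports)
        logger.info("stage=cv elapsed=%.1fs", time.time() - t0)

        stage = "test"
        cfg = replace(config.classifier, seed=config.train_seed)
        model = build_classifier(cfg)
        fit(model, np.stack([feats[p] for p in split.train_ids]),
            [labels[p] for p in split.train_ids])
        y_pred = list(model.predict(np.stack([feats[p] for p in split.test_ids])))
        test_report = confusion_metrics(
            [labels[p] for p in split.test_ids], y_pred,
            context=f"test/{config.mode}",
        )

        reports = {"cv": cv_reports, "cv_aggregate": cv_aggregate, "test": test_report}

        if config.with_ablation:
            stage = "ablation"
            reports["ablation"] = run_ablation(
                cohort, volumes, markers, backbone, cfg,
                test_fraction=config.test_fraction, split_seed=config.split_seed,
                clahe_params=config.clahe, nlm_params=config.nlmeans,
                enhanced_cache=enhanced_cache, split=split,
            )
            logger.info("stage=ablation elapsed=%.1fs", time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"run failed at stage {stage!r}: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_reports(reports, out)
        manifest.write(out / "manifest.json")
    return reports, manifest


def _report_rows(report: EvaluationReport) -> dict:
    row = {"context": report.context, "tp": report.tp, "fp": report.fp,
           "tn": report.tn, "fn": report.fn}
    row.update({
        k: ("" if v is None else round(v, 4)) for k, v in report.metrics().items()
    })
    return row


def _write_reports(reports: dict, out: Path) -> None:
    import csv

    def write_csv(path: Path, rows: list[dict]) -> None:
        if not rows:
            return
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)

    write_csv(out / "cv_reports.csv", [_report_rows(r) for r in reports["cv"]])
    write_csv(out / "test_report.csv", [_report_rows(reports["test"])])
    if "ablation" in reports:
        write_csv(out / "ablation_reports.csv",
                  [_report_rows(r) for r in reports["ablation"]])
    agg_rows = [
        {"metric": m, "mean": round(mean, 4), "sd": round(sd, 4)}
        for m, (mean, sd) in reports["cv_aggregate"].items()
    ]
    write_csv(out / "cv_aggregate.csv", agg_rows)
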