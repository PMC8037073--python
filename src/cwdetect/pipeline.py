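"""End-to-end orchestration of training and detection.

Training ("indicator-model computing"): preprocess every labeled record,
segment into 1-minute slots, run the Choi-Williams analysis, truncate the
negative part, extract ST/PR band percentages, and fit the per-lead
one-vs-one SVM. Detection ("normal operation") repeats the identical signal
chain on an unknown record and maps each minute through the trained model.

All stages are deterministic under the configured seed; each stage's output
is a file another stage (or the CLI verb for it) can consume.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .config import PipelineConfig
from .errors import ValidationError
from .features import extract_dataset
from .preprocess import preprocess_record, segment_minutes
from .records import ECGRecord, FeatureTable
from .svm import ClassDecision, TrainedModel, evaluate, kfold_cv, predict, train

logger = logging.getLogger(__name__)

POSITIVE = ("ischemia", "infarction")


@dataclass
class DetectionSummary:
    """Per-record roll-up of minute-level decisions."""

    record_id: str
    decisions: list[ClassDecision]
    minutes: int = field(init=False)
    fraction_ischemic: float = field(init=False)

    def __post_init__(self) -> None:
        self.minutes = len(self.decisions)
        flagged = sum(d.fused_label in POSITIVE for d in self.decisions)
        self.fraction_ischemic = flagged / self.minutes if self.minutes else 0.0


def prepare(record: ECGRecord, config: PipelineConfig) -> ECGRecord:
    """The shared conditioning chain: resample, filter, scale."""
    return preprocess_record(
        record,
        target_fs=config.target_fs,
        hp_cutoff=config.hp_cutoff,
        passband=(config.bp_low, config.bp_high),
        hp_taps=config.hp_taps,
        bp_taps=config.bp_taps,
    )


def compute_features(records: list[ECGRecord], config: PipelineConfig) -> FeatureTable:
    """Preprocess + segment + Choi-Williams ST/PR extraction for a corpus."""
    segments = []
    for rec in records:
        t0 = time.perf_counter()
        segments.extend(segment_minutes(prepare(rec, config)))
        logger.info("prepared %s in %.2f s", rec.record_id, time.perf_counter() - t0)
    t0 = time.perf_counter()
    table = extract_dataset(segments, config.tfd)
    logger.info("extracted %d feature rows in %.2f s", len(table), time.perf_counter() - t0)
    return table


def run_training(
    records: list[ECGRecord],
    config: PipelineConfig | None = None,
    cross_validate: bool = False,
) -> tuple[TrainedModel, dict]:
    """Full training pass; returns the model and a metrics report.

    The report carries the feature table, training-set confusion matrix, and
    (optionally) record-stratified k-fold cross-validation metrics.
    """
    config = config or PipelineConfig()
    if not records:
        raise ValidationError("no training records supplied")
    if any(r.label is None for r in records):
        missing = [r.record_id for r in records if r.label is None]
        raise ValidationError(f"unlabeled training records: {missing}")

    table = compute_features(records, config)
    model = train(
        table, sigma_rbf=config.sigma_rbf, gamma_cost=config.gamma_cost, seed=config.seed
    )
    decisions = predict(model, table)
    report = {
        "features": table,
        "training": evaluate([d.fused_label for d in decisions], [d.truth for d in decisions]),
    }
    if cross_validate:
        report["cv"] = kfold_cv(
            table,
            k=config.k_folds,
            seed=config.seed,
            sigma_rbf=config.sigma_rbf,
            gamma_cost=config.gamma_cost,
        )
    return model, report


def run_detection(
    record: ECGRecord,
    model: TrainedModel,
    config: PipelineConfig | None = None,
) -> DetectionSummary:
    """Classify every minute of one record through a trained model."""
    config = config or PipelineConfig()
    prepared = prepare(record, config)
    unknown = sorted(set(prepared.lead_names) - set(model.lead_models))
    if unknown:
        raise ValidationError(
            f"record leads {unknown} unknown to the model; model covers {model.leads}"
        )
    table = extract_dataset(segment_minutes(prepared), config.tfd)
    decisions = predict(model, table)
    summary = DetectionSummary(record_id=record.record_id, decisions=decisions)
    logger.info(
        "%s: %d minutes, %.0f%% flagged ischemic/infarct",
        summary.record_id, summary.minutes, 100 * summary.fraction_ischemic,
    )
    return summary
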