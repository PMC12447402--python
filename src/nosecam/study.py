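"""In-memory study orchestration: one seed, one dataset, all tasks.

This is the file-free core used by the pipeline driver (which persists
artifacts around it) and by reproduction scripts: generate a synthetic
dataset, run leave-one-out CV for the CNN and the SVM/RF baselines on
each task, explain every sample with its held-out fold model, aggregate
the importance maps, and compare Score-CAM channel activity with RF
channel importance and with the generator's planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import (
    TASKS,
    CnnConfig,
    EvalReport,
    TrainedClassifier,
    baseline_fit_predict,
    loocv_tensors,
)
from .preprocess import FeatureVector, InputTensor, assemble_normalize, extract_baseline_features
from .report import (
    AveragedMap,
    ChannelImportance,
    average_maps,
    channel_activity,
    per_sample_maps,
    recovery_and_consistency,
)
from .report import rf_channel_importance
from .sensor_sim import AffinityModel, default_affinity_model, generate_dataset
from .xai import ImportanceMap

__all__ = ["TaskResult", "StudyResult", "evaluate_task", "run_study"]


@dataclass
class TaskResult:
    """Everything computed for one classification task."""

    task: str
    cnn: EvalReport
    svm: EvalReport
    rf: EvalReport
    rf_importances: np.ndarray
    rf_channels: ChannelImportance
    maps: list[ImportanceMap]
    averaged: dict[str, AveragedMap]
    class_activity: dict[str, ChannelImportance]
    task_activity: ChannelImportance | None
    fold_models: dict[str, TrainedClassifier] = field(repr=False, default_factory=dict)


@dataclass
class StudyResult:
    seed: int
    manifest: dict
    tasks: dict[str, TaskResult]
    summary: dict


def _task_seed(base: int, task_idx: int) -> int:
    return int(np.random.SeedSequence([base, 0x7A5C, task_idx]).generate_state(1)[0] % (2**31))


def evaluate_task(
    task_name: str,
    tensors: Sequence[InputTensor],
    features: Sequence[FeatureVector],
    labels: Sequence[str],
    sample_ids: Sequence[str],
    cnn_config: CnnConfig,
    baseline_seed: int = 0,
    scorecam_use_logits: bool = False,
    scorecam_subtract_baseline: bool = False,
    keep_fold_models: bool = False,
) -> TaskResult:
    """LOOCV all three classifiers, explain, and aggregate for one task."""
    cnn_report, fold_models = loocv_tensors(
        tensors, labels, cnn_config, sample_ids=sample_ids,
        task_name=task_name, keep_models=True,
    )
    svm_report, _ = baseline_fit_predict(
        features, labels, "svm", seed=baseline_seed,
        sample_ids=sample_ids, task_name=task_name)
    rf_report, rf_imp = baseline_fit_predict(
        features, labels, "rf", seed=baseline_seed,
        sample_ids=sample_ids, task_name=task_name)

    tensor_by_id = {t.sample_id: t.values for t in tensors}
    maps = per_sample_maps(
        tensor_by_id, cnn_report, fold_models,
        use_logits=scorecam_use_logits,
        subtract_baseline=scorecam_subtract_baseline,
    )
    averaged: dict[str, AveragedMap] = {}
    class_act: dict[str, ChannelImportance] = {}
    weights, vectors = [], []
    for cls in cnn_report.classes:
        avg = average_maps(maps, cnn_report, cls)
        averaged[cls] = avg
        if not avg.absent:
            ci = channel_activity(avg)
            class_act[cls] = ci
            weights.append(avg.n_contributing)
            vectors.append(ci.values)
    task_act = None
    if vectors:
        # classes weighted by how many correctly predicted samples contribute
        v = np.average(np.stack(vectors), axis=0, weights=np.asarray(weights, float))
        task_act = ChannelImportance(values=v / v.sum(), source="scorecam")

    return TaskResult(
        task=task_name,
        cnn=cnn_report,
        svm=svm_report,
        rf=rf_report,
        rf_importances=rf_imp,
        rf_channels=rf_channel_importance(rf_imp),
        maps=maps,
        averaged=averaged,
        class_activity=class_act,
        task_activity=task_act,
        fold_models=fold_models if keep_fold_models else {},
    )


def run_study(
    seed: int,
    tasks: Sequence[str] = ("category9", "oxygen2", "oxygen_count3", "ring2"),
    n_per_category: int = 5,
    noise_sigma: float = 0.02,
    cnn_config: CnnConfig | None = None,
    affinity_model: AffinityModel | None = None,
) -> StudyResult:
    """Run the full analysis for one dataset seed, entirely in memory.

    The Score-CAM channel activities (per class, plus a per-task
    aggregate keyed by the task name) are compared against the planted
    channels and the RF channel importances in ``summary``.
    """
    if cnn_config is None:
        cnn_config = CnnConfig()
    model = affinity_model or default_affinity_model(noise_sigma=noise_sigma)
    samples, manifest = generate_dataset(n_per_category, model, seed)
    tensors = [assemble_normalize(s) for s in samples]
    features = [extract_baseline_features(s) for s in samples]
    ids = [s.sample_id for s in samples]

    results: dict[str, TaskResult] = {}
    scorecam_activity: dict[str, ChannelImportance] = {}
    rf_activity: dict[str, ChannelImportance] = {}
    for ti, task_name in enumerate(tasks):
        task = TASKS[task_name]
        labels = [task.extract(s.molecule) for s in samples]
        cfg = CnnConfig(**{**cnn_config.__dict__, "seed": _task_seed(cnn_config.seed, ti)})
        tr = evaluate_task(task_name, tensors, features, labels, ids, cfg,
                           baseline_seed=seed)
        results[task_name] = tr
        scorecam_activity.update(tr.class_activity)
        if tr.task_activity is not None:
            scorecam_activity[task_name] = tr.task_activity
        rf_activity[task_name] = tr.rf_channels

    summary = recovery_and_consistency(scorecam_activity, rf_activity, manifest)
    return StudyResult(seed=seed, manifest=manifest, tasks=results, summary=summary)
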