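"""End-to-end pipeline: simulate -> preprocess -> classify -> explain -> report.

A run is a pure function of its :class:`PipelineConfig` (which includes
every seed); rerunning with the same config reproduces the numeric
outputs byte-identically.  Each stage persists its artifacts into the
run directory as it completes, so a failing stage leaves the earlier
stages' outputs on disk.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .models import TASKS, CnnConfig, EvalReport
from .preprocess import assemble_normalize, extract_baseline_features
from .report import AveragedMap, ChannelImportance, recovery_and_consistency
from .sensor_sim import N_CHANNELS, default_affinity_model, generate_dataset
from .study import _task_seed, evaluate_task

__all__ = ["ConfigError", "StageError", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run.

    ``seed`` drives the dataset; the CNN seed lives in ``cnn``.
    ``tasks`` selects which classification tasks to run.
    """

    outdir: str = "runs/run"
    seed: int = 42
    n_per_category: int = 5
    noise_sigma: float = 0.02
    tasks: tuple[str, ...] = ("category9", "oxygen2", "oxygen_count3", "ring2")
    cnn: CnnConfig = field(default_factory=CnnConfig)
    scorecam_use_logits: bool = False
    scorecam_subtract_baseline: bool = False
    write_raw_traces: bool = True
    save_heatmaps: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.cnn, dict):
            self.cnn = CnnConfig(**self.cnn)
        self.tasks = tuple(self.tasks)
        unknown = [t for t in self.tasks if t not in TASKS]
        if unknown:
            raise ConfigError(f"unknown task name(s) {unknown}; valid: {sorted(TASKS)}")
        if self.n_per_category < 1:
            raise ConfigError("n_per_category must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = list(self.tasks)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        _validate_config_schema(raw, path)
        return cls(**raw)


_SCHEMA: dict[str, type | tuple[type, ...]] = {
    "outdir": str,
    "seed": int,
    "n_per_category": int,
    "noise_sigma": (int, float),
    "tasks": list,
    "cnn": dict,
    "scorecam_use_logits": bool,
    "scorecam_subtract_baseline": bool,
    "write_raw_traces": bool,
    "save_heatmaps": bool,
}

_CNN_SCHEMA: dict[str, type | tuple[type, ...]] = {
    "conv_filters": list,
    "kernel": list,
    "dense": int,
    "dropout": (int, float),
    "epochs": int,
    "batch_size": int,
    "learning_rate": (int, float),
    "seed": int,
}


def _validate_config_schema(raw: dict, path) -> None:
    for key, val in raw.items():
        if key not in _SCHEMA:
            raise ConfigError(f"{path}: unknown config key {key!r}")
        if not isinstance(val, _SCHEMA[key]):
            raise ConfigError(f"{path}: key {key!r} must be {_SCHEMA[key]}")
    for key, val in raw.get("cnn", {}).items():
        if key not in _CNN_SCHEMA:
            raise ConfigError(f"{path}: unknown cnn key {key!r}")
        if not isinstance(val, _CNN_SCHEMA[key]):
            raise ConfigError(f"{path}: cnn key {key!r} must be {_CNN_SCHEMA[key]}")
    if "cnn" in raw:
        raw["cnn"] = {
            k: tuple(v) if k in ("conv_filters", "kernel") else v
            for k, v in raw["cnn"].items()
        }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        model = default_affinity_model(noise_sigma=config.noise_sigma)
        samples, manifest = generate_dataset(config.n_per_category, model, config.seed)
        nio.write_manifest(manifest, outdir / "dataset_manifest.json")
        if config.write_raw_traces:
            nio.write_traces(samples, outdir / "traces.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        tensors = [assemble_normalize(s) for s in samples]
        features = [extract_baseline_features(s) for s in samples]
        nio.save_tensors(tensors, outdir / "tensors.h5")
        nio.features_to_frame(features).to_csv(outdir / "features.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        sample_ids = [s.sample_id for s in samples]
        scorecam_activity: dict[str, ChannelImportance] = {}
        rf_activity: dict[str, ChannelImportance] = {}
        reports: dict[str, dict] = {}

        for ti, task_name in enumerate(config.tasks):
            task = TASKS[task_name]
            labels = [task.extract(s.molecule) for s in samples]

            stage = f"task[{task_name}]"
            t0 = time.perf_counter()
            cnn_cfg = CnnConfig(**{**config.cnn.__dict__,
                                   "seed": _task_seed(config.cnn.seed, ti)})
            tr = evaluate_task(
                task_name, tensors, features, labels, sample_ids, cnn_cfg,
                baseline_seed=config.seed,
                scorecam_use_logits=config.scorecam_use_logits,
                scorecam_subtract_baseline=config.scorecam_subtract_baseline,
            )
            reports[task_name] = {
                "cnn": tr.cnn.to_dict(),
                "svm": tr.svm.to_dict(),
                "rf": tr.rf.to_dict(),
            }
            _write_confusions(outdir, task_name, tr.cnn, tr.svm, tr.rf)
            map_dir = outdir / "maps" / task_name
            map_dir.mkdir(parents=True, exist_ok=True)
            for m in tr.maps:
                nio.importance_map_frame(m).to_csv(map_dir / f"{m.sample_id}.csv")
            for cls, avg in tr.averaged.items():
                if not avg.absent:
                    nio.importance_map_frame(_as_importance(avg)).to_csv(
                        map_dir / f"avg_{_slug(cls)}.csv")
                    if config.save_heatmaps:
                        _render_heatmap(avg, map_dir / f"avg_{_slug(cls)}.png")
            scorecam_activity.update(tr.class_activity)
            if tr.task_activity is not None:
                scorecam_activity[task_name] = tr.task_activity
            rf_activity[task_name] = tr.rf_channels
            timings[stage] = time.perf_counter() - t0

        stage = "consistency"
        summary = recovery_and_consistency(scorecam_activity, rf_activity, manifest)
        summary["channel_importance"] = {
            "scorecam": {k: v.values.tolist() for k, v in scorecam_activity.items()},
            "rf": {k: v.values.tolist() for k, v in rf_activity.items()},
        }
        nio.write_manifest(summary, outdir / "consistency.json")
        nio.write_manifest(reports, outdir / "eval_reports.json")

        run_manifest = {
            "config": config.to_dict(),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "versions": _versions(),
        }
        nio.write_manifest(run_manifest, outdir / "run_manifest.json")
    except (ConfigError, nio.DataError):
        raise
    except Exception as e:  # noqa: BLE001 - stage attribution is the contract
        raise StageError(stage, e) from e
    return outdir


def _slug(label: str) -> str:
    return label.replace(" ", "_")


def _as_importance(avg: AveragedMap):
    from .xai import ImportanceMap

    # averaged values stay in [0,1]; reuse the CSV writer
    return ImportanceMap(values=avg.values, target_class=avg.category,
                         sample_id=f"avg_{_slug(avg.category)}")


def _write_confusions(outdir: Path, task: str, *reports: EvalReport) -> None:
    import pandas as pd

    cdir = outdir / "confusion"
    cdir.mkdir(exist_ok=True)
    for rep, kind in zip(reports, ("cnn", "svm", "rf")):
        pd.DataFrame(rep.confusion, index=rep.classes, columns=rep.classes).to_csv(
            cdir / f"{task}_{kind}.csv"
        )


def _render_heatmap(avg: AveragedMap, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 5))
    im = ax.imshow(avg.values, aspect="auto", origin="lower",
                   extent=(0.5, N_CHANNELS + 0.5, 3, 120), cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_xlabel("channel")
    ax.set_ylabel("time (s)")
    ax.set_title(f"{avg.category} (n={avg.n_contributing})")
    fig.colorbar(im, ax=ax, label="importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _versions() -> dict:
    import sklearn

    import nosecam

    return {
        "nosecam": getattr(nosecam, "__version__", "unknown"),
        "numpy": np.__version__,
        "sklearn": sklearn.__version__,
    }
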