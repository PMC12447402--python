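"""Aggregation of importance maps and explanation/ground-truth checks.

Per-sample Score-CAM maps (each computed by the leave-one-out fold
model that held the sample out, with respect to the sample's PREDICTED
class) are averaged per class over the correctly predicted samples,
summarized into per-channel activity, and compared against (a) the
planted discriminative channels recorded by the synthetic generator and
(b) the random-forest channel importances derived from the 168-dim
baseline features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .models import EvalReport, TrainedClassifier
from .preprocess import FEATURE_NAMES, N_FEATURES, N_TIME_POINTS
from .sensor_sim import CONCENTRATIONS, N_CHANNELS
from .xai import ImportanceMap, scorecam

__all__ = [
    "AveragedMap",
    "ChannelImportance",
    "per_sample_maps",
    "average_maps",
    "channel_activity",
    "rf_channel_importance",
    "rank_consistency",
    "recovery_and_consistency",
]

logger = logging.getLogger(__name__)


@dataclass
class AveragedMap:
    """Elementwise mean of importance maps over correctly predicted samples.

    ``n_contributing`` counts the averaged samples; when it is zero the
    map is absent (``values is None``), never zero-filled.
    """

    category: str
    n_contributing: int
    values: np.ndarray | None

    def __post_init__(self) -> None:
        if self.n_contributing < 0:
            raise ValueError("n_contributing must be >= 0")
        if (self.n_contributing == 0) != (self.values is None):
            raise ValueError("values must be None exactly when n_contributing == 0")
        if self.values is not None:
            self.values = np.asarray(self.values, float)
            if self.values.shape != (N_TIME_POINTS, N_CHANNELS):
                raise ValueError("averaged map must be 40 x 14")

    @property
    def absent(self) -> bool:
        return self.n_contributing == 0


@dataclass
class ChannelImportance:
    """Nonnegative 14-vector summing to 1; ``source`` is 'scorecam' or 'rf'."""

    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (N_CHANNELS,):
            raise ValueError("channel importance must have length 14")
        if (self.values < 0).any():
            raise ValueError("channel importance must be nonnegative")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("channel importance must sum to 1")

    def top_channels(self, k: int = 2) -> list[int]:
        """The k highest-importance channels, 1-based, best first."""
        order = np.argsort(-self.values, kind="stable")
        return [int(i) + 1 for i in order[:k]]


def per_sample_maps(
    tensors: Mapping[str, np.ndarray],
    loocv_report: EvalReport,
    fold_models: Mapping[str, TrainedClassifier],
    use_logits: bool = False,
    subtract_baseline: bool = False,
) -> list[ImportanceMap]:
    """Explain every sample with its own held-out fold model.

    Each sample's map is computed with respect to the class PREDICTED
    for it during leave-one-out CV — the explanation asks "why was this
    sample classified the way it was", not "why should it have been".
    Samples with no fold model are skipped with a warning.
    """
    maps: list[ImportanceMap] = []
    for sid, pred in zip(loocv_report.sample_ids, loocv_report.y_pred):
        if sid not in fold_models:
            logger.warning("no fold model for sample %s; skipped", sid)
            continue
        m = scorecam(
            fold_models[sid], tensors[sid], pred,
            use_logits=use_logits, subtract_baseline=subtract_baseline,
        )
        m.sample_id = sid
        maps.append(m)
    return maps


def average_maps(
    maps: Sequence[ImportanceMap],
    loocv_report: EvalReport,
    category: str,
) -> AveragedMap:
    """Average the maps of samples with true == predicted == category.

    Individual maps are already in [0, 1]; they are averaged as-is and
    the result is NOT re-stretched, preserving comparability across
    classes with different numbers of contributing samples.
    """
    truth = dict(zip(loocv_report.sample_ids, loocv_report.y_true))
    pred = dict(zip(loocv_report.sample_ids, loocv_report.y_pred))
    selected = [
        m.values for m in maps
        if truth.get(m.sample_id) == category and pred.get(m.sample_id) == category
    ]
    if not selected:
        return AveragedMap(category=category, n_contributing=0, values=None)
    return AveragedMap(
        category=category,
        n_contributing=len(selected),
        values=np.mean(selected, axis=0),
    )


def channel_activity(avg: AveragedMap) -> ChannelImportance:
    """Per-channel activity: time-mean of the averaged map, unit-normalized.

    The time-mean (rather than time-max) is robust to single-point
    noise and matches the banded structure of averaged maps.
    """
    if avg.absent:
        raise ValueError(f"no correctly predicted samples for {avg.category!r}; map absent")
    per_channel = avg.values.mean(axis=0)
    total = per_channel.sum()
    if total <= 0:
        # a uniformly zero map carries no ranking information
        per_channel = np.full(N_CHANNELS, 1.0 / N_CHANNELS)
    else:
        per_channel = per_channel / total
    return ChannelImportance(values=per_channel, source="scorecam")


def rf_channel_importance(rf_importances: np.ndarray) -> ChannelImportance:
    """Collapse 168 RF feature importances to per-channel importances.

    The feature layout is concentration-major, then channel, then
    feature; importances are averaged across the four signal features
    and the three concentration levels, then renormalized to unit sum.
    """
    imp = np.asarray(rf_importances, float)
    if imp.shape != (N_FEATURES,):
        raise ValueError(f"expected length {N_FEATURES}, got {imp.shape}")
    if (imp < 0).any():
        raise ValueError("importances must be nonnegative")
    grid = imp.reshape(len(CONCENTRATIONS), N_CHANNELS, len(FEATURE_NAMES))
    per_channel = grid.mean(axis=(0, 2))
    total = per_channel.sum()
    if total <= 0:
        per_channel = np.full(N_CHANNELS, 1.0 / N_CHANNELS)
    else:
        per_channel = per_channel / total
    return ChannelImportance(values=per_channel, source="rf")


def rank_consistency(a: ChannelImportance, b: ChannelImportance) -> float:
    """Spearman rank correlation between two channel-importance vectors."""
    rho = spearmanr(a.values, b.values).statistic
    return float(rho)


def recovery_and_consistency(
    scorecam_activity: Mapping[str, ChannelImportance],
    rf_importance: Mapping[str, ChannelImportance],
    manifest: Mapping,
) -> dict:
    """Planted-channel recovery and Score-CAM/RF consistency summary.

    Parameters
    ----------
    scorecam_activity
        Per-class Score-CAM channel activity, keyed by class label
        (category names, ``"has_oxygen"``, ``"has_ring"``, ...).
    rf_importance
        Per-task RF channel importance, keyed by task name.
    manifest
        The generator's ground-truth manifest; its
        ``affinity_model.planted_channels`` maps class labels to the
        channel planted as most discriminative.

    Returns a summary with, per planted label present in
    ``scorecam_activity``: the planted channel, its rank in the
    Score-CAM activity, and whether it lies in the top 2; plus the
    Spearman rank correlation between Score-CAM activity and RF channel
    importance for every task name present in both mappings.
    """
    planted = manifest["affinity_model"]["planted_channels"]
    recovery: dict[str, dict] = {}
    for label, channel in planted.items():
        if label not in scorecam_activity:
            continue
        ci = scorecam_activity[label]
        order = ci.top_channels(N_CHANNELS)
        rank = order.index(int(channel)) + 1
        recovery[label] = {
            "planted_channel": int(channel),
            "rank": rank,
            "top2": rank <= 2,
        }
    consistency: dict[str, float] = {}
    for task, rf_ci in rf_importance.items():
        if task in scorecam_activity:
            consistency[task] = rank_consistency(scorecam_activity[task], rf_ci)
    return {"recovery": recovery, "spearman": consistency}
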