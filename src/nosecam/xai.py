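"""Score-CAM: gradient-free class activation mapping for sensor tensors.

Score-CAM explains a CNN prediction without gradients: each activation
map of the final convolution layer is upsampled to the input grid and
min-max normalized, used as a point-wise mask on the input, and the
masked input is re-scored by the network.  The maps are then combined
in a linear combination weighted by a softmax over those masked-input
scores for the target class; the rectified, min-max-normalized result
is the importance map — a 40 (time) x 14 (channel) matrix in [0, 1]
indicating which signal regions drove the classification.

The 40 x 14 mask is broadcast identically over the three concentration
planes, so the explanation lives on the same 2-D time x channel grid on
which averaged importance maps are displayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import softmax

from .models import TrainedClassifier
from .preprocess import N_TIME_POINTS, InputTensor
from .sensor_sim import N_CHANNELS

__all__ = ["ImportanceMap", "upsample_map", "minmax_norm", "mask_input", "scorecam"]

INPUT_GRID = (N_TIME_POINTS, N_CHANNELS)  # (40, 14)


@dataclass
class ImportanceMap:
    """A 40 x 14 importance matrix in [0, 1] for one (sample, class)."""

    values: np.ndarray
    target_class: str
    sample_id: str = ""
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != INPUT_GRID:
            raise ValueError(f"importance map must be {INPUT_GRID}, got {self.values.shape}")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("importance map entries must lie in [0, 1]")


def upsample_map(m: np.ndarray, target: tuple[int, int] = INPUT_GRID) -> np.ndarray:
    """Bilinear upsampling of a conv-layer map onto the input grid.

    Corner-aligned: source corners map to target corners, so a constant
    map stays constant and a map already at the target size is returned
    unchanged.
    """
    m = np.asarray(m, float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("expected a non-empty 2-D map")
    hs, ws = m.shape
    ht, wt = target
    if hs > ht or ws > wt:
        raise ValueError(f"map {m.shape} larger than target {target}")
    if (hs, ws) == (ht, wt):
        return m.copy()
    rows = np.linspace(0, hs - 1, ht) if hs > 1 else np.zeros(ht)
    cols = np.linspace(0, ws - 1, wt) if ws > 1 else np.zeros(wt)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(m, [rr, cc], order=1, mode="nearest")


def minmax_norm(m: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant map maps to all zeros."""
    m = np.asarray(m, float)
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def mask_input(x: InputTensor | np.ndarray, h: np.ndarray) -> np.ndarray:
    """Point-wise mask: multiply each concentration plane of x by h."""
    vals = x.values if isinstance(x, InputTensor) else np.asarray(x, float)
    h = np.asarray(h, float)
    if h.shape != vals.shape[:2]:
        raise ValueError(f"mask shape {h.shape} does not match input grid {vals.shape[:2]}")
    return vals * h[:, :, None]


def scorecam(
    model: TrainedClassifier,
    x: InputTensor | np.ndarray,
    target_class: str,
    use_logits: bool = False,
    subtract_baseline: bool = False,
) -> ImportanceMap:
    """Compute the Score-CAM importance map for one input and class.

    Steps: (1) extract the K final-conv activation maps; (2) upsample
    each to 40 x 14 and min-max normalize -> masks ``H_k``; (3) score
    each masked input ``x * H_k`` with the network and take the
    target-class score (post-softmax probability by default, logits
    with ``use_logits``); (4) weight ``alpha = softmax(s_1..s_K)``;
    (5) ``L = max(0, sum_k alpha_k H_k)``; (6) min-max normalize.

    With ``subtract_baseline`` the unmasked input's target-class score
    is subtracted from each masked score before the softmax
    (increase-of-confidence variant).

    Exactly K + 1 forward passes are used: one for the activation maps
    and one per masked input.
    """
    vals = x.values if isinstance(x, InputTensor) else np.asarray(x, float)
    sample_id = x.sample_id if isinstance(x, InputTensor) else ""
    ci = model.class_index(target_class)  # raises KeyError for unknown labels

    maps = model.activation_maps(vals)  # (K, h_f, w_f); forward pass 1
    masks = np.stack([minmax_norm(upsample_map(m)) for m in maps])  # (K, 40, 14)

    masked = np.stack([mask_input(vals, h) for h in masks])  # (K, 40, 14, 3)
    if use_logits:
        scores = model.predict_logits(masked)[:, ci]  # K forward passes
    else:
        scores = model.predict_proba(masked)[:, ci]
    if subtract_baseline:  # one extra forward pass (K + 2 total)
        base = model.predict_logits(vals)[ci] if use_logits else model.predict_proba(vals)[ci]
        scores = scores - base

    alpha = softmax(scores)
    combined = np.tensordot(alpha, masks, axes=(0, 0))
    rectified = np.maximum(combined, 0.0)
    return ImportanceMap(
        values=minmax_norm(rectified),
        target_class=target_class,
        sample_id=sample_id,
        weights=alpha,
    )
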