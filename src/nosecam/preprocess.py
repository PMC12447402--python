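"""Raw traces -> CNN input tensors and hand-crafted baseline features.

The CNN input is built exactly as in the measurement pipeline: the
signal value at 0 s is set to zero, points are extracted every 3 s
(40 points per channel, t = 3..120 s), and each channel is normalized
so that the maximum over its three concentration planes equals 1.

The SVM/RF baselines instead use a 168-dimensional feature vector:
4 signal features x 14 channels x 3 concentrations.  The four features
capture the adsorption/desorption physics: end-of-adsorption level,
initial adsorption slope, initial desorption slope, and the residual
signal after the purge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sensor_sim import (
    CONCENTRATIONS,
    N_CHANNELS,
    N_RAW_POINTS,
    SAMPLING_HZ,
    OdorSample,
    SignalTrace,
)

__all__ = [
    "N_TIME_POINTS",
    "TIME_GRID_S",
    "FEATURE_NAMES",
    "InputTensor",
    "FeatureVector",
    "baseline_zero",
    "downsample",
    "assemble_normalize",
    "extract_baseline_features",
]

logger = logging.getLogger(__name__)

#: Downsampled time grid: every 3 s, excluding t=0 (identically zero
#: after baselining), giving exactly 40 points: t = 3, 6, ..., 120 s.
N_TIME_POINTS = 40
TIME_GRID_S = np.arange(1, N_TIME_POINTS + 1) * 3.0

#: Names of the four per-(channel, concentration) baseline features.
FEATURE_NAMES = (
    "adsorption_peak",      # S(30): end of the sampling phase
    "adsorption_slope",     # (S(6) - S(3)) / 3: initial uptake rate, 1/s
    "desorption_slope",     # (S(33) - S(30)) / 3: initial decay rate, 1/s
    "residual_signal",      # S(120): what remains after the purge
)
N_FEATURES = len(FEATURE_NAMES) * N_CHANNELS * len(CONCENTRATIONS)  # 168


@dataclass
class InputTensor:
    """The 40 (time) x 14 (channel) x 3 (concentration) CNN input."""

    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (N_TIME_POINTS, N_CHANNELS, len(CONCENTRATIONS)):
            raise ValueError(
                f"InputTensor must be {N_TIME_POINTS}x{N_CHANNELS}x{len(CONCENTRATIONS)}, "
                f"got {self.values.shape}"
            )


@dataclass
class FeatureVector:
    """168-dimensional hand-crafted feature vector.

    Layout is concentration-major, then channel, then feature:
    ``index = (conc_idx * 14 + channel_idx) * 4 + feature_idx`` with
    concentrations ordered (5, 10, 20) %, channels 1..14, and features
    as in :data:`FEATURE_NAMES`.  This layout is relied on by the
    random-forest channel-importance reshaping.
    """

    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"FeatureVector must have length {N_FEATURES}")


def baseline_zero(trace: SignalTrace) -> SignalTrace:
    """Subtract the t = 0 s value from the whole trace."""
    if trace.signal.size == 0:
        raise ValueError("empty trace")
    if trace.time_s[0] != 0.0:
        raise ValueError("trace must start at t = 0 s")
    return SignalTrace(
        time_s=trace.time_s,
        signal=trace.signal - trace.signal[0],
        channel=trace.channel,
        concentration=trace.concentration,
    )


def downsample(trace: SignalTrace) -> np.ndarray:
    """Extract the 40-point vector S(3), S(6), ..., S(120).

    Requires the full 20 Hz grid over [0, 120] s; every 3 s step is
    60 raw samples.
    """
    if trace.signal.shape[0] != N_RAW_POINTS:
        raise ValueError(
            f"expected {N_RAW_POINTS} points (20 Hz over 120 s), got {trace.signal.shape[0]}"
        )
    dt = np.diff(trace.time_s)
    if not np.allclose(dt, 1.0 / SAMPLING_HZ):
        raise ValueError("trace grid is not uniform 20 Hz")
    step = 3 * SAMPLING_HZ
    return trace.signal[step::step].copy()


def _downsampled_grid(sample: OdorSample) -> np.ndarray:
    """Baseline-zero and downsample every trace -> (40, 14, 3) array."""
    out = np.empty((N_TIME_POINTS, N_CHANNELS, len(CONCENTRATIONS)))
    for ch in range(1, N_CHANNELS + 1):
        for ci, conc in enumerate(CONCENTRATIONS):
            key = (ch, conc)
            if key not in sample.traces:
                raise ValueError(f"sample {sample.sample_id}: missing trace for channel={ch}, concentration={conc}%")
            out[:, ch - 1, ci] = downsample(baseline_zero(sample.traces[key]))
    return out


def assemble_normalize(sample: OdorSample) -> InputTensor:
    """Assemble the normalized 40 x 14 x 3 input tensor for one sample.

    For each channel, all three concentration planes are divided by the
    single maximum over that channel's 40 x 3 entries.  Channels whose
    maximum is not positive are passed through unscaled (and logged):
    dividing by a non-positive maximum would be meaningless.
    """
    grid = _downsampled_grid(sample)
    for ch in range(N_CHANNELS):
        m = grid[:, ch, :].max()
        if m > 0:
            grid[:, ch, :] /= m
        else:
            logger.info(
                "sample %s channel %d has non-positive maximum (%.3g); left unscaled",
                sample.sample_id, ch + 1, m,
            )
    return InputTensor(values=grid, sample_id=sample.sample_id)


def extract_baseline_features(sample: OdorSample) -> FeatureVector:
    """Compute the 168-dimensional adsorption/desorption feature vector.

    Per (channel, concentration): S(30), (S(6)-S(3))/3, (S(33)-S(30))/3
    and S(120), computed on the baseline-zeroed downsampled grid (raw
    scale, no per-channel normalization).
    """
    grid = _downsampled_grid(sample)
    # indices on the 3 s grid: t = 3*(k+1)
    i3, i6, i30, i33, i120 = 0, 1, 9, 10, 39
    feats = np.empty((len(CONCENTRATIONS), N_CHANNELS, len(FEATURE_NAMES)))
    for ci in range(len(CONCENTRATIONS)):
        for ch in range(N_CHANNELS):
            s = grid[:, ch, ci]
            feats[ci, ch, 0] = s[i30]
            feats[ci, ch, 1] = (s[i6] - s[i3]) / 3.0
            feats[ci, ch, 2] = (s[i33] - s[i30]) / 3.0
            feats[ci, ch, 3] = s[i120]
    return FeatureVector(values=feats.reshape(-1), sample_id=sample.sample_id)
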