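"""File-format contracts: long-format trace CSV, manifests, tensors, maps.

The interchange format for raw measurements is a long-format CSV with
one row per (sample, channel, concentration, time point):

    sample_id, solvent_id, category, n_oxygen, has_ring,
    channel, concentration_pct, time_s, signal

Writing then reading a dataset reproduces it exactly (floats are
serialized with full repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import TIME_GRID_S, FeatureVector, InputTensor
from .sensor_sim import (
    CONCENTRATIONS,
    N_CHANNELS,
    N_RAW_POINTS,
    MoleculeSpec,
    OdorSample,
    SignalTrace,
)
from .xai import ImportanceMap

__all__ = [
    "DataError",
    "TRACE_COLUMNS",
    "write_traces",
    "read_traces",
    "write_manifest",
    "read_manifest",
    "save_tensors",
    "load_tensors",
    "features_to_frame",
    "importance_map_frame",
    "nims_repository_adapter",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


TRACE_COLUMNS = (
    "sample_id", "solvent_id", "category", "n_oxygen", "has_ring",
    "channel", "concentration_pct", "time_s", "signal",
)


def write_traces(samples: Sequence[OdorSample], path: str | Path) -> None:
    """Write odor samples to the long-format trace CSV."""
    frames = []
    for s in samples:
        for (ch, conc), tr in sorted(s.traces.items()):
            frames.append(pd.DataFrame({
                "sample_id": s.sample_id,
                "solvent_id": s.molecule.solvent_id,
                "category": s.molecule.category,
                "n_oxygen": s.molecule.n_oxygen,
                "has_ring": s.molecule.has_ring,
                "channel": ch,
                "concentration_pct": conc,
                "time_s": tr.time_s,
                "signal": tr.signal,
            }))
    # 17 significant digits: float64 round-trips exactly
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_traces(path: str | Path) -> list[OdorSample]:
    """Read odor samples back from the long-format trace CSV.

    Raises :class:`DataError` (with row numbers where applicable) for
    missing columns, out-of-range channels or concentrations, duplicate
    keys, or non-uniform time grids.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty input file") from None
    if df.empty:
        raise DataError(f"{path}: no data rows")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")

    bad_ch = df.loc[~df["channel"].isin(range(1, N_CHANNELS + 1))]
    if not bad_ch.empty:
        row = bad_ch.index[0] + 2  # header + 1-based
        raise DataError(
            f"{path}: invalid channel value {bad_ch['channel'].iloc[0]} (first at row {row})"
        )
    bad_conc = df.loc[~df["concentration_pct"].isin(CONCENTRATIONS)]
    if not bad_conc.empty:
        row = bad_conc.index[0] + 2
        raise DataError(
            f"{path}: invalid concentration {bad_conc['concentration_pct'].iloc[0]} "
            f"(first at row {row})"
        )
    dup = df.duplicated(subset=["sample_id", "channel", "concentration_pct", "time_s"])
    if dup.any():
        rows = (df.index[dup][:5] + 2).tolist()
        raise DataError(f"{path}: duplicate (sample, channel, concentration, time) keys at rows {rows}")

    samples: list[OdorSample] = []
    for sid, g in df.groupby("sample_id", sort=True):
        meta = g.iloc[0]
        mol = MoleculeSpec(
            solvent_id=str(meta["solvent_id"]),
            category=str(meta["category"]),
            n_oxygen=int(meta["n_oxygen"]),
            has_oxygen=int(meta["n_oxygen"]) > 0,
            has_ring=bool(meta["has_ring"]),
        )
        traces = {}
        for (ch, conc), tg in g.groupby(["channel", "concentration_pct"], sort=True):
            tg = tg.sort_values("time_s")
            t = tg["time_s"].to_numpy(float)
            if len(t) != N_RAW_POINTS or not np.allclose(np.diff(t), t[1] - t[0]):
                raise DataError(
                    f"{path}: sample {sid} channel {ch} conc {conc}%: "
                    f"non-uniform or incomplete time grid ({len(t)} points)"
                )
            traces[(int(ch), int(conc))] = SignalTrace(
                time_s=t, signal=tg["signal"].to_numpy(float),
                channel=int(ch), concentration=int(conc),
            )
        try:
            samples.append(OdorSample(sample_id=str(sid), molecule=mol, traces=traces))
        except ValueError as e:
            raise DataError(f"{path}: sample {sid}: {e}") from None
    return samples


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_tensors(tensors: Sequence[InputTensor], path: str | Path) -> None:
    """Save input tensors to HDF5 with a JSON layout sidecar."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("tensors", data=np.stack([t.values for t in tensors]))
        f.create_dataset(
            "sample_ids",
            data=np.array([t.sample_id for t in tensors], dtype=h5py.string_dtype()),
        )
    sidecar = {
        "layout": "tensors[n, time, channel, concentration]",
        "time_grid_s": TIME_GRID_S.tolist(),
        "channels": list(range(1, N_CHANNELS + 1)),
        "concentrations_pct": list(CONCENTRATIONS),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_tensors(path: str | Path) -> list[InputTensor]:
    import h5py

    with h5py.File(path, "r") as f:
        vals = f["tensors"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][...]]
    return [InputTensor(values=v, sample_id=i) for v, i in zip(vals, ids)]


def features_to_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame, one row per sample, f000..f167."""
    cols = [f"f{i:03d}" for i in range(features[0].values.size)]
    df = pd.DataFrame([f.values for f in features], columns=cols)
    df.insert(0, "sample_id", [f.sample_id for f in features])
    return df


def importance_map_frame(m: ImportanceMap) -> pd.DataFrame:
    """A 40 x 14 importance map as a DataFrame (rows t = 3..120 s)."""
    df = pd.DataFrame(
        m.values,
        index=pd.Index(TIME_GRID_S, name="time_s"),
        columns=[f"ch{c:02d}" for c in range(1, N_CHANNELS + 1)],
    )
    return df


def nims_repository_adapter(local_dir: str | Path) -> None:
    """Adapter contract for the deposited real measurement data.

    The measured 94-solvent MSS dataset is deposited as "NIMS Materials
    Data Repository, 10.48505/nims.5556".  This package does not
    download it.  To analyze it, export each measurement to the
    long-format CSV of :func:`write_traces`:

    * one row per (sample, channel, concentration, time point);
    * ``channel`` 1..14 per the receptor-material table, ``concentration_pct``
      in {5, 10, 20}, ``time_s`` the 20 Hz grid over [0, 120] s;
    * molecule metadata columns (``category``, ``n_oxygen``, ``has_ring``)
      from the solvent annotation table.

    The resulting file is accepted by :func:`read_traces` and flows
    through the identical pipeline as synthetic data.
    """
    raise NotImplementedError(
        "automatic retrieval of the deposited dataset is out of scope; "
        "see this function's docstring for the required CSV layout"
    )
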