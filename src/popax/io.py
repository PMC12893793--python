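"""File formats.

* Traces: one HDF5 file per session-condition with datasets ``/F``
  (cells x frames raw fluorescence), ``/frame_rate`` (scalar Hz),
  ``/cell_ids``, and optional ``/roi_centroids``, ``/roi_masks``.
* Event tables: CSV with the canonical column order
  (:data:`popax.containers.EVENT_COLUMNS`); empty fields mean the attribute
  does not apply; ``onset_frame`` is 0-based.
* Response matrices: long-format CSV (one row per cell-trial response).
* Results: JSON with the config hash and seed embedded.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .config import Config
from .containers import EVENT_COLUMNS, ResponseMatrix, TraceSet


def save_traces(path, traces: TraceSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=traces.fluorescence)
        f.create_dataset("frame_rate", data=float(traces.frame_rate))
        ids = traces.cell_ids
        if ids.dtype.kind in ("U", "O"):
            ids = ids.astype("S")
        f.create_dataset("cell_ids", data=ids)
        if traces.roi_centroids is not None:
            f.create_dataset("roi_centroids", data=traces.roi_centroids)
        if traces.roi_masks is not None:
            f.create_dataset("roi_masks", data=traces.roi_masks.astype(np.uint8))


def load_traces(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        ids = f["cell_ids"][()]
        if ids.dtype.kind == "S":
            ids = ids.astype(str)
        return TraceSet(
            fluorescence=f["F"][()],
            frame_rate=float(f["frame_rate"][()]),
            cell_ids=ids,
            roi_centroids=f["roi_centroids"][()] if "roi_centroids" in f else None,
            roi_masks=f["roi_masks"][()].astype(bool) if "roi_masks" in f else None,
        )


def save_events(path, events: pd.DataFrame) -> None:
    cols = [c for c in EVENT_COLUMNS if c in events.columns]
    cols += [c for c in events.columns if c not in cols]
    events[cols].to_csv(path, index=False)


def load_events(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"luminance": "string", "movie_id": "string"},
    )
    for col in ("luminance", "movie_id"):
        if col in df:
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    return df


def save_responses(path, responses: ResponseMatrix) -> None:
    responses.to_frame().to_csv(path, index=False)


def load_responses(path) -> ResponseMatrix:
    df = pd.read_csv(path, dtype={"luminance": "string", "movie_id": "string"})
    for col in ("luminance", "movie_id"):
        if col in df:
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    return ResponseMatrix.from_frame(df)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def save_result(path, result: Any, config: Config | None = None, seed: int | None = None) -> None:
    """Write any result object to JSON, embedding config hash and seed."""
    config = config or Config()
    payload = {
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "seed": seed,
        "result": _jsonable(result),
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))
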