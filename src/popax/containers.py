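"""Core data containers.

The package moves data between three representations:

* :class:`TraceSet` — raw fluorescence, cells x frames, with a frame rate.
* an event table — a pandas ``DataFrame`` with one row per stimulus
  presentation (see :data:`EVENT_COLUMNS`), 0-based onset frames.
* :class:`ResponseMatrix` — condition-keyed cells x trials scalar responses
  in ΔF/F units, the input of all decoding and geometry analyses.

Conditions are immutable :class:`Condition` records over the stimulus grid
(orientation, contrast, luminance, SF, TF, movie id / time bin); fields that
do not apply are ``None``.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field, fields, replace
from typing import Any

import numpy as np
import pandas as pd

from .errors import BoundsError, ShapeError

#: Columns of an event table, in canonical CSV order. ``onset_frame`` is a
#: 0-based index into the trace; inapplicable stimulus attributes are NaN/empty.
EVENT_COLUMNS = [
    "onset_frame",
    "duration_s",
    "orientation_deg",
    "contrast_pct",
    "luminance",
    "sf_cpd",
    "tf_hz",
    "movie_id",
    "movie_bin",
    "trial_index",
]

#: Condition attributes, i.e. the stimulus-grid coordinates of a trial.
CONDITION_FIELDS = (
    "orientation_deg",
    "contrast_pct",
    "luminance",
    "sf_cpd",
    "tf_hz",
    "movie_id",
    "movie_bin",
)


@dataclass(frozen=True)
class Condition:
    """One cell of the stimulus-condition grid. Hashable; unset fields are None."""

    orientation_deg: float | None = None
    contrast_pct: float | None = None
    luminance: str | None = None
    sf_cpd: float | None = None
    tf_hz: float | None = None
    movie_id: str | None = None
    movie_bin: int | None = None

    def replace(self, **kwargs: Any) -> "Condition":
        return replace(self, **kwargs)

    def matches(self, **attrs: Any) -> bool:
        """True if every given attribute equals this condition's value."""
        return all(getattr(self, k) == v for k, v in attrs.items())

    def as_dict(self, drop_none: bool = True) -> dict[str, Any]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if drop_none:
            d = {k: v for k, v in d.items() if v is not None}
        return d

    def sort_key(self) -> tuple:
        # None sorts first within each field; fields compared positionally.
        return tuple(
            (0, "") if getattr(self, f.name) is None else (1, getattr(self, f.name))
            for f in fields(self)
        )


def condition_of_event(row: Mapping[str, Any], include_movie_bin: bool = False) -> Condition:
    """Build the :class:`Condition` an event-table row belongs to.

    ``movie_bin`` is excluded by default because for movie stimuli the bin is
    assigned during response binning, not in the event table.
    """

    def _get(key: str) -> Any:
        v = row.get(key) if isinstance(row, dict) else row[key] if key in row else None
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    kw: dict[str, Any] = {k: _get(k) for k in CONDITION_FIELDS if k != "movie_bin"}
    if include_movie_bin:
        mb = _get("movie_bin")
        kw["movie_bin"] = None if mb is None else int(mb)
    return Condition(**kw)


@dataclass
class TraceSet:
    """Raw fluorescence traces for one imaging session-condition.

    Attributes
    ----------
    fluorescence : ndarray, shape (n_cells, n_frames)
        Raw fluorescence F, arbitrary units.
    frame_rate : float
        Acquisition rate in Hz.
    cell_ids : ndarray of shape (n_cells,)
        Unique opaque identifiers (default ``arange(n_cells)``).
    roi_centroids : ndarray (n_cells, 2), optional
        (x, y) pixel centroids used for cross-session ROI matching.
    roi_masks : ndarray (n_cells, H, W) of bool, optional
        Pixel masks on a shared canvas.
    """

    fluorescence: np.ndarray
    frame_rate: float
    cell_ids: np.ndarray | None = None
    roi_centroids: np.ndarray | None = None
    roi_masks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise ShapeError("fluorescence must be 2-D (cells x frames)")
        if not np.isfinite(self.fluorescence).all():
            raise ValueError("fluorescence contains NaN/inf frames")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.n_cells)
        self.cell_ids = np.asarray(self.cell_ids)
        if len(self.cell_ids) != self.n_cells:
            raise ShapeError("cell_ids length must equal number of cells")
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]


@dataclass
class DffSegments:
    """Per-trial ΔF/F segments, aligned on stimulus onset.

    ``dff[e, c, t]`` is the fractional fluorescence change of cell ``c`` on
    event ``e`` at segment frame ``t``; the onset frame sits at index
    ``onset_index`` so frames ``[0, onset_index)`` are the pre-stimulus
    baseline. ``invalid[e, c]`` flags cell-trials whose baseline mean was
    non-positive (ΔF/F undefined); their segment values are NaN.
    """

    dff: np.ndarray  # (n_events, n_cells, n_segment_frames)
    onset_index: int
    frame_rate: float
    events: pd.DataFrame
    invalid: np.ndarray  # (n_events, n_cells) bool

    @property
    def n_events(self) -> int:
        return self.dff.shape[0]

    @property
    def n_cells(self) -> int:
        return self.dff.shape[1]

    @property
    def n_post_frames(self) -> int:
        return self.dff.shape[2] - self.onset_index


class ResponseMatrix(Mapping):
    """Condition-keyed cells x trials response matrices with a shared cell axis.

    Behaves as an immutable mapping ``Condition -> ndarray (n_cells, n_trials)``.
    All conditions share an identical cell ordering (``cell_ids``).
    """

    def __init__(
        self,
        data: Mapping[Condition, np.ndarray],
        cell_ids: np.ndarray | None = None,
    ) -> None:
        if not data:
            raise ValueError("ResponseMatrix requires at least one condition")
        conv: dict[Condition, np.ndarray] = {}
        n_cells = None
        for cond, arr in data.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if n_cells is None:
                n_cells = arr.shape[0]
            elif arr.shape[0] != n_cells:
                raise ShapeError(
                    f"condition {cond} has {arr.shape[0]} cells, expected {n_cells}"
                )
            conv[cond] = arr
        # deterministic condition ordering
        self._data = {c: conv[c] for c in sorted(conv, key=Condition.sort_key)}
        self._n_cells = int(n_cells)  # type: ignore[arg-type]
        if cell_ids is None:
            cell_ids = np.arange(self._n_cells)
        self.cell_ids = np.asarray(cell_ids)
        if len(self.cell_ids) != self._n_cells:
            raise ShapeError("cell_ids length must equal the cell axis")

    # Mapping interface ----------------------------------------------------
    def __getitem__(self, cond: Condition) -> np.ndarray:
        return self._data[cond]

    def __iter__(self) -> Iterator[Condition]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    # Convenience ----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self._n_cells

    @property
    def conditions(self) -> list[Condition]:
        return list(self._data)

    def trial_counts(self) -> dict[Condition, int]:
        return {c: a.shape[1] for c, a in self._data.items()}

    def select(self, **attrs: Any) -> "ResponseMatrix":
        """Sub-matrix of conditions matching all given attributes."""
        sub = {c: a for c, a in self._data.items() if c.matches(**attrs)}
        if not sub:
            raise KeyError(f"no condition matches {attrs}")
        return ResponseMatrix(sub, cell_ids=self.cell_ids)

    def single(self, **attrs: Any) -> np.ndarray:
        """The unique cells x trials array matching the given attributes."""
        sub = [a for c, a in self._data.items() if c.matches(**attrs)]
        if len(sub) != 1:
            raise KeyError(f"{len(sub)} conditions match {attrs}, expected exactly 1")
        return sub[0]

    def subset_cells(self, index: np.ndarray) -> "ResponseMatrix":
        index = np.asarray(index)
        return ResponseMatrix(
            {c: a[index] for c, a in self._data.items()}, cell_ids=self.cell_ids[index]
        )

    def map_trials(self, fn) -> "ResponseMatrix":
        """Apply ``fn(condition, array) -> array`` to every condition."""
        return ResponseMatrix(
            {c: fn(c, a) for c, a in self._data.items()}, cell_ids=self.cell_ids
        )

    def levels(self, attr: str) -> list:
        """Distinct non-None values of a condition attribute, sorted."""
        vals = {getattr(c, attr) for c in self._data if getattr(c, attr) is not None}
        return sorted(vals)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (one row per cell-trial response)."""
        rows = []
        for cond, arr in self._data.items():
            n_cells, n_trials = arr.shape
            df = pd.DataFrame(
                {
                    "cell_id": np.repeat(self.cell_ids, n_trials),
                    "trial": np.tile(np.arange(n_trials), n_cells),
                    "response": arr.ravel(),
                }
            )
            for k, v in cond.as_dict(drop_none=False).items():
                df[k] = v
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseMatrix":
        """Inverse of :meth:`to_frame`."""
        cell_ids = np.unique(df["cell_id"].to_numpy())
        order = {cid: i for i, cid in enumerate(cell_ids)}
        data: dict[Condition, np.ndarray] = {}
        for key, grp in df.groupby(list(CONDITION_FIELDS), dropna=False, sort=True):
            kw = {}
            for name, val in zip(CONDITION_FIELDS, key):
                if pd.isna(val):
                    kw[name] = None
                elif name == "movie_bin":
                    kw[name] = int(val)
                else:
                    kw[name] = val
            cond = Condition(**kw)
            trials = np.sort(grp["trial"].unique())
            arr = np.full((len(cell_ids), len(trials)), np.nan)
            tpos = {t: j for j, t in enumerate(trials)}
            for cid, t, r in zip(grp["cell_id"], grp["trial"], grp["response"]):
                arr[order[cid], tpos[t]] = r
            data[cond] = arr
        return cls(data, cell_ids=cell_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ResponseMatrix({len(self)} conditions, {self.n_cells} cells, "
            f"trials={sorted(set(self.trial_counts().values()))})"
        )


def validate_events(events: pd.DataFrame, n_frames: int | None = None) -> pd.DataFrame:
    """Check an event table's schema and invariants; returns the table.

    Requires ``onset_frame`` and ``trial_index`` columns; onsets must be
    non-negative (and inside the trace when ``n_frames`` is given); within
    each condition, trial_index must be 1..n with no gaps.
    """
    missing = {"onset_frame", "trial_index"} - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    onset = events["onset_frame"].to_numpy()
    if (onset < 0).any():
        raise BoundsError("negative onset frame")
    if n_frames is not None and (onset >= n_frames).any():
        raise BoundsError("onset frame beyond trace length")
    for cond, grp in events.groupby(
        [c for c in CONDITION_FIELDS if c in events.columns and c != "movie_bin"],
        dropna=False,
    ):
        ti = np.sort(grp["trial_index"].to_numpy())
        if not np.array_equal(ti, np.arange(1, len(ti) + 1)):
            raise ValueError(f"trial_index not contiguous 1..n for condition {cond}")
    return events
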