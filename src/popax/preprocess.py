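"""Trace preprocessing: ΔF/F extraction, response windowing, QC, ROI matching.

The pipeline mirrors standard two-photon calcium-imaging practice:

1. :func:`compute_dff` — baseline-normalize each trial with the mean raw
   fluorescence in the 200 ms preceding stimulus onset,
   ΔF/F = (F(t) − p) / p.
2. :func:`extract_responses` — one scalar per cell per trial: the mean ΔF/F
   over frames whose centers fall 450–1,300 ms after onset (the peak of the
   GCaMP6s response to brief stimuli), grouped by stimulus condition.
3. :func:`bin_movie_responses` — for natural movies, the mean ΔF/F per
   166 ms time bin per repeat; each (movie, bin, luminance) is a condition.
4. :func:`qc_filter` — retain cells whose raw trace has sample skewness > 2
   and whose trial-averaged evoked response exceeds baseline by a one-sided
   two-sample t test at p < 0.001, optionally requiring a match in a second
   session.
5. :func:`match_rois` — greedy centroid-distance / IoU matching of ROIs
   across two sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    Condition,
    DffSegments,
    ResponseMatrix,
    TraceSet,
    condition_of_event,
    validate_events,
)
from .errors import (
    BoundsError,
    ConfigurationError,
    InsufficientDataError,
    ParameterError,
)


def compute_dff(
    traces: TraceSet,
    events: pd.DataFrame,
    baseline_ms: float = 200.0,
    post_ms: float | None = None,
) -> DffSegments:
    """Baseline-normalize each trial: ΔF/F = (F(t) − p) / p.

    ``p`` is the mean raw fluorescence over the ``baseline_ms`` preceding
    each event's onset, computed per cell per trial. Segments span the
    baseline window plus ``post_ms`` after onset (default: enough to cover
    the 450–1,300 ms response window, or the longest event, whichever is
    larger). Cell-trials with ``p <= 0`` are flagged invalid (ΔF/F set to
    NaN), never silently zeroed.
    """
    validate_events(events, n_frames=traces.n_frames)
    fs = traces.frame_rate
    n_base = int(round(fs * baseline_ms / 1000.0))
    if n_base < 1:
        raise ConfigurationError(
            f"baseline of {baseline_ms} ms holds no full frame at {fs} Hz"
        )
    if post_ms is None:
        dur = events["duration_s"].fillna(0.0).max() if "duration_s" in events else 0.0
        post_ms = max(1500.0, float(dur) * 1000.0)
    n_post = int(np.ceil(fs * post_ms / 1000.0))

    onsets = events["onset_frame"].to_numpy().astype(int)
    if (onsets - n_base < 0).any():
        raise BoundsError("an event lacks a full pre-onset baseline window")
    if (onsets + n_post > traces.n_frames).any():
        raise BoundsError("an event's post-onset segment extends beyond the trace")

    F = traces.fluorescence
    n_events = len(events)
    dff = np.empty((n_events, traces.n_cells, n_base + n_post))
    invalid = np.zeros((n_events, traces.n_cells), dtype=bool)
    for e, onset in enumerate(onsets):
        seg = F[:, onset - n_base : onset + n_post]
        p = seg[:, :n_base].mean(axis=1)
        bad = p <= 0
        invalid[e] = bad
        safe_p = np.where(bad, 1.0, p)
        dff[e] = (seg - safe_p[:, None]) / safe_p[:, None]
        dff[e, bad, :] = np.nan
    n_bad = int(invalid.sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} cell-trials flagged invalid (non-positive baseline)",
            stacklevel=2,
        )
    return DffSegments(
        dff=dff,
        onset_index=n_base,
        frame_rate=fs,
        events=events.reset_index(drop=True),
        invalid=invalid,
    )


def window_frame_offsets(
    frame_rate: float,
    window_ms: tuple[float, float],
    n_post_frames: int,
) -> np.ndarray:
    """Post-onset frame offsets whose centers fall in [start, end) ms.

    Frame offset d (0 = onset frame) covers time [d, d+1)/rate, so its
    center is (d + 0.5)/rate; the half-open window makes the mapping
    unambiguous at any frame rate.
    """
    lo, hi = window_ms
    if not (0 <= lo < hi):
        raise ParameterError(f"invalid window {window_ms}: need 0 <= start < end")
    d = np.arange(n_post_frames)
    centers_ms = (d + 0.5) / frame_rate * 1000.0
    keep = d[(centers_ms >= lo) & (centers_ms < hi)]
    if keep.size == 0:
        raise ConfigurationError(
            f"no frame centers in window {window_ms} ms at {frame_rate} Hz"
        )
    return keep


def extract_responses(
    segments: DffSegments,
    window_ms: tuple[float, float] = (450.0, 1300.0),
) -> ResponseMatrix:
    """Scalar single-trial responses: mean ΔF/F over the response window.

    Events are grouped into conditions by their stimulus attributes; within
    each condition, trials are ordered by ``trial_index``. Invalid
    cell-trials propagate as NaN.
    """
    offs = window_frame_offsets(segments.frame_rate, window_ms, segments.n_post_frames)
    post = segments.dff[:, :, segments.onset_index :]
    resp = post[:, :, offs].mean(axis=2)  # (n_events, n_cells)

    events = segments.events
    data: dict[Condition, np.ndarray] = {}
    for cond, grp in _group_events(events):
        order = grp.sort_values("trial_index").index.to_numpy()
        data[cond] = resp[order].T  # cells x trials
    return ResponseMatrix(data)


def _group_events(events: pd.DataFrame):
    keys: dict[Condition, list[int]] = {}
    for i, (_, row) in enumerate(events.iterrows()):
        cond = condition_of_event(row)
        keys.setdefault(cond, []).append(i)
    for cond, idx in keys.items():
        yield cond, events.iloc[idx]


def bin_movie_responses(
    segments: DffSegments,
    bin_ms: float = 166.0,
) -> ResponseMatrix:
    """Movie responses: mean ΔF/F per time bin per repeat.

    Each (movie_id, movie_bin, luminance) triple becomes a condition whose
    trials are the movie repeats. Bins tile the movie from onset; only
    complete bins are kept (a trailing partial bin is dropped), so a 10 s
    movie at 166.67 ms bins yields 60 bins.
    """
    events = segments.events
    if "movie_id" not in events or events["movie_id"].isna().all():
        raise ParameterError("no movie events present")
    movie_events = events[events["movie_id"].notna()]
    durations = movie_events["duration_s"].to_numpy(dtype=float)
    if (durations * 1000.0 < bin_ms).any():
        raise ParameterError("bin_ms longer than a movie presentation")

    fs = segments.frame_rate
    post = segments.dff[:, :, segments.onset_index :]
    centers_ms = (np.arange(segments.n_post_frames) + 0.5) / fs * 1000.0

    data: dict[Condition, np.ndarray] = {}
    for (movie_id, lum), grp in movie_events.groupby(["movie_id", "luminance"], dropna=False):
        if len(grp) < 2:
            raise InsufficientDataError(
                f"movie {movie_id!r} at {lum!r} has {len(grp)} repeat(s); >= 2 required"
            )
        dur_ms = float(grp["duration_s"].min()) * 1000.0
        n_bins = int(np.floor(dur_ms / bin_ms))
        order = grp.sort_values("trial_index").index.to_numpy()
        for b in range(n_bins):
            lo, hi = b * bin_ms, (b + 1) * bin_ms
            offs = np.flatnonzero((centers_ms >= lo) & (centers_ms < hi))
            if offs.size == 0:
                continue  # frame rate too low to sample this bin
            cond = Condition(movie_id=movie_id, movie_bin=b, luminance=lum)
            data[cond] = post[order][:, :, offs].mean(axis=2).T
    if not data:
        raise ConfigurationError("no movie bins contained any frame centers")
    return ResponseMatrix(data)


@dataclass
class QCReport:
    """Per-cell quality-control outcome.

    ``table`` has one row per cell: cell_id, skewness, p_value, passed,
    reason (empty when passed). ``retained`` indexes passing cells into the
    TraceSet's cell axis.
    """

    table: pd.DataFrame
    retained: np.ndarray
    n_retained: int
    n_removed: int
    skew_threshold: float
    p_threshold: float


def qc_filter(
    traces: TraceSet,
    segments: DffSegments,
    *,
    skew_threshold: float = 2.0,
    p_threshold: float = 0.001,
    window_ms: tuple[float, float] = (450.0, 1300.0),
    matched_ids: np.ndarray | None = None,
) -> QCReport:
    """Retain responsive, healthy, session-matched cells.

    A cell passes iff (a) its raw fluorescence trace has adjusted
    Fisher–Pearson sample skewness above ``skew_threshold``; (b) its
    per-trial response-window ΔF/F means exceed its per-trial baseline-window
    means by a one-sided, equal-variance two-sample t test at
    ``p < p_threshold``; and (c) its cell_id appears in ``matched_ids`` when
    a second session is supplied. The criteria are conjunctive, so their
    application order is immaterial.
    """
    if segments.n_events < 2:
        raise InsufficientDataError("need >= 2 trials for the evoked-response test")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(traces.fluorescence, axis=1, bias=False)

    offs = window_frame_offsets(segments.frame_rate, window_ms, segments.n_post_frames)
    post = segments.dff[:, :, segments.onset_index :]
    evoked = post[:, :, offs].mean(axis=2)  # (events, cells)
    base = segments.dff[:, :, : segments.onset_index].mean(axis=2)

    pvals = np.ones(traces.n_cells)
    for c in range(traces.n_cells):
        ev, ba = evoked[:, c], base[:, c]
        ok = ~(np.isnan(ev) | np.isnan(ba))
        if ok.sum() < 2:
            pvals[c] = 1.0
            continue
        res = stats.ttest_ind(ev[ok], ba[ok], equal_var=True, alternative="greater")
        pvals[c] = res.pvalue if np.isfinite(res.pvalue) else 1.0

    reasons = []
    passed = np.zeros(traces.n_cells, dtype=bool)
    matched = (
        np.isin(traces.cell_ids, matched_ids)
        if matched_ids is not None
        else np.ones(traces.n_cells, dtype=bool)
    )
    for c in range(traces.n_cells):
        why = []
        if not np.isfinite(skew[c]):
            why.append("degenerate trace")
        elif skew[c] <= skew_threshold:
            why.append("low skewness")
        if pvals[c] >= p_threshold:
            why.append("not evoked")
        if not matched[c]:
            why.append("unmatched")
        reasons.append("; ".join(why))
        passed[c] = not why

    table = pd.DataFrame(
        {
            "cell_id": traces.cell_ids,
            "skewness": skew,
            "p_value": pvals,
            "passed": passed,
            "reason": reasons,
        }
    )
    retained = np.flatnonzero(passed)
    return QCReport(
        table=table,
        retained=retained,
        n_retained=int(passed.sum()),
        n_removed=int((~passed).sum()),
        skew_threshold=skew_threshold,
        p_threshold=p_threshold,
    )


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_rois(
    centroids_a: np.ndarray,
    masks_a: np.ndarray,
    centroids_b: np.ndarray,
    masks_b: np.ndarray,
    max_dist_px: float = 10.0,
    min_iou: float = 0.3,
) -> pd.DataFrame:
    """Greedy one-to-one ROI pairing across two sessions.

    Candidate pairs within ``max_dist_px`` centroid distance are accepted in
    ascending-distance order (ties broken by higher IoU, then lower indices)
    provided their mask IoU is at least ``min_iou``. Returns a DataFrame with
    columns index_a, index_b, distance, iou; unmatched ROIs are simply absent.
    """
    centroids_a = np.atleast_2d(np.asarray(centroids_a, dtype=float))
    centroids_b = np.atleast_2d(np.asarray(centroids_b, dtype=float))
    diff = centroids_a[:, None, :] - centroids_b[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))

    cand = []
    for i in range(dist.shape[0]):
        for j in range(dist.shape[1]):
            if dist[i, j] <= max_dist_px:
                iou = _mask_iou(masks_a[i], masks_b[j])
                if iou >= min_iou:
                    cand.append((dist[i, j], -iou, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for d, neg_iou, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append({"index_a": i, "index_b": j, "distance": d, "iou": -neg_iou})
    return pd.DataFrame(rows, columns=["index_a", "index_b", "distance", "iou"])
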