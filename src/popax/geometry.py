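"""Coding-axis geometry: how two stimulus variables are jointly encoded.

For a pair of stimulus variables (say orientation and luminance) measured on
a shared population, the joint code is characterized by:

* the per-cell sensitivities dμ_a and dμ_b (change in trial-averaged
  response between the two levels of each variable) and their Pearson
  correlation across cells;
* the cosine between the population decoding axes dU_a and dU_b (0 under
  the random encoding model, ±1 under the shared model);
* the overlap between the "most informative" cell sets (top 10% |dμ|) for
  the two variables — 10% expected under independence;
* per-cell response log-ratios between two conditions (the direction and
  size of rate modulation, e.g. photopic vs scotopic).

:func:`joint_axes_report` sweeps a full stimulus-condition grid, computing
these statistics for every valid level pair of each requested variable pair
while holding all other attributes fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Condition, ResponseMatrix
from .ddr import compute_dU, cv_dprime, scaled_split
from .errors import DegenerateBasisError, ParameterError, ShapeError

__all__ = [
    "AlignmentResult",
    "dmu_per_cell",
    "dmu_correlation",
    "axis_alignment",
    "informative_overlap",
    "response_log_ratio",
    "joint_axes_report",
]


@dataclass
class AlignmentResult:
    """Joint-coding statistics for one variable pair at one grid setting."""

    var_a: str
    var_b: str
    pair_a: tuple
    pair_b: tuple
    fixed: dict
    dmu_a: np.ndarray
    dmu_b: np.ndarray
    pearson_r: float
    axis_dot: float
    overlap_pct: float
    informative_a: np.ndarray
    informative_b: np.ndarray
    n_cells: int
    dprime_a: float | None = None


def dmu_per_cell(resp_a: np.ndarray, resp_b: np.ndarray) -> np.ndarray:
    """Per-cell change in trial-averaged response (dU's entries).

    Identical contract to :func:`popax.ddr.compute_dU`: second argument
    minus first, matched cell axes.
    """
    return compute_dU(resp_a, resp_b)


def dmu_correlation(dmu_a: np.ndarray, dmu_b: np.ndarray) -> float:
    """Pearson correlation of two per-cell sensitivity vectors across cells.

    Returns NaN (flagged missing) if either vector has zero variance.
    """
    a = np.asarray(dmu_a, dtype=float)
    b = np.asarray(dmu_b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError("dmu vectors must have equal length")
    if a.size < 3:
        raise ParameterError("need at least 3 cells for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def axis_alignment(dU_a: np.ndarray, dU_b: np.ndarray) -> float:
    """Cosine between two population decoding axes (unit-normalized dot)."""
    a = np.asarray(dU_a, dtype=float)
    b = np.asarray(dU_b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError("dU vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateBasisError("cannot align a zero decoding axis")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def informative_sets(dmu: np.ndarray, frac: float) -> np.ndarray:
    """Indices of the round(frac * n) cells with the largest |dμ|.

    Threshold ties are broken by ascending cell index (deterministic).
    """
    n = len(dmu)
    k = int(round(frac * n))
    order = np.lexsort((np.arange(n), -np.abs(dmu)))
    return np.sort(order[:k])


def informative_overlap(
    dmu_a: np.ndarray,
    dmu_b: np.ndarray,
    frac: float = 0.10,
    method: str = "intersection_over_set",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Overlap (percent) between the most informative cell sets.

    The sets A and B each contain the round(frac*n) cells with the largest
    |dμ| for their variable. ``method="intersection_over_set"`` (default)
    returns 100·|A∩B|/|A|; ``"jaccard"`` returns 100·|A∩B|/|A∪B|.
    """
    a = np.asarray(dmu_a, dtype=float)
    b = np.asarray(dmu_b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError("dmu vectors must have equal length")
    if not 0 < frac <= 0.5:
        raise ParameterError("frac must lie in (0, 0.5]")
    if a.size < 10:
        raise ParameterError("need at least 10 cells for the overlap statistic")
    A = informative_sets(a, frac)
    B = informative_sets(b, frac)
    inter = np.intersect1d(A, B).size
    if method == "intersection_over_set":
        pct = 100.0 * inter / len(A)
    elif method == "jaccard":
        pct = 100.0 * inter / np.union1d(A, B).size
    else:
        raise ParameterError(f"unknown overlap method {method!r}")
    return float(pct), A, B


@dataclass
class LogRatioResult:
    log_ratios: np.ndarray
    mean: float
    sd: float
    n_excluded: int
    retained_index: np.ndarray
    base: str = "e"


def response_log_ratio(
    resp_a: np.ndarray,
    resp_b: np.ndarray,
    min_mean: float = 1e-3,
    base: str = "e",
) -> LogRatioResult:
    """Per-cell log of the trial-mean response ratio, condition B over A.

    Cells whose trial mean falls at or below ``min_mean`` in either
    condition are excluded (their count is reported); natural log by
    default, ``base="10"`` and ``base="2"`` available.
    """
    if not min_mean > 0:
        raise ParameterError("min_mean must be positive")
    ma = _trial_means(resp_a)
    mb = _trial_means(resp_b)
    if ma.shape != mb.shape:
        raise ShapeError("cell axes differ")
    keep = (ma > min_mean) & (mb > min_mean)
    if not keep.any():
        raise ParameterError("all cells excluded by the min_mean threshold")
    logfn = {"e": np.log, "10": np.log10, "2": np.log2}.get(base)
    if logfn is None:
        raise ParameterError(f"unknown log base {base!r}")
    lr = logfn(mb[keep] / ma[keep])
    return LogRatioResult(
        log_ratios=lr,
        mean=float(lr.mean()),
        sd=float(lr.std(ddof=1)) if lr.size > 1 else 0.0,
        n_excluded=int((~keep).sum()),
        retained_index=np.flatnonzero(keep),
        base=base,
    )


def _trial_means(resp: np.ndarray) -> np.ndarray:
    r = np.asarray(resp, dtype=float)
    if r.ndim == 1:
        return r
    return r.mean(axis=1)


# ---------------------------------------------------------------------------
# grid-level report


def candidate_level_pairs(attr: str, levels: list) -> list[tuple]:
    """Level pairs of a stimulus attribute worth comparing.

    Orientation: pairs separated by 45 deg; SF/TF: pairs one octave apart
    (ratio 2); luminance: (scotopic, photopic); anything else: consecutive
    sorted levels. Pair order fixes the dU sign convention (ascending value,
    scotopic before photopic).
    """
    if attr == "luminance":
        if "scotopic" in levels and "photopic" in levels:
            return [("scotopic", "photopic")]
        return [tuple(sorted(levels))] if len(levels) == 2 else []
    vals = sorted(levels)
    if attr == "orientation_deg":
        pairs = [
            (x, y) for i, x in enumerate(vals) for y in vals[i + 1 :]
            if abs(y - x - 45.0) < 1e-9
        ]
        if pairs:
            return pairs
    if attr in ("sf_cpd", "tf_hz"):
        pairs = [
            (x, y) for i, x in enumerate(vals) for y in vals[i + 1 :]
            if x > 0 and abs(y / x - 2.0) < 1e-9
        ]
        if pairs:
            return pairs
    return list(zip(vals[:-1], vals[1:]))


def joint_axes_report(
    responses: ResponseMatrix,
    pairs: list[tuple[str, str]],
    frac: float = 0.10,
    overlap_method: str = "intersection_over_set",
    cv: dict | None = None,
    seed: int = 0,
) -> tuple[list[AlignmentResult], pd.DataFrame]:
    """Joint-coding statistics for each requested variable pair on a grid.

    For each (var_a, var_b) pair and each fixed setting of the remaining
    attributes, dμ_a is computed between the two var_a levels with var_b
    held at its first level, and dμ_b between the var_b levels with var_a
    held at its first level. Missing grid cells skip that combination with
    a warning. If ``cv`` is given (kwargs for :func:`popax.ddr.cv_dprime`,
    e.g. ``{"n_train": 40, "n_iterations": 50}``), the cross-validated d′
    for the var_a discrimination is attached, enabling the
    orthogonality-versus-d′ analysis (|axis_dot| vs d′_a).

    Returns the per-combination :class:`AlignmentResult` list and a summary
    DataFrame with per-pair means of |axis_dot|, Pearson r, and overlap.
    """
    results: list[AlignmentResult] = []
    rng = np.random.default_rng(seed)
    for var_a, var_b in pairs:
        levels_a = responses.levels(var_a)
        levels_b = responses.levels(var_b)
        pairs_a = candidate_level_pairs(var_a, levels_a)
        pairs_b = candidate_level_pairs(var_b, levels_b)
        if not pairs_a or not pairs_b:
            warnings.warn(f"no level pairs for ({var_a}, {var_b}); skipped", stacklevel=2)
            continue
        fixed_settings = _fixed_settings(responses, exclude=(var_a, var_b))
        for fixed in fixed_settings:
            for a1, a2 in pairs_a:
                for b1, b2 in pairs_b:
                    try:
                        r_a1b1 = responses.single(**fixed, **{var_a: a1, var_b: b1})
                        r_a2b1 = responses.single(**fixed, **{var_a: a2, var_b: b1})
                        r_a1b2 = responses.single(**fixed, **{var_a: a1, var_b: b2})
                    except KeyError:
                        warnings.warn(
                            f"grid cells missing for {var_a}=({a1},{a2}), "
                            f"{var_b}=({b1},{b2}) at {fixed}; pair skipped",
                            stacklevel=2,
                        )
                        continue
                    dmu_a = dmu_per_cell(r_a1b1, r_a2b1)
                    dmu_b = dmu_per_cell(r_a1b1, r_a1b2)
                    pct, A, B = informative_overlap(
                        dmu_a, dmu_b, frac=frac, method=overlap_method
                    )
                    dp = None
                    if cv is not None:
                        kwargs = dict(cv)
                        n = min(r_a1b1.shape[1], r_a2b1.shape[1])
                        kwargs.setdefault("n_train", scaled_split(n))
                        kwargs["n_train"] = min(kwargs["n_train"], n - 2)
                        sub = int(rng.integers(0, 2**31 - 1))
                        dp = cv_dprime(r_a1b1, r_a2b1, seed=sub, **kwargs).mean_dprime
                    results.append(
                        AlignmentResult(
                            var_a=var_a,
                            var_b=var_b,
                            pair_a=(a1, a2),
                            pair_b=(b1, b2),
                            fixed=dict(fixed),
                            dmu_a=dmu_a,
                            dmu_b=dmu_b,
                            pearson_r=dmu_correlation(dmu_a, dmu_b),
                            axis_dot=axis_alignment(dmu_a, dmu_b),
                            overlap_pct=pct,
                            informative_a=A,
                            informative_b=B,
                            n_cells=len(dmu_a),
                            dprime_a=dp,
                        )
                    )
    rows = []
    for var_a, var_b in pairs:
        sub = [r for r in results if (r.var_a, r.var_b) == (var_a, var_b)]
        if not sub:
            continue
        rows.append(
            {
                "var_a": var_a,
                "var_b": var_b,
                "n_combinations": len(sub),
                "mean_abs_axis_dot": float(np.mean([abs(r.axis_dot) for r in sub])),
                "mean_pearson_r": float(np.nanmean([r.pearson_r for r in sub])),
                "mean_overlap_pct": float(np.mean([r.overlap_pct for r in sub])),
                "mean_dprime_a": (
                    float(np.mean([r.dprime_a for r in sub]))
                    if all(r.dprime_a is not None for r in sub)
                    else np.nan
                ),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "var_a", "var_b", "n_combinations", "mean_abs_axis_dot",
            "mean_pearson_r", "mean_overlap_pct", "mean_dprime_a",
        ],
    )
    return results, summary


def _fixed_settings(responses: ResponseMatrix, exclude: tuple[str, str]) -> list[dict]:
    """Distinct settings of all condition attributes other than the pair."""
    other = [
        f for f in Condition.__dataclass_fields__
        if f not in exclude
        and any(getattr(c, f) is not None for c in responses.conditions)
    ]
    if not other:
        return [{}]
    seen: list[dict] = []
    for c in responses.conditions:
        setting = {f: getattr(c, f) for f in other}
        if setting not in seen:
            seen.append(setting)
    return seen
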