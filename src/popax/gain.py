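"""Scalar-gain hypothesis test: is luminance coded as a one-dimensional gain?

If luminance were carried purely by a multiplicative gain g inherited from
the retina — photopic responses drawn from N(g·μ, g·Σ) when scotopic
responses follow N(μ, Σ) — then equalizing response magnitudes across the
two light conditions (dividing each condition by its maximum trial-averaged
response across cells) would erase luminance information: the condition
means become identical and the two clouds are no longer linearly separable.
If instead luminance modulation is heterogeneous and bidirectional across
cells (high-dimensional), the same normalization barely moves d′.

The statistic is the d′ ratio d′_post / d′_pre: near 0 under the scalar-gain
model, near 1 under high-dimensional (random-encoding) modulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Condition, ResponseMatrix
from .ddr import cv_dprime, scaled_split, shuffled_null_dprime
from .errors import ParameterError
from .synthetic import PopulationModel, make_population, sample_trials

__all__ = [
    "NormalizationResult",
    "normalize_by_condition_max",
    "gain_sim_dprime",
    "dataset_dprime_ratio",
]


@dataclass
class NormalizationResult:
    """d′ before/after per-condition max normalization and their ratio.

    ``dprime_ratio`` is NaN (flagged undefined) when ``dprime_pre`` does not
    exceed the shuffled-label null threshold (no luminance information to
    begin with). ``per_condition`` carries the per-stimulus breakdown for
    dataset-mode results.
    """

    mode: str  # "scalar_gain_sim" | "dataset"
    dprime_pre: float
    dprime_post: float
    dprime_ratio: float
    constants: dict
    null_95: float | None = None
    per_condition: pd.DataFrame | None = None
    seed: int = 0


def normalize_by_condition_max(
    responses: ResponseMatrix,
    by: str | None = None,
) -> tuple[ResponseMatrix, dict]:
    """Divide every trial by its condition's maximum trial-averaged response.

    One positive scalar per condition: the max over cells of that
    condition's trial-averaged response. With ``by`` set to a condition
    attribute (e.g. ``"luminance"``), conditions sharing that attribute are
    normalized by a common constant — the max over all their cells and
    stimuli — matching normalization per light condition. Idempotent: after
    one application every group's max trial-averaged response is 1.
    """
    groups: dict = {}
    for cond in responses.conditions:
        key = cond if by is None else getattr(cond, by)
        groups.setdefault(key, []).append(cond)

    constants: dict = {}
    for key, conds in groups.items():
        m = max(float(responses[c].mean(axis=1).max()) for c in conds)
        if m <= 0:
            raise ParameterError(
                f"non-positive maximum trial-averaged response in group {key!r}; "
                "cannot normalize"
            )
        constants[key] = m

    def _scale(cond: Condition, arr: np.ndarray) -> np.ndarray:
        key = cond if by is None else getattr(cond, by)
        return arr / constants[key]

    return responses.map_trials(_scale), constants


def gain_sim_dprime(
    n_cells: int = 2,
    gain: float = 2.0,
    base_mean: np.ndarray | None = None,
    base_var: float = 0.01,
    n_trials: int = 200,
    n_train: int | None = None,
    n_iterations: int = 50,
    seed: int = 0,
    *,
    with_null: bool = True,
    n_null: int = 100,
) -> NormalizationResult:
    """Simulate scalar-gain luminance coding and test the normalization control.

    Scotopic trials are drawn from N(μ, Σ) and photopic from N(g·μ, g·Σ)
    with Σ = base_var·I (variance, not SD, scaled by g). Cross-validated d′
    is computed before and after per-condition max normalization; when
    ``with_null``, the post-normalization d′ is referenced against the 95th
    percentile of a shuffled-label null on the normalized data.
    """
    if not gain > 0:
        raise ParameterError("gain must be positive")
    if n_trials < 20:
        raise ParameterError("n_trials must be >= 20")
    if base_mean is None:
        base_mean = (
            np.array([1.0, 0.5])
            if n_cells == 2
            else np.linspace(0.5, 1.5, n_cells)
        )
    base_mean = np.asarray(base_mean, dtype=float)
    if base_mean.shape != (n_cells,):
        raise ParameterError("base_mean must have one entry per cell")

    model = PopulationModel(
        n_cells=n_cells,
        conditions=(
            Condition(luminance="scotopic"),
            Condition(luminance="photopic"),
        ),
        mean_matrix=np.column_stack([base_mean, gain * base_mean]),
        dmu={"luminance": (gain - 1.0) * base_mean},
        dmu_rho=0.0,
        gain=gain,
        noise_sd=np.full(n_cells, np.sqrt(base_var)),
        shared_noise_loading=np.zeros(n_cells) + 1e-12,
        cov_scale=np.array([1.0, gain]),
        baseline=float(base_mean.mean()),
        seed=int(seed),
        model="scalar_gain",
    )
    ds = sample_trials(model, n_trials, seed=seed)
    return _pre_post_ratio(
        ds.responses,
        mode="scalar_gain_sim",
        by=None,
        n_train=n_train,
        n_iterations=n_iterations,
        seed=seed,
        with_null=with_null,
        n_null=n_null,
    )


def _pre_post_ratio(
    responses: ResponseMatrix,
    mode: str,
    by: str | None,
    n_train: int | None,
    n_iterations: int,
    seed: int,
    with_null: bool,
    n_null: int,
) -> NormalizationResult:
    scot = responses.single(luminance="scotopic")
    phot = responses.single(luminance="photopic")
    n = min(scot.shape[1], phot.shape[1])
    if n_train is None:
        n_train = scaled_split(n)
    pre = cv_dprime(scot, phot, n_train=n_train, n_iterations=n_iterations, seed=seed)

    normed, constants = normalize_by_condition_max(responses, by=by)
    scot_n = normed.single(luminance="scotopic")
    phot_n = normed.single(luminance="photopic")
    post = cv_dprime(
        scot_n, phot_n, n_train=n_train, n_iterations=n_iterations, seed=seed
    )

    null_95 = None
    ratio = post.mean_dprime / pre.mean_dprime if pre.mean_dprime > 0 else np.nan
    if with_null:
        null = shuffled_null_dprime(
            scot_n,
            phot_n,
            n_shuffles=n_null,
            seed=seed + 1,
            n_train=n_train,
            n_iterations=max(5, n_iterations // 10),
        )
        null_95 = float(np.percentile(null, 95))
        if pre.mean_dprime <= null_95:
            warnings.warn(
                "pre-normalization d' does not exceed the shuffled null; "
                "d' ratio flagged undefined",
                stacklevel=3,
            )
            ratio = np.nan
    return NormalizationResult(
        mode=mode,
        dprime_pre=pre.mean_dprime,
        dprime_post=post.mean_dprime,
        dprime_ratio=float(ratio),
        constants={str(k): v for k, v in constants.items()},
        null_95=null_95,
        seed=int(seed),
    )


def dataset_dprime_ratio(
    responses: ResponseMatrix,
    n_train: int | None = None,
    n_iterations: int = 50,
    seed: int = 0,
    *,
    by: str = "luminance",
    with_null: bool = False,
    n_null: int = 50,
) -> NormalizationResult:
    """d′ ratio for a dataset: luminance d′ before vs after max normalization.

    For each setting of the non-luminance attributes (e.g. each grating
    orientation), the scotopic and photopic response matrices are compared
    with :func:`popax.ddr.cv_dprime` before and after normalization by the
    per-light-condition maximum (``by="luminance"``). Per-stimulus ratios
    are reported and averaged; a ratio near 1 rules out a purely
    one-dimensional gain code for luminance.
    """
    if not any(c.luminance is not None for c in responses.conditions):
        raise ParameterError("responses carry no luminance conditions")

    normed, constants = normalize_by_condition_max(responses, by=by)

    fixed_attrs = [
        f for f in Condition.__dataclass_fields__
        if f != "luminance"
        and any(getattr(c, f) is not None for c in responses.conditions)
    ]
    settings: list[dict] = []
    for c in responses.conditions:
        s = {f: getattr(c, f) for f in fixed_attrs}
        if s not in settings:
            settings.append(s)
    if not settings:
        settings = [{}]

    rng = np.random.default_rng(seed)
    rows = []
    for s in settings:
        try:
            scot = responses.single(luminance="scotopic", **s)
            phot = responses.single(luminance="photopic", **s)
            scot_n = normed.single(luminance="scotopic", **s)
            phot_n = normed.single(luminance="photopic", **s)
        except KeyError:
            warnings.warn(f"setting {s} lacks a luminance pair; skipped", stacklevel=2)
            continue
        n = min(scot.shape[1], phot.shape[1])
        nt = scaled_split(n) if n_train is None else min(n_train, n - 2)
        sub = int(rng.integers(0, 2**31 - 1))
        pre = cv_dprime(scot, phot, n_train=nt, n_iterations=n_iterations, seed=sub)
        post = cv_dprime(scot_n, phot_n, n_train=nt, n_iterations=n_iterations, seed=sub)
        ratio = post.mean_dprime / pre.mean_dprime if pre.mean_dprime > 0 else np.nan
        null_95 = None
        if with_null:
            null = shuffled_null_dprime(
                scot_n, phot_n, n_shuffles=n_null, seed=sub + 1,
                n_train=nt, n_iterations=max(5, n_iterations // 10),
            )
            null_95 = float(np.percentile(null, 95))
            if pre.mean_dprime <= null_95:
                ratio = np.nan
        rows.append(
            {**s, "dprime_pre": pre.mean_dprime, "dprime_post": post.mean_dprime,
             "dprime_ratio": ratio, "null_95": null_95}
        )
    if not rows:
        raise ParameterError("no luminance condition pairs found")
    per = pd.DataFrame(rows)
    ratios = per["dprime_ratio"].to_numpy(dtype=float)
    return NormalizationResult(
        mode="dataset",
        dprime_pre=float(per["dprime_pre"].mean()),
        dprime_post=float(per["dprime_post"].mean()),
        dprime_ratio=float(np.nanmean(ratios)) if np.isfinite(ratios).any() else np.nan,
        constants={str(k): v for k, v in constants.items()},
        null_95=None,
        per_condition=per,
        seed=int(seed),
    )
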