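"""Synthetic population generator.

Generates V1-like population responses with controlled joint-coding structure:

* **bidirectional model** — each cell carries a per-variable sensitivity
  dμ_v (its change in trial-averaged ΔF/F for the two levels of stimulus
  variable v), drawn from a zero-mean multivariate normal whose pairwise
  correlations are set by the caller. A correlation of 0 between two
  variables is the *random encoding model* (orthogonal population decoding
  axes); |ρ| = 1 is the *shared encoding model* (parallel axes).
* **scalar-gain model** — luminance is coded purely as a one-dimensional
  multiplicative gain g: photopic condition means equal g times the
  scotopic means cell-wise, and photopic trial covariance equals g times
  the scotopic covariance (variance, not SD, scaled).

Trial noise is diagonal (per-cell SD) plus one shared rank-1 latent
dimension, giving the trial-to-trial covariance a dominant axis as the dDR
construction assumes. Optionally, scalar trial responses are rendered into
GCaMP6s-like fluorescence traces as exponential-decay transients so the
trace-preprocessing pipeline can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Condition, EVENT_COLUMNS, ResponseMatrix, TraceSet
from .errors import BoundsError, ConfigurationError, NumericError, ParameterError

DEFAULT_VARIABLES: dict[str, tuple] = {
    "orientation_deg": (0.0, 45.0),
    "luminance": ("scotopic", "photopic"),
}


@dataclass
class PopulationModel:
    """Ground-truth generative model for a synthetic population.

    ``mean_matrix`` has one column per condition (ordered as ``conditions``);
    ``dmu`` maps each varied stimulus attribute to the per-cell mean-response
    difference between its two levels (level 2 minus level 1).
    ``cov_scale[j]`` multiplies the trial covariance of condition j (g for
    photopic conditions under the scalar-gain model, 1 otherwise).
    """

    n_cells: int
    conditions: tuple[Condition, ...]
    mean_matrix: np.ndarray  # (n_cells, n_conditions)
    dmu: dict[str, np.ndarray]
    dmu_rho: float
    gain: float
    noise_sd: np.ndarray  # (n_cells,)
    shared_noise_loading: np.ndarray  # (n_cells,)
    cov_scale: np.ndarray  # (n_conditions,)
    baseline: float
    seed: int
    model: str  # "bidirectional" | "scalar_gain"

    def __post_init__(self) -> None:
        self.mean_matrix = np.asarray(self.mean_matrix, dtype=float)
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_cells,)
        ).copy()
        self.shared_noise_loading = np.broadcast_to(
            np.asarray(self.shared_noise_loading, dtype=float), (self.n_cells,)
        ).copy()
        if abs(self.dmu_rho) > 1:
            raise ParameterError("|dmu_rho| must be <= 1")
        if not self.gain > 0:
            raise ParameterError("gain must be positive")
        if not (self.noise_sd > 0).all():
            raise ParameterError("all noise_sd must be positive")
        if self.mean_matrix.shape != (self.n_cells, len(self.conditions)):
            raise ParameterError("mean_matrix must be n_cells x n_conditions")
        if not np.isfinite(self.mean_matrix).all():
            raise NumericError("mean_matrix contains missing values")

    def condition_index(self, **attrs) -> int:
        idx = [j for j, c in enumerate(self.conditions) if c.matches(**attrs)]
        if len(idx) != 1:
            raise KeyError(f"{len(idx)} conditions match {attrs}, expected 1")
        return idx[0]


@dataclass
class SyntheticDataset:
    """A sampled dataset plus the model that generated it."""

    responses: ResponseMatrix
    events: pd.DataFrame
    ground_truth: PopulationModel
    frame_rate: float
    traces: TraceSet | None = None
    n_trials: int = 0
    seed: int = 0


def _pair_correlation_matrix(
    names: list[str], dmu_rho: float, rho: dict[tuple[str, str], float] | None
) -> np.ndarray:
    k = len(names)
    R = np.eye(k)
    if k >= 2:
        R[0, 1] = R[1, 0] = dmu_rho
    if rho:
        pos = {n: i for i, n in enumerate(names)}
        for (a, b), r in rho.items():
            if abs(r) > 1:
                raise ParameterError(f"|rho({a},{b})| must be <= 1")
            R[pos[a], pos[b]] = R[pos[b], pos[a]] = r
    # validity check: smallest eigenvalue may be ~0 for |rho|=1
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10:
        raise NumericError(f"requested dμ correlation matrix is not PSD (min eig {w.min():.3g})")
    return R


def make_population(
    n_cells: int,
    dmu_rho: float = 0.0,
    gain: float = 1.0,
    seed: int = 0,
    *,
    variables: dict[str, tuple] | None = None,
    rho: dict[tuple[str, str], float] | None = None,
    dmu_sd: float | dict[str, float] = 0.5,
    baseline: float = 1.0,
    noise_sd: float | np.ndarray = 0.3,
    shared_noise_loading: float | np.ndarray = 0.15,
    model: str = "bidirectional",
) -> PopulationModel:
    """Build a ground-truth population model.

    Parameters
    ----------
    n_cells : int
        Population size (>= 2).
    dmu_rho : float in [-1, 1]
        Correlation between per-cell sensitivities to the first two varied
        variables (orientation and luminance by default). 0 is the random
        encoding model, |1| the shared encoding model.
    gain : float > 0
        Scalar gain applied to photopic means and variances when
        ``model="scalar_gain"``; ignored (must be 1-compatible) otherwise.
    variables : mapping name -> (level_1, level_2)
        Stimulus attributes varied over a full factorial grid. Default:
        two orientations (0, 45 deg) x two luminances (scotopic, photopic).
    rho : mapping (name, name) -> float, optional
        Extra pairwise dμ correlations for grids with > 2 varied variables.
    dmu_sd : float or mapping name -> float
        SD of the per-cell sensitivity for each variable (ΔF/F units).
    baseline : float
        Positive offset added to every condition mean so that responses are
        mostly positive, as evoked ΔF/F is.
    noise_sd, shared_noise_loading : float or per-cell array
        Private trial-noise SD and loading on the single shared latent noise
        dimension; the trial covariance is
        ``diag(noise_sd**2) + loading @ loading.T`` (times ``cov_scale``).
    """
    if n_cells < 2:
        raise ParameterError("n_cells must be >= 2")
    if abs(dmu_rho) > 1:
        raise ParameterError("|dmu_rho| must be <= 1")
    if not gain > 0:
        raise ParameterError("gain must be positive")
    if model not in ("bidirectional", "scalar_gain"):
        raise ParameterError(f"unknown model {model!r}")

    variables = dict(variables) if variables else dict(DEFAULT_VARIABLES)
    for name, levels in variables.items():
        if name not in Condition.__dataclass_fields__:
            raise ParameterError(f"unknown condition attribute {name!r}")
        if len(levels) != 2:
            raise ParameterError(f"variable {name!r} must have exactly 2 levels")

    rng = np.random.default_rng(seed)
    names = list(variables)

    # the scalar-gain model does not draw a luminance sensitivity: luminance
    # enters as a pure multiplicative gain on the other variables' tuning
    drawn = [n for n in names if not (model == "scalar_gain" and n == "luminance")]
    if model == "scalar_gain" and "luminance" not in names:
        raise ParameterError("scalar_gain model requires a 'luminance' variable")

    sds = (
        {n: float(dmu_sd) for n in drawn}
        if np.isscalar(dmu_sd)
        else {n: float(dmu_sd[n]) for n in drawn}  # type: ignore[index]
    )
    R = _pair_correlation_matrix(drawn, dmu_rho if len(drawn) >= 2 else 0.0, rho)
    D = np.diag([sds[n] for n in drawn])
    cov = D @ R @ D
    # eigen factorization tolerates the singular |rho|=1 case exactly
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    Z = rng.standard_normal((n_cells, len(drawn)))
    sens = Z @ (V * np.sqrt(w)) @ V.T  # (n_cells, k) with covariance `cov`
    dmu = {n: sens[:, i].copy() for i, n in enumerate(drawn)}

    # factorial condition grid, deterministic order
    conditions: list[Condition] = []
    grid_idx: list[dict[str, int]] = []

    def _extend(partial: dict[str, int], remaining: list[str]) -> None:
        if not remaining:
            grid_idx.append(dict(partial))
            return
        name = remaining[0]
        for li in (0, 1):
            partial[name] = li
            _extend(partial, remaining[1:])
        del partial[name]

    _extend({}, names)
    for g in grid_idx:
        conditions.append(Condition(**{n: variables[n][g[n]] for n in names}))

    mean = np.empty((n_cells, len(conditions)))
    cov_scale = np.ones(len(conditions))
    for j, g in enumerate(grid_idx):
        m = np.full(n_cells, float(baseline))
        for n in drawn:
            m = m + (g[n] - 0.5) * dmu[n]  # level 1 -> -dμ/2, level 2 -> +dμ/2
        mean[:, j] = m
    if model == "scalar_gain":
        lum_levels = variables["luminance"]
        for j, g in enumerate(grid_idx):
            if g["luminance"] == 1:  # photopic level
                cov_scale[j] = gain
                mean[:, j] *= gain
        # implied luminance sensitivity: photopic minus scotopic means
        scot = [j for j, g in enumerate(grid_idx) if g["luminance"] == 0]
        phot = [j for j, g in enumerate(grid_idx) if g["luminance"] == 1]
        dmu["luminance"] = (mean[:, phot].mean(axis=1) - mean[:, scot].mean(axis=1))
        del lum_levels

    return PopulationModel(
        n_cells=n_cells,
        conditions=tuple(conditions),
        mean_matrix=mean,
        dmu=dmu,
        dmu_rho=float(dmu_rho),
        gain=float(gain),
        noise_sd=np.asarray(noise_sd, dtype=float),
        shared_noise_loading=np.asarray(shared_noise_loading, dtype=float),
        cov_scale=cov_scale,
        baseline=float(baseline),
        seed=int(seed),
        model=model,
    )


def sample_trials(
    model: PopulationModel,
    n_trials: int,
    seed: int = 0,
    *,
    frame_rate: float = 10.0,
    trial_spacing_s: float = 6.0,
    pre_s: float = 2.0,
    duration_s: float = 0.5,
) -> SyntheticDataset:
    """Draw per-condition trials from the model's multivariate normal.

    Each condition j yields ``n_trials`` draws from
    ``N(mean[:, j], cov_scale[j] * (diag(noise_sd^2) + L L^T))`` where L is
    the shared-noise loading vector. Sampling is structural
    (``mean + sqrt(scale) * (noise_sd * z + L * u)``), which realizes that
    covariance exactly and is deterministic given the seed.

    The returned event table interleaves conditions on a fixed schedule
    (``pre_s`` of baseline, then one trial every ``trial_spacing_s``), giving
    :func:`synth_traces` a concrete frame layout.
    """
    if n_trials < 2:
        raise ParameterError("n_trials must be >= 2")
    if (model.cov_scale <= 0).any():
        raise NumericError("requested covariance scale is non-positive")

    rng = np.random.default_rng(seed)
    n_cond = len(model.conditions)
    data: dict[Condition, np.ndarray] = {}
    for j, cond in enumerate(model.conditions):
        z = rng.standard_normal((model.n_cells, n_trials))
        u = rng.standard_normal(n_trials)
        noise = model.noise_sd[:, None] * z + model.shared_noise_loading[:, None] * u[None, :]
        data[cond] = model.mean_matrix[:, j : j + 1] + math.sqrt(model.cov_scale[j]) * noise
    responses = ResponseMatrix(data, cell_ids=np.arange(model.n_cells))

    rows = []
    for t in range(n_trials):
        for j, cond in enumerate(model.conditions):
            slot = t * n_cond + j
            onset_s = pre_s + slot * trial_spacing_s
            row = {k: None for k in EVENT_COLUMNS}
            row.update(cond.as_dict(drop_none=True))
            row["onset_frame"] = int(round(onset_s * frame_rate))
            row["onset_time_s"] = onset_s
            row["duration_s"] = duration_s
            row["trial_index"] = t + 1
            rows.append(row)
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS + ["onset_time_s"])

    return SyntheticDataset(
        responses=responses,
        events=events,
        ground_truth=model,
        frame_rate=frame_rate,
        n_trials=n_trials,
        seed=int(seed),
    )


def exponential_kernel(n_frames: int, frame_rate: float, tau_s: float) -> np.ndarray:
    """Causal single-exponential transient sampled per frame, k[0] = 1."""
    t = np.arange(n_frames) / frame_rate
    return np.exp(-t / tau_s)


def window_kernel_factor(
    frame_rate: float,
    kernel_tau: float,
    window_ms: tuple[float, float] = (450.0, 1300.0),
) -> float:
    """Mean of the exponential transient over the response-window frames.

    A trial whose injected scalar amplitude is ``a`` produces a window-mean
    ΔF/F of exactly ``a * window_kernel_factor(...)`` in a noise-free trace:
    the transient is sampled at frame offsets d = 0, 1, ... from onset, and
    the response window keeps frames whose centers (d + 0.5)/rate fall in
    [start, end) ms after onset.
    """
    lo, hi = window_ms
    d = np.arange(int(np.ceil(frame_rate * hi / 1000.0)) + 1)
    centers_ms = (d + 0.5) / frame_rate * 1000.0
    keep = (centers_ms >= lo) & (centers_ms < hi)
    if not keep.any():
        raise ConfigurationError(
            f"no frame centers fall in window {window_ms} ms at {frame_rate} Hz"
        )
    return float(np.exp(-d[keep] / (frame_rate * kernel_tau)).mean())


def synth_traces(
    dataset: SyntheticDataset,
    frame_rate: float | None = None,
    kernel_tau: float = 1.0,
    baseline_level: float = 1.0,
    trace_noise_sd: float = 0.02,
    seed: int = 0,
    n_frames: int | None = None,
) -> TraceSet:
    """Render the dataset's scalar responses into raw fluorescence traces.

    Each trial's response amplitude ``a`` (ΔF/F units) becomes an
    exponential-decay transient starting at its onset frame on a constant
    raw-fluorescence baseline ``F0``::

        F[c, t] = F0 * (1 + sum_e a[e, c] * k(t - onset_e)) + F0 * noise

    Overlapping transients add linearly by construction. With zero noise,
    running the preprocessing pipeline (ΔF/F + response-window mean) on the
    output recovers ``a * window_kernel_factor(frame_rate, kernel_tau)``.
    """
    fr = dataset.frame_rate if frame_rate is None else float(frame_rate)
    if not (5.0 <= fr <= 60.0):
        raise ParameterError("frame_rate must be in [5, 60] Hz")
    if not kernel_tau > 0:
        raise ParameterError("kernel_tau must be positive")

    events = dataset.events
    if frame_rate is not None and frame_rate != dataset.frame_rate:
        events = events.copy()
        events["onset_frame"] = np.round(events["onset_time_s"] * fr).astype(int)

    onsets = events["onset_frame"].to_numpy().astype(int)
    tail_s = max(5.0 * kernel_tau, 2.0)
    needed = int(onsets.max() + math.ceil(fr * tail_s)) + 1
    if n_frames is None:
        n_frames = needed
    elif n_frames < onsets.max() + 1:
        raise BoundsError("events extend beyond the requested trace length")

    n_cells = dataset.responses.n_cells
    rng = np.random.default_rng(seed)
    signal = np.zeros((n_cells, n_frames))
    kernel_cache: dict[int, np.ndarray] = {}
    for row, onset in zip(events.itertuples(index=False), onsets):
        cond = _row_condition(row)
        amp = dataset.responses[cond][:, int(row.trial_index) - 1]
        span = n_frames - onset
        if span not in kernel_cache:
            kernel_cache[span] = exponential_kernel(span, fr, kernel_tau)
        signal[:, onset:] += amp[:, None] * kernel_cache[span][None, :]

    F = baseline_level * (1.0 + signal)
    if trace_noise_sd > 0:
        F = F + baseline_level * trace_noise_sd * rng.standard_normal(F.shape)
    return TraceSet(
        fluorescence=F, frame_rate=fr, cell_ids=dataset.responses.cell_ids.copy()
    )


def _row_condition(row) -> Condition:
    kw = {}
    for name in Condition.__dataclass_fields__:
        v = getattr(row, name, None)
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            kw[name] = v
    return Condition(**kw)
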