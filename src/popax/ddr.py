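"""Targeted dimensionality reduction (dDR) and cross-validated discriminability.

The decoding space for a pair of stimulus conditions is the plane spanned by

* **dU** — the signal axis: the per-cell difference between the two
  conditions' trial-averaged responses (second condition minus first), and
* **n1** — the dominant noise axis: the first principal component e1 of the
  "noise matrix" (each condition's trials with its own trial mean removed,
  concatenated, N_cells x (n_A + n_B)), orthogonalized against dU and
  renormalized.

Trials projected into (dU_unit, n1) are summarized by the discriminability
index d′ between the two projected clouds. The default is the Mahalanobis
form d′ = sqrt(ΔU Σ⁻¹ ΔUᵀ) with Σ the pooled 2x2 covariance of the
mean-centered projected trials; the raw quadratic form ΔU Σ ΔUᵀ is available
for comparison via ``method="raw_quadratic"``.

Cross-validation follows the hold-out scheme of the source analysis: per
iteration, fit the basis on a random subset of trials per condition
(default 40 of 50), project the held-out trials, and compute d′ on those
projections alone; the reported d′ is the mean over iterations (default 50).

Two scikit-learn style estimators expose the same machinery for pipeline
composition: :class:`DDRBasis` (a ``TransformerMixin``: ``fit(X, y)`` on
trials x cells with binary condition labels, ``transform`` projects into the
plane) and :class:`DPrimeDecoder` (``fit`` runs the full cross-validated
procedure and stores ``mean_dprime_`` etc.). The module-level functions,
which operate on the field-standard cells x trials orientation, are thin
wrappers around the same internals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .containers import Condition, ResponseMatrix
from .errors import (
    DegenerateBasisError,
    InsufficientDataError,
    ParameterError,
    ShapeError,
)

__all__ = [
    "DecodingBasis",
    "DPrimeResult",
    "compute_dU",
    "build_noise_matrix",
    "fit_basis",
    "project",
    "dprime_2d",
    "cv_dprime",
    "shuffled_null_dprime",
    "movie_luminance_dprime",
    "DDRBasis",
    "DPrimeDecoder",
]


# ---------------------------------------------------------------------------
# results


@dataclass
class DecodingBasis:
    """The fitted dDR pair.

    ``dU_unit`` and ``n1`` are unit-norm and mutually orthogonal (within
    1e-10); ``e1`` is the first noise principal component before
    orthogonalization, sign-fixed so that e1 · 1 >= 0.
    """

    dU_raw: np.ndarray
    dU_unit: np.ndarray
    e1: np.ndarray
    n1: np.ndarray
    fitted_on: dict | None = None

    @property
    def n_cells(self) -> int:
        return self.dU_raw.shape[0]


@dataclass
class DPrimeResult:
    """Cross-validated discriminability between two conditions."""

    per_iteration_dprime: np.ndarray
    mean_dprime: float
    sd_dprime: float
    n_train: int
    n_test: int
    n_iterations: int
    seed: int
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.per_iteration_dprime = np.asarray(self.per_iteration_dprime, dtype=float)


# ---------------------------------------------------------------------------
# building blocks


def _as_cells_by_trials(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ShapeError(f"{name} must be a cells x trials matrix")
    if np.isnan(a).any():
        raise ShapeError(f"{name} contains NaN responses; drop invalid trials first")
    return a


def compute_dU(resp_a: np.ndarray, resp_b: np.ndarray) -> np.ndarray:
    """Signal axis: trial-mean of ``resp_b`` minus trial-mean of ``resp_a``.

    The sign convention is second argument minus first; callers order
    luminance scotopic -> photopic and orientations by ascending angle.
    """
    a = _as_cells_by_trials(resp_a, "resp_a")
    b = _as_cells_by_trials(resp_b, "resp_b")
    if a.shape[0] != b.shape[0]:
        raise ShapeError(
            f"cell axes differ: {a.shape[0]} vs {b.shape[0]}"
        )
    return b.mean(axis=1) - a.mean(axis=1)


def build_noise_matrix(resp_a: np.ndarray, resp_b: np.ndarray) -> np.ndarray:
    """Concatenate per-condition mean-centered trials: cells x (n_a + n_b)."""
    a = _as_cells_by_trials(resp_a, "resp_a")
    b = _as_cells_by_trials(resp_b, "resp_b")
    if a.shape[0] != b.shape[0]:
        raise ShapeError("cell axes differ")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise InsufficientDataError("need >= 2 trials per condition for the noise matrix")
    return np.concatenate(
        [a - a.mean(axis=1, keepdims=True), b - b.mean(axis=1, keepdims=True)], axis=1
    )


def _first_noise_pcs(noise: np.ndarray, n_components: int) -> np.ndarray:
    """Leading principal directions (rows) of the noise matrix in cell space.

    Trials are samples, cells are features. The per-condition blocks are
    already zero-mean per cell, so PCA's feature centering is a no-op and
    the components equal the left singular vectors of the noise matrix.
    """
    n_components = min(n_components, min(noise.shape))
    pca = PCA(n_components=n_components)
    pca.fit(noise.T)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):  # deterministic sign: e · 1 >= 0
        if comps[i].sum() < 0:
            comps[i] = -comps[i]
    return comps


def fit_basis(
    resp_a: np.ndarray,
    resp_b: np.ndarray,
    fitted_on: dict | None = None,
) -> DecodingBasis:
    """Fit the dDR basis (dU_unit, n1) from two cells x trials matrices."""
    dU = compute_dU(resp_a, resp_b)
    norm = np.linalg.norm(dU)
    if norm == 0:
        raise DegenerateBasisError("dU is the zero vector; conditions are identical")
    dU_unit = dU / norm

    noise = build_noise_matrix(resp_a, resp_b)
    comps = _first_noise_pcs(noise, n_components=2)
    e1 = comps[0]

    def _orthogonalize(e: np.ndarray) -> np.ndarray | None:
        v = e - (e @ dU_unit) * dU_unit
        nv = np.linalg.norm(v)
        if nv < 1e-8:
            return None
        return v / nv

    n1 = _orthogonalize(e1)
    if n1 is None:
        if comps.shape[0] > 1:
            warnings.warn(
                "e1 is parallel to dU; falling back to the second noise PC",
                stacklevel=2,
            )
            n1 = _orthogonalize(comps[1])
        if n1 is None:
            raise DegenerateBasisError(
                "noise principal components are parallel to dU; no 2-D basis exists"
            )
    return DecodingBasis(dU_raw=dU, dU_unit=dU_unit, e1=e1, n1=n1, fitted_on=fitted_on)


def project(resp: np.ndarray, basis: DecodingBasis) -> np.ndarray:
    """Project cells x trials responses into the decoding plane (2 x trials)."""
    r = _as_cells_by_trials(resp, "resp")
    if r.shape[0] != basis.n_cells:
        raise ShapeError(
            f"response has {r.shape[0]} cells, basis was fitted on {basis.n_cells}"
        )
    return np.vstack([basis.dU_unit @ r, basis.n1 @ r])


def _pooled_cov(proj_a: np.ndarray, proj_b: np.ndarray) -> np.ndarray:
    ca = proj_a - proj_a.mean(axis=1, keepdims=True)
    cb = proj_b - proj_b.mean(axis=1, keepdims=True)
    X = np.concatenate([ca, cb], axis=1)
    dof = X.shape[1] - 2  # one mean estimated per condition
    if dof < 1:
        raise InsufficientDataError("need >= 2 trials per condition for Σ")
    return (X @ X.T) / dof


def _dprime_from(dU2: np.ndarray, sigma: np.ndarray, method: str) -> float:
    if not np.any(dU2):
        return 0.0
    if method == "raw_quadratic":
        return float(dU2 @ sigma @ dU2)
    if method != "mahalanobis":
        raise ParameterError(f"unknown d-prime method {method!r}")
    try:
        sol = np.linalg.solve(sigma, dU2)
        if not np.isfinite(sol).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        eps = 1e-6 * np.trace(sigma) / sigma.shape[0]
        if eps <= 0:
            eps = 1e-12
        warnings.warn("singular Σ; applying ridge regularization", stacklevel=3)
        sol = np.linalg.solve(sigma + eps * np.eye(sigma.shape[0]), dU2)
    return float(np.sqrt(max(dU2 @ sol, 0.0)))


def dprime_2d(
    proj_a: np.ndarray,
    proj_b: np.ndarray,
    method: str = "mahalanobis",
    sigma: np.ndarray | None = None,
) -> float:
    """Discriminability between two projected trial clouds (2 x n each).

    ΔU is the difference of the projected condition means; Σ is the pooled
    covariance of the mean-centered projected trials from both conditions
    (or ``sigma`` if supplied, e.g. a train-set estimate). The default
    returns sqrt(ΔU Σ⁻¹ ΔUᵀ); ``method="raw_quadratic"`` returns ΔU Σ ΔUᵀ.
    """
    pa = np.atleast_2d(np.asarray(proj_a, dtype=float))
    pb = np.atleast_2d(np.asarray(proj_b, dtype=float))
    if pa.shape[0] != pb.shape[0]:
        raise ShapeError("projections live in different dimensions")
    if pa.shape[1] < 2 or pb.shape[1] < 2:
        raise InsufficientDataError("need >= 2 trials per condition")
    dU2 = pb.mean(axis=1) - pa.mean(axis=1)
    if sigma is None:
        sigma = _pooled_cov(pa, pb)
    return _dprime_from(dU2, np.asarray(sigma, dtype=float), method)


# ---------------------------------------------------------------------------
# cross-validated d-prime


def cv_dprime(
    resp_a: np.ndarray,
    resp_b: np.ndarray,
    n_train: int = 40,
    n_iterations: int = 50,
    seed: int = 0,
    *,
    n_test: int | None = None,
    method: str = "mahalanobis",
    cov_source: str = "test",
    labels: tuple = (),
) -> DPrimeResult:
    """Cross-validated d′ between two cells x trials response matrices.

    Per iteration: sample ``n_train`` trials per condition without
    replacement, fit the dDR basis on them, project the held-out trials,
    and compute d′ on the held-out projections. ``cov_source="train"``
    instead pools Σ from the projected training trials (held-out means only).
    The reported value is the mean over iterations.
    """
    a = _as_cells_by_trials(resp_a, "resp_a")
    b = _as_cells_by_trials(resp_b, "resp_b")
    na, nb = a.shape[1], b.shape[1]
    if n_train < 2:
        raise ParameterError("n_train must be >= 2")
    if na <= n_train or nb <= n_train:
        raise ParameterError(
            f"both conditions need more than n_train={n_train} trials (have {na}, {nb})"
        )
    if cov_source not in ("test", "train"):
        raise ParameterError(f"unknown cov_source {cov_source!r}")

    rng = np.random.default_rng(seed)
    vals = np.empty(n_iterations)
    used_test = None
    for it in range(n_iterations):
        pa = rng.permutation(na)
        pb = rng.permutation(nb)
        tr_a, te_a = pa[:n_train], pa[n_train:]
        tr_b, te_b = pb[:n_train], pb[n_train:]
        if n_test is not None:
            te_a, te_b = te_a[:n_test], te_b[:n_test]
        used_test = (len(te_a), len(te_b))
        basis = fit_basis(a[:, tr_a], b[:, tr_b])
        qa, qb = project(a[:, te_a], basis), project(b[:, te_b], basis)
        sigma = None
        if cov_source == "train":
            sigma = _pooled_cov(project(a[:, tr_a], basis), project(b[:, tr_b], basis))
        vals[it] = dprime_2d(qa, qb, method=method, sigma=sigma)
    return DPrimeResult(
        per_iteration_dprime=vals,
        mean_dprime=float(vals.mean()),
        sd_dprime=float(vals.std(ddof=1)) if n_iterations > 1 else 0.0,
        n_train=n_train,
        n_test=int(min(used_test)) if used_test else 0,
        n_iterations=n_iterations,
        seed=int(seed),
        labels=labels,
    )


def shuffled_null_dprime(
    resp_a: np.ndarray,
    resp_b: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
    **cv_kwargs,
) -> np.ndarray:
    """Null distribution of mean d′ under random condition labels.

    Pools the trials of both conditions and, per shuffle, reassigns them to
    two pseudo-conditions of the original sizes before running
    :func:`cv_dprime`. Returns the array of null mean-d′ values.
    """
    a = _as_cells_by_trials(resp_a, "resp_a")
    b = _as_cells_by_trials(resp_b, "resp_b")
    pooled = np.concatenate([a, b], axis=1)
    na = a.shape[1]
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(pooled.shape[1])
        fake_a, fake_b = pooled[:, perm[:na]], pooled[:, perm[na:]]
        sub = int(rng.integers(0, 2**31 - 1))
        out[s] = cv_dprime(fake_a, fake_b, seed=sub, **cv_kwargs).mean_dprime
    return out


def scaled_split(n_trials: int, train_frac: float = 0.8) -> int:
    """Training-set size for small repeat counts: floor(frac*n), keeping
    at least 2 train and 2 held-out trials."""
    n_train = int(np.floor(train_frac * n_trials))
    return int(min(max(n_train, 2), n_trials - 2))


def movie_luminance_dprime(
    binned: ResponseMatrix,
    n_iterations: int = 50,
    seed: int = 0,
    *,
    train_frac: float = 0.8,
    min_repeats: int = 4,
    method: str = "mahalanobis",
    luminance_order: tuple[str, str] = ("scotopic", "photopic"),
) -> pd.DataFrame:
    """Per-bin luminance d′ for movie responses.

    For each (movie_id, movie_bin) with both luminance levels and at least
    ``min_repeats`` repeats per level, runs :func:`cv_dprime` between the
    scotopic and photopic repeat sets with a train/test split scaled to the
    repeat count (default 80/20). Bins with too few repeats are skipped with
    a warning. Returns a tidy DataFrame (movie_id, movie_bin, dprime,
    sd_dprime, n_repeats); a per-movie summary is its mean over bins.
    """
    pairs: dict[tuple, dict[str, np.ndarray]] = {}
    for cond, arr in binned.items():
        if cond.movie_id is None or cond.movie_bin is None or cond.luminance is None:
            continue
        pairs.setdefault((cond.movie_id, cond.movie_bin), {})[cond.luminance] = arr

    rng = np.random.default_rng(seed)
    rows = []
    for (movie_id, movie_bin), lum_map in sorted(pairs.items()):
        if not all(l in lum_map for l in luminance_order):
            continue
        a, b = lum_map[luminance_order[0]], lum_map[luminance_order[1]]
        n = min(a.shape[1], b.shape[1])
        if n < min_repeats:
            warnings.warn(
                f"movie {movie_id!r} bin {movie_bin}: {n} repeats < {min_repeats}; skipped",
                stacklevel=2,
            )
            continue
        n_train = scaled_split(n, train_frac)
        sub = int(rng.integers(0, 2**31 - 1))
        res = cv_dprime(
            a, b, n_train=n_train, n_iterations=n_iterations, seed=sub, method=method,
            labels=(movie_id, movie_bin),
        )
        rows.append(
            {
                "movie_id": movie_id,
                "movie_bin": movie_bin,
                "dprime": res.mean_dprime,
                "sd_dprime": res.sd_dprime,
                "n_repeats": n,
                "n_train": n_train,
            }
        )
    return pd.DataFrame(
        rows, columns=["movie_id", "movie_bin", "dprime", "sd_dprime", "n_repeats", "n_train"]
    )


# ---------------------------------------------------------------------------
# scikit-learn estimators


class DDRBasis(TransformerMixin, BaseEstimator):
    """dDR projection as a scikit-learn transformer.

    ``fit(X, y)`` takes trials x cells data with exactly two condition
    labels in ``y``; dU points from the first class to the second (classes
    sorted ascending). ``transform(X)`` returns trials x 2 coordinates in
    the (dU_unit, n1) plane.

    Attributes (after fit): ``dU_raw_``, ``dU_unit_``, ``e1_``, ``n1_``,
    ``classes_``, ``n_features_in_``, ``basis_``.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DDRBasis":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ShapeError("X must be trials x cells with one label per trial")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ParameterError(f"need exactly 2 classes, got {len(classes)}")
        a = X[y == classes[0]].T
        b = X[y == classes[1]].T
        self.basis_ = fit_basis(a, b)
        self.dU_raw_ = self.basis_.dU_raw
        self.dU_unit_ = self.basis_.dU_unit
        self.e1_ = self.basis_.e1
        self.n1_ = self.basis_.n1
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "basis_"):
            raise RuntimeError("DDRBasis is not fitted")
        X = np.asarray(X, dtype=float)
        return project(X.T, self.basis_).T


class DPrimeDecoder(BaseEstimator):
    """Cross-validated dDR d′ as a scikit-learn estimator.

    ``fit(X, y)`` runs the hold-out d′ procedure between the two classes in
    ``y`` (trials x cells ``X``) and stores ``mean_dprime_``,
    ``per_iteration_dprime_``, ``sd_dprime_`` and the full ``result_``.
    ``score(X, y)`` refits on the given data and returns the mean d′.
    """

    def __init__(
        self,
        n_train: int = 40,
        n_iterations: int = 50,
        n_test: int | None = None,
        method: str = "mahalanobis",
        cov_source: str = "test",
        random_state: int = 0,
    ) -> None:
        self.n_train = n_train
        self.n_iterations = n_iterations
        self.n_test = n_test
        self.method = method
        self.cov_source = cov_source
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DPrimeDecoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ParameterError(f"need exactly 2 classes, got {len(classes)}")
        res = cv_dprime(
            X[y == classes[0]].T,
            X[y == classes[1]].T,
            n_train=self.n_train,
            n_iterations=self.n_iterations,
            seed=self.random_state,
            n_test=self.n_test,
            method=self.method,
            cov_source=self.cov_source,
            labels=tuple(classes),
        )
        self.result_ = res
        self.classes_ = classes
        self.mean_dprime_ = res.mean_dprime
        self.sd_dprime_ = res.sd_dprime
        self.per_iteration_dprime_ = res.per_iteration_dprime
        self.n_features_in_ = X.shape[1]
        return self

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return self.fit(X, y).mean_dprime_
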