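"""Flat analysis configuration with YAML round-trip and a stable hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml

from .errors import ParameterError


@dataclass
class Config:
    """Tunable analysis parameters (units in field names).

    Windowing: ``baseline_ms`` pre-onset baseline for ΔF/F; the response
    window ``response_start_ms``/``response_end_ms`` (frame centers,
    half-open); ``movie_bin_ms`` for natural-movie time bins.
    QC: ``skew_threshold`` on raw-trace sample skewness and ``p_threshold``
    for the evoked-response t test.
    Cross-validation: ``n_train`` trials per condition for basis fitting and
    ``n_iterations`` hold-out repeats.
    Formula variants: ``dprime_method`` in {mahalanobis, raw_quadratic},
    ``log_base`` in {e, 10, 2}, ``overlap_method`` in
    {intersection_over_set, jaccard}.
    """

    baseline_ms: float = 200.0
    response_start_ms: float = 450.0
    response_end_ms: float = 1300.0
    movie_bin_ms: float = 166.0
    skew_threshold: float = 2.0
    p_threshold: float = 0.001
    n_train: int = 40
    n_iterations: int = 50
    dprime_method: str = "mahalanobis"
    log_base: str = "e"
    overlap_method: str = "intersection_over_set"

    def __post_init__(self) -> None:
        if self.dprime_method not in ("mahalanobis", "raw_quadratic"):
            raise ParameterError(f"unknown dprime_method {self.dprime_method!r}")
        if self.log_base not in ("e", "10", "2"):
            raise ParameterError(f"unknown log_base {self.log_base!r}")
        if self.overlap_method not in ("intersection_over_set", "jaccard"):
            raise ParameterError(f"unknown overlap_method {self.overlap_method!r}")

    @property
    def response_window_ms(self) -> tuple[float, float]:
        return (self.response_start_ms, self.response_end_ms)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """First 12 hex digits of the SHA-256 of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
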