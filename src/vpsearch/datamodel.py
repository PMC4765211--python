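"""Core domain types shared by every module.

An expression database is a named feature x sample matrix of log2-normalized
values.  Similarity between profiles is measured by a :class:`Metric` — any
binary function satisfying the triangle inequality — whose default is plain
Euclidean distance, typically applied after PCA reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "VPSearchError",
    "DimensionError",
    "ValidationError",
    "ParameterError",
    "ExpressionMatrix",
    "ProfileVector",
    "Metric",
    "SearchResult",
    "euclidean",
    "vantage_lower_bound",
    "get_metric",
    "register_metric",
    "METRICS",
]


class VPSearchError(Exception):
    """Base class for all errors raised by this package."""


class DimensionError(VPSearchError, ValueError):
    """Vector or matrix dimensions do not line up."""


class ValidationError(VPSearchError, ValueError):
    """Input data violates a construction-time invariant."""


class ParameterError(VPSearchError, ValueError):
    """A user-supplied parameter is out of range."""


def _as_finite_vector(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1:
        raise DimensionError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries (NaN/Inf)")
    return arr


def euclidean(a, b) -> float:
    """L2 distance between two equal-length finite vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise DimensionError(
            f"vectors have mismatched lengths: {a.shape} vs {b.shape}"
        )
    return float(np.linalg.norm(a - b))


def vantage_lower_bound(d_qp: float, d_ps: float) -> float:
    """Lower bound |d(q,p) - d(p,s)| on d(q,s) implied by the triangle inequality.

    For any metric, the distance from a query ``q`` to a record ``s`` seen
    "through" a vantage point ``p`` can never exceed the true distance, which
    is what makes subtree fathoming sound.
    """
    if d_qp < 0 or d_ps < 0:
        raise ParameterError(
            f"distances must be non-negative, got ({d_qp}, {d_ps})"
        )
    return abs(d_qp - d_ps)


@dataclass(frozen=True)
class Metric:
    """A named distance function required to satisfy the metric axioms.

    The contract (non-negativity, symmetry, identity, triangle inequality)
    is not enforceable pointwise at construction; it is validated on sampled
    triples by the test suite.  Anything registered here may be plugged into
    the tree.
    """

    name: str
    fn: Callable[[np.ndarray, np.ndarray], float]

    def __call__(self, a, b) -> float:
        return self.fn(a, b)


METRICS: dict[str, Metric] = {}


def register_metric(metric: Metric) -> Metric:
    if metric.name in METRICS:
        raise ParameterError(f"metric {metric.name!r} already registered")
    METRICS[metric.name] = metric
    return metric


register_metric(Metric("euclidean", euclidean))


def get_metric(name: str) -> Metric:
    try:
        return METRICS[name]
    except KeyError:
        raise ParameterError(
            f"unknown metric {name!r}; available: {sorted(METRICS)}"
        ) from None


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for x in ids:
            (dups if x in seen else seen).add(x)
        raise ValidationError(f"duplicate {what}: {sorted(dups)[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A feature x sample matrix of finite log2 expression values.

    ``values`` has shape ``(n_features, n_samples)`` matching the on-disk
    "Data" orientation.  Non-finite values are rejected outright — the data
    model assumes fully processed input and silent imputation would corrupt
    distances.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.feature_ids = _check_unique(self.feature_ids, "feature ids")
        if len(self.sample_ids) == 0:
            raise ValidationError("sample list must be non-empty")
        if len(self.feature_ids) == 0:
            raise ValidationError("feature list must be non-empty")
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (len(self.feature_ids), len(self.sample_ids))
        if self.values.shape != expected:
            raise DimensionError(
                f"Data shape {self.values.shape} inconsistent with "
                f"{expected[0]} features x {expected[1]} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sample_vector(self, sample_id: str) -> np.ndarray:
        """Column of ``values`` for one sample (copy)."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise ParameterError(f"unknown sample id {sample_id!r}") from None
        return self.values[:, j].copy()

    def vectors(self) -> dict[str, np.ndarray]:
        """Mapping sample id -> expression vector, in sample order."""
        return {
            sid: self.values[:, j].copy()
            for j, sid in enumerate(self.sample_ids)
        }


_SPACE_TAGS = ("raw", "pca")


@dataclass
class ProfileVector:
    """One sample's numeric profile, tagged with the space it lives in.

    ``feature_ids`` is carried for raw-space vectors read from files so they
    can be aligned against a database's feature order; reduced vectors drop
    it (components have no gene identity).
    """

    sample_id: str
    values: np.ndarray
    space_tag: str = "raw"
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = _as_finite_vector(self.values, "profile values")
        if self.space_tag not in _SPACE_TAGS:
            raise ValidationError(
                f"space_tag must be one of {_SPACE_TAGS}, got {self.space_tag!r}"
            )
        if self.feature_ids is not None:
            self.feature_ids = _check_unique(self.feature_ids, "feature ids")
            if len(self.feature_ids) != self.values.size:
                raise DimensionError(
                    f"{len(self.feature_ids)} feature ids for "
                    f"{self.values.size} values"
                )


@dataclass
class SearchResult:
    """Ranked hits plus instrumentation.

    ``hits`` is ascending by distance with ties broken lexicographically by
    sample id; ``n_distance_evals`` counts metric calls made to produce it —
    the hardware-independent cost measure used throughout.
    """

    hits: list[tuple[str, float]]
    n_distance_evals: int

    def __post_init__(self) -> None:
        if self.n_distance_evals < 0:
            raise ValidationError("n_distance_evals must be non-negative")
        ids = [h[0] for h in self.hits]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in hit list")
        dists = [h[1] for h in self.hits]
        for d in dists:
            if not (d >= 0 and math.isfinite(d)):
                raise ValidationError(f"invalid hit distance {d}")
        if any(b < a for a, b in zip(dists, dists[1:])):
            raise ValidationError("hit distances are not non-decreasing")

    @property
    def sample_ids(self) -> list[str]:
        return [h[0] for h in self.hits]

    @property
    def distances(self) -> list[float]:
        return [h[1] for h in self.hits]

    def __len__(self) -> int:
        return len(self.hits)
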