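"""PCA fitting and projection into the reduced search space.

The index stores profiles after projection onto the top principal components
of the database (10 by default); queries are projected with the same fitted
model, never refitted.  Because the components are orthonormal, projection
can only shrink Euclidean distances, so pruning bounds computed in the
reduced space remain valid there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import DimensionError, ExpressionMatrix, ParameterError, ValidationError

__all__ = ["PCAModel", "fit_pca", "transform", "transform_matrix", "variance_report"]

DEFAULT_N_COMPONENTS = 10
#: Above this reduced dimension, tree pruning degrades badly.
DIMENSION_WARN_THRESHOLD = 30

_ORTHO_TOL = 1e-8


@dataclass
class PCAModel:
    """Centering vector, orthonormal components and explained-variance shares.

    ``components`` has shape (n_components, p) with unit-norm, pairwise
    orthogonal rows; ``explained_variance_fraction`` is non-increasing and
    sums to at most 1.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.components = np.asarray(self.components, dtype=np.float64)
        self.explained_variance_fraction = np.asarray(
            self.explained_variance_fraction, dtype=np.float64
        )
        if self.mean.ndim != 1 or self.components.ndim != 2:
            raise DimensionError("mean must be a vector, components a matrix")
        k, p = self.components.shape
        if self.mean.size != p:
            raise DimensionError(
                f"mean length {self.mean.size} != component width {p}"
            )
        if self.explained_variance_fraction.shape != (k,):
            raise DimensionError("one variance fraction required per component")
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(k), atol=_ORTHO_TOL):
            raise ValidationError("components are not orthonormal")
        evf = self.explained_variance_fraction
        if np.any(evf < -1e-12) or evf.sum() > 1 + 1e-9:
            raise ValidationError("variance fractions outside [0, 1] budget")
        if np.any(np.diff(evf) > 1e-12):
            raise ValidationError("variance fractions must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_features(self) -> int:
        return self.components.shape[1]


def fit_pca(matrix: ExpressionMatrix, n_components: int = DEFAULT_N_COMPONENTS) -> PCAModel:
    """Fit PCA by SVD of the mean-centered sample x feature matrix.

    No per-feature scaling is applied — the input is assumed to be already
    normalized log2 expression.  Deterministic: each component's sign is
    fixed so that its largest-magnitude loading is positive.  A constant
    matrix yields all-zero variance fractions rather than an error.
    """
    if n_components < 1:
        raise ParameterError(f"n_components must be >= 1, got {n_components}")
    max_rank = min(matrix.n_features, matrix.n_samples)
    if n_components > max_rank:
        raise ParameterError(
            f"n_components={n_components} exceeds min(n_features, n_samples)={max_rank}"
        )
    if n_components > DIMENSION_WARN_THRESHOLD:
        warnings.warn(
            f"n_components={n_components} > {DIMENSION_WARN_THRESHOLD}: "
            "tree search performance degrades in high dimension",
            stacklevel=2,
        )

    X = matrix.values.T  # samples x features
    mean = X.mean(axis=0)
    Xc = X - mean
    # full_matrices=False keeps only min(n, p) singular triplets.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    components = vt[:n_components].copy()
    if total > 0.0:
        fractions = (s[:n_components] ** 2) / total
    else:
        fractions = np.zeros(n_components)

    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0

    return PCAModel(mean=mean, components=components, explained_variance_fraction=fractions)


def transform(model: PCAModel, vector) -> np.ndarray:
    """Project one raw-space vector: components @ (vector - mean)."""
    v = np.asarray(vector, dtype=np.float64)
    if v.ndim != 1 or v.size != model.n_features:
        raise DimensionError(
            f"vector length {v.size if v.ndim == 1 else v.shape} "
            f"!= model feature count {model.n_features}"
        )
    return model.components @ (v - model.mean)


def transform_matrix(model: PCAModel, values: np.ndarray) -> np.ndarray:
    """Project a (n_features, n_samples) matrix to (n_components, n_samples)."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != model.n_features:
        raise DimensionError(
            f"matrix shape {values.shape} incompatible with "
            f"{model.n_features} model features"
        )
    return model.components @ (values - model.mean[:, None])


def variance_report(model: PCAModel) -> np.ndarray:
    """Cumulative explained-variance fraction after 1, 2, ... components."""
    return np.cumsum(model.explained_variance_fraction)
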