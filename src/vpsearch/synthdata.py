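"""Deterministic synthetic expression databases with known cluster structure.

The generator produces Gaussian clusters separated along a block of
informative features, plus two kinds of planted anomalies: "crossers" drawn
from one cluster's distribution while belonging nominally to another, and
"outliers" displaced far from every cluster along a random direction.  This
mirrors the geometry of a two-cancer-type cohort — two clean clusters, one
cluster-crossing sample and one sample outside both — without requiring any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ExpressionMatrix, ParameterError, ProfileVector, euclidean

__all__ = ["SyntheticSpec", "generate", "prototype_query", "write_labels", "read_labels"]

#: log2-expression values are clamped into this range after generation.
CLAMP_RANGE = (0.0, 20.0)
_BASELINE = 8.0
_OUTLIER_SHIFT_SD = 20.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic database.

    ``cluster_separation`` is the per-informative-feature mean shift between
    adjacent clusters, in units of the within-cluster standard deviation
    ``noise_sd``.  Crossers are sampled from the last cluster's distribution
    but labeled ``"crosser"``; outliers sit ``20 * noise_sd`` (Euclidean)
    from the baseline along a random direction and are labeled ``"outlier"``.
    """

    n_per_cluster: tuple[int, ...] = (50, 50)
    n_features: int = 200
    n_informative: int = 10
    cluster_separation: float = 6.0
    noise_sd: float = 1.0
    n_crossers: int = 1
    n_outliers: int = 1
    seed: int = 17

    def __post_init__(self) -> None:
        self.n_per_cluster = tuple(int(x) for x in self.n_per_cluster)
        if any(x < 0 for x in self.n_per_cluster) or not self.n_per_cluster:
            raise ParameterError("n_per_cluster must be non-negative counts")
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        if not (0 <= self.n_informative <= self.n_features):
            raise ParameterError("n_informative must lie in [0, n_features]")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.n_crossers < 0 or self.n_outliers < 0:
            raise ParameterError("anomaly counts must be >= 0")
        if self.cluster_separation < 0:
            raise ParameterError("cluster_separation must be >= 0")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_cluster) + self.n_crossers + self.n_outliers


def _cluster_mean(spec: SyntheticSpec, c: int) -> np.ndarray:
    """Cluster c's mean: a +/- half-shift sign pattern on informative features.

    Cluster 0 takes -separation/2, cluster 1 +separation/2 on every
    informative feature (adjacent clusters differ by the full separation per
    feature); further clusters get distinct deterministic sign patterns.
    Keeping shifts centered on the baseline means any number of clusters
    stays inside the plausible expression range, unlike stacking clusters
    along a single line.
    """
    mean = np.full(spec.n_features, _BASELINE)
    half = 0.5 * spec.cluster_separation * spec.noise_sd
    if c < 2:
        signs = np.full(spec.n_informative, -1.0 if c == 0 else 1.0)
    else:
        signs = np.where(
            np.random.default_rng(1000 + c).integers(0, 2, spec.n_informative) == 1,
            1.0,
            -1.0,
        )
    mean[: spec.n_informative] += signs * half
    return mean


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Generate a database and its label mapping, deterministically per seed.

    Labels are ``cluster<i>`` for regular members, ``crosser`` and
    ``outlier`` for the planted anomalies.
    """
    rng = np.random.default_rng(spec.seed)
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    labels: dict[str, str] = {}

    for c, count in enumerate(spec.n_per_cluster):
        mean = _cluster_mean(spec, c)
        for i in range(count):
            sid = f"c{c}_s{i:04d}"
            columns.append(mean + rng.normal(0.0, spec.noise_sd, spec.n_features))
            sample_ids.append(sid)
            labels[sid] = f"cluster{c}"

    # Crossers: distribution of the last cluster, nominally not part of it.
    source_mean = _cluster_mean(spec, len(spec.n_per_cluster) - 1)
    for i in range(spec.n_crossers):
        sid = f"cross_{i:03d}"
        columns.append(source_mean + rng.normal(0.0, spec.noise_sd, spec.n_features))
        sample_ids.append(sid)
        labels[sid] = "crosser"

    # Outliers: far from every cluster, spread over all features so the
    # displacement survives clamping to the plausible expression range.  The
    # direction keeps a fixed component toward cluster 0's side of the
    # baseline, so cluster 0 is deterministically the nearest cluster.
    axis = _cluster_mean(spec, 0) - _BASELINE
    axis_norm = np.linalg.norm(axis)
    for i in range(spec.n_outliers):
        sid = f"out_{i:03d}"
        direction = rng.normal(size=spec.n_features)
        if axis_norm > 0:
            a_hat = axis / axis_norm
            perp = direction - (direction @ a_hat) * a_hat
            perp /= np.linalg.norm(perp)
            direction = 0.3 * a_hat + np.sqrt(1 - 0.3**2) * perp
        else:
            direction /= np.linalg.norm(direction)
        mean = np.full(spec.n_features, _BASELINE)
        mean += _OUTLIER_SHIFT_SD * spec.noise_sd * direction
        columns.append(mean + rng.normal(0.0, spec.noise_sd, spec.n_features))
        sample_ids.append(sid)
        labels[sid] = "outlier"

    if not sample_ids:
        raise ParameterError("spec generates zero samples")
    values = np.clip(np.column_stack(columns), *CLAMP_RANGE)
    matrix = ExpressionMatrix(sample_ids=sample_ids, feature_ids=[f"g{j:05d}" for j in range(spec.n_features)], values=values)
    return matrix, labels


def prototype_query(
    matrix: ExpressionMatrix, labels: dict[str, str], cluster: str
) -> ProfileVector:
    """The cluster member nearest (Euclidean) to the cluster's mean vector.

    Ties are broken by lexicographically smaller sample id.  The result is a
    representative query in whatever space ``matrix`` is expressed in.
    """
    members = [sid for sid in matrix.sample_ids if labels.get(sid) == cluster]
    if not members:
        raise ParameterError(f"no samples labeled {cluster!r}")
    cols = {sid: matrix.sample_vector(sid) for sid in members}
    centroid = np.mean(list(cols.values()), axis=0)
    best = min(members, key=lambda sid: (euclidean(cols[sid], centroid), sid))
    return ProfileVector(
        sample_id=best,
        values=cols[best],
        feature_ids=list(matrix.feature_ids),
    )


def write_labels(labels: dict[str, str], path) -> None:
    """Write the label mapping as a two-column sample_id,label CSV."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "label"])
        for sid, label in labels.items():
            writer.writerow([sid, label])


def read_labels(path) -> dict[str, str]:
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["sample_id", "label"]:
            raise ParameterError(f"unexpected label CSV header in {path}: {header}")
        return {row[0]: row[1] for row in reader if row}
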