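"""Readers and writers for the on-disk formats.

Three artifacts are exchanged on disk:

* the expression database — an HDF5 file with root datasets ``Sample``
  (n strings), ``Feature`` (p strings) and ``Data`` (p x n float64 matrix,
  features x samples);
* a query — either the same HDF5 layout with a single sample column, or a
  small CSV (``feature,value`` rows, or one feature-id header row plus one
  value row);
* the persisted index — a versioned HDF5 container holding the metric name,
  the optional PCA model, the tree topology as flat per-node arrays and the
  reduced record vectors.

Readers reject malformed files; nothing is silently repaired.  One caveat is
inherent to the dialect: a square ``Data`` matrix written transposed is
indistinguishable from a valid one.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .datamodel import (
    ExpressionMatrix,
    Metric,
    ProfileVector,
    SearchResult,
    VPSearchError,
    get_metric,
)
from .preprocess import PCAModel, transform
from .vptree import VPNode, VPTree, search_knn

__all__ = [
    "FormatError",
    "VersionError",
    "AmbiguityError",
    "MissingFeatureError",
    "IndexFile",
    "FORMAT_VERSION",
    "read_database",
    "write_database",
    "read_query",
    "align_query",
    "save_index",
    "load_index",
]

FORMAT_VERSION = 1

_STR_DT = h5py.string_dtype(encoding="utf-8")


class FormatError(VPSearchError):
    """File does not conform to the expected on-disk layout."""


class VersionError(FormatError):
    """Index file written with an unsupported format version."""


class AmbiguityError(FormatError):
    """A query file contains more than one sample."""


class MissingFeatureError(VPSearchError):
    """The query lacks features required by the database."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        shown = ", ".join(self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"query is missing database features: {shown}{more}")


def _decode(ds) -> list[str]:
    return [x.decode("utf-8") if isinstance(x, bytes) else str(x) for x in ds[()]]


def read_database(path) -> ExpressionMatrix:
    """Read an expression database from the HDF5 dialect."""
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as e:
        raise FormatError(f"cannot open {path} as HDF5: {e}") from e
    with f:
        for name in ("Sample", "Feature", "Data"):
            if name not in f:
                raise FormatError(f"missing required dataset {name!r} in {path}")
        sample_ids = _decode(f["Sample"])
        feature_ids = _decode(f["Feature"])
        data = np.asarray(f["Data"][()], dtype=np.float64)
    if data.ndim != 2 or data.shape != (len(feature_ids), len(sample_ids)):
        raise FormatError(
            f"'Data' shape {data.shape} inconsistent with "
            f"{len(feature_ids)} features x {len(sample_ids)} samples"
        )
    return ExpressionMatrix(sample_ids=sample_ids, feature_ids=feature_ids, values=data)


def write_database(matrix: ExpressionMatrix, path) -> None:
    """Write an :class:`ExpressionMatrix` in the HDF5 dialect."""
    with h5py.File(path, "w") as f:
        f.create_dataset("Sample", data=np.array(matrix.sample_ids, dtype=object), dtype=_STR_DT)
        f.create_dataset("Feature", data=np.array(matrix.feature_ids, dtype=object), dtype=_STR_DT)
        f.create_dataset("Data", data=matrix.values, dtype=np.float64)


def _read_query_csv(path) -> ProfileVector:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]
    if not rows:
        raise FormatError(f"empty CSV query file: {path}")
    name = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    header = [c.strip() for c in rows[0]]
    try:
        if len(header) == 2 and [h.lower() for h in header] == ["feature", "value"]:
            features = [r[0].strip() for r in rows[1:]]
            values = [float(r[1]) for r in rows[1:]]
        elif len(rows) == 2 and len(rows[0]) == len(rows[1]):
            features = header
            values = [float(c) for c in rows[1]]
        else:
            raise FormatError(
                f"unrecognized CSV query layout in {path}: expected "
                "'feature,value' columns or a feature header plus one value row"
            )
    except (ValueError, IndexError) as e:
        raise FormatError(f"unparsable CSV query {path}: {e}") from e
    return ProfileVector(sample_id=name, values=np.array(values), feature_ids=features)


def read_query(path) -> ProfileVector:
    """Read a query profile from single-sample HDF5 or from CSV.

    Files ending in ``.csv`` are parsed as CSV; anything else must be a
    database-dialect HDF5 file with exactly one sample column.
    """
    if str(path).lower().endswith(".csv"):
        return _read_query_csv(path)
    matrix = read_database(path)
    if matrix.n_samples != 1:
        raise AmbiguityError(
            f"query file {path} contains {matrix.n_samples} samples; exactly one required"
        )
    return ProfileVector(
        sample_id=matrix.sample_ids[0],
        values=matrix.values[:, 0],
        feature_ids=list(matrix.feature_ids),
    )


def align_query(query: ProfileVector, feature_ids: list[str]) -> np.ndarray:
    """Reorder a query's values to a database's feature order.

    Every database feature must be present in the query; extra query
    features are dropped with a warning.
    """
    if query.feature_ids is None:
        raise MissingFeatureError(list(feature_ids))
    pos = {fid: i for i, fid in enumerate(query.feature_ids)}
    missing = [fid for fid in feature_ids if fid not in pos]
    if missing:
        raise MissingFeatureError(missing)
    extra = len(pos) - len(feature_ids)
    if extra > 0:
        warnings.warn(
            f"query has {extra} feature(s) absent from the database; dropped",
            stacklevel=2,
        )
    idx = np.array([pos[fid] for fid in feature_ids], dtype=np.intp)
    return query.values[idx]


@dataclass
class IndexFile:
    """A fully built, persistable search index.

    Couples the tree with the reduced vectors it references, the metric, the
    optional PCA model used to reduce queries, and the database feature
    order needed to align raw queries.
    """

    tree: VPTree
    metric_name: str
    feature_ids: list[str]
    pca_model: PCAModel | None = None
    format_version: int = FORMAT_VERSION

    @classmethod
    def build(
        cls,
        matrix: ExpressionMatrix,
        n_components: int | None = 10,
        metric_name: str = "euclidean",
        seed: int = 0,
    ) -> "IndexFile":
        """Build an index from a database: optional PCA, then the tree."""
        from .preprocess import fit_pca
        from .vptree import build_tree

        metric = get_metric(metric_name)
        pca_model = None
        values = matrix.values
        if n_components is not None:
            pca_model = fit_pca(matrix, n_components=n_components)
            # Reduce each column with the same matvec the query path uses so
            # a record queried against itself lands at distance exactly 0.
            values = np.column_stack(
                [transform(pca_model, values[:, j]) for j in range(matrix.n_samples)]
            )
        records = {sid: values[:, j] for j, sid in enumerate(matrix.sample_ids)}
        tree = build_tree(records, metric, seed=seed)
        return cls(
            tree=tree,
            metric_name=metric_name,
            feature_ids=list(matrix.feature_ids),
            pca_model=pca_model,
        )

    def reduce_query(self, query: ProfileVector) -> np.ndarray:
        """Align a raw query to the index features and project it if needed."""
        if query.space_tag == "pca":
            return query.values
        vec = align_query(query, self.feature_ids)
        if self.pca_model is not None:
            vec = transform(self.pca_model, vec)
        return vec

    def search(
        self,
        query: ProfileVector,
        k: int = 10,
        exclude_self: bool = False,
        **kwargs,
    ) -> SearchResult:
        vec = self.reduce_query(query)
        exclude_id = query.sample_id if exclude_self else None
        return search_knn(self.tree, vec, k=k, exclude_id=exclude_id, **kwargs)


def _serialize_tree(root: VPNode | None, sample_order: dict[str, int]):
    """Flatten the tree into parallel preorder arrays (-1 = absent child)."""
    vantage, mu, left, right = [], [], [], []
    if root is None:
        return (np.array([], dtype=np.int64),) * 3 + (np.array([], dtype=np.float64),)
    stack = [(root, -1, None)]  # (node, parent array index, side)
    while stack:
        node, pidx, side = stack.pop()
        idx = len(vantage)
        vantage.append(sample_order[node.vantage_id])
        mu.append(np.nan if node.mu is None else float(node.mu))
        left.append(-1)
        right.append(-1)
        if pidx >= 0:
            (left if side == "left" else right)[pidx] = idx
        if node.right is not None:
            stack.append((node.right, idx, "right"))
        if node.left is not None:
            stack.append((node.left, idx, "left"))
    return (
        np.array(vantage, dtype=np.int64),
        np.array(left, dtype=np.int64),
        np.array(right, dtype=np.int64),
        np.array(mu, dtype=np.float64),
    )


def save_index(index: IndexFile, path) -> None:
    """Persist an index as a versioned HDF5 container."""
    sample_ids = list(index.tree.vectors.keys())
    order = {sid: i for i, sid in enumerate(sample_ids)}
    vantage, left, right, mu = _serialize_tree(index.tree.root, order)
    dim = index.tree.dim or 0
    data = np.empty((len(sample_ids), dim), dtype=np.float64)
    for i, sid in enumerate(sample_ids):
        data[i] = index.tree.vectors[sid]

    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = index.format_version
        meta.attrs["metric_name"] = index.metric_name
        meta.attrs["rng_seed"] = index.tree.rng_seed
        tree = f.create_group("tree")
        tree.create_dataset("vantage", data=vantage)
        tree.create_dataset("mu", data=mu)
        tree.create_dataset("left", data=left)
        tree.create_dataset("right", data=right)
        vectors = f.create_group("vectors")
        vectors.create_dataset("data", data=data)
        vectors.create_dataset(
            "sample_ids", data=np.array(sample_ids, dtype=object), dtype=_STR_DT
        )
        vectors.create_dataset(
            "feature_ids", data=np.array(index.feature_ids, dtype=object), dtype=_STR_DT
        )
        if index.pca_model is not None:
            pca = f.create_group("pca")
            pca.create_dataset("mean", data=index.pca_model.mean)
            pca.create_dataset("components", data=index.pca_model.components)
            pca.create_dataset(
                "explained_variance",
                data=index.pca_model.explained_variance_fraction,
            )


def _deserialize_tree(vantage, mu, left, right, sample_ids) -> VPNode | None:
    if len(vantage) == 0:
        return None
    nodes = [
        VPNode(
            vantage_id=sample_ids[vantage[i]],
            mu=None if np.isnan(mu[i]) else float(mu[i]),
        )
        for i in range(len(vantage))
    ]
    for i, node in enumerate(nodes):
        if left[i] >= 0:
            node.left = nodes[left[i]]
        if right[i] >= 0:
            node.right = nodes[right[i]]
    return nodes[0]  # preorder: the root is written first


def load_index(path) -> IndexFile:
    """Load an index written by :func:`save_index`.

    Round-trip guarantee: the loaded index produces bit-identical search
    results (hits, distances, eval counts) to the one that was saved.
    """
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as e:
        raise FormatError(f"cannot open index {path}: {e}") from e
    with f:
        if "meta" not in f or "format_version" not in f["meta"].attrs:
            raise FormatError(f"{path} is not an index file (no meta/format_version)")
        version = int(f["meta"].attrs["format_version"])
        if version != FORMAT_VERSION:
            raise VersionError(
                f"index format version {version} unsupported (expected {FORMAT_VERSION})"
            )
        for member in ("tree", "vectors"):
            if member not in f:
                raise FormatError(f"index file {path} lacks the {member!r} group")
        metric_name = str(f["meta"].attrs["metric_name"])
        rng_seed = int(f["meta"].attrs.get("rng_seed", 0))
        sample_ids = _decode(f["vectors/sample_ids"])
        feature_ids = _decode(f["vectors/feature_ids"])
        data = np.asarray(f["vectors/data"][()], dtype=np.float64)
        vantage = np.asarray(f["tree/vantage"][()], dtype=np.int64)
        mu = np.asarray(f["tree/mu"][()], dtype=np.float64)
        left = np.asarray(f["tree/left"][()], dtype=np.int64)
        right = np.asarray(f["tree/right"][()], dtype=np.int64)
        pca_model = None
        if "pca" in f:
            pca_model = PCAModel(
                mean=f["pca/mean"][()],
                components=f["pca/components"][()],
                explained_variance_fraction=f["pca/explained_variance"][()],
            )

    if data.shape[0] != len(sample_ids):
        raise FormatError("vector matrix row count does not match sample ids")
    root = _deserialize_tree(vantage, mu, left, right, sample_ids)
    vectors = {sid: data[i].copy() for i, sid in enumerate(sample_ids)}
    tree = VPTree(root=root, metric=get_metric(metric_name), vectors=vectors, rng_seed=rng_seed)
    return IndexFile(
        tree=tree,
        metric_name=metric_name,
        feature_ids=feature_ids,
        pca_model=pca_model,
        format_version=version,
    )
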