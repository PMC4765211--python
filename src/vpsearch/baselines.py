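"""Reference search methods and the hardware-independent scaling benchmark.

``brute_force_knn`` is the exactness oracle: a full scan whose output every
tree search must reproduce bit-for-bit.  The KD-tree comparator wraps
scipy's exact implementation (Euclidean only) for cross-checking.  The
benchmark reports mean distance-evaluation counts rather than wall-clock
time, which captures the same algorithmic scaling without depending on the
machine; wall-clock is emitted as informational output only.
"""

from __future__ import annotations

import math
import time
from bisect import insort
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .datamodel import DimensionError, Metric, ParameterError, SearchResult, get_metric
from .synthdata import SyntheticSpec, generate
from .vptree import build_tree, search_knn

__all__ = [
    "BenchmarkRecord",
    "brute_force_knn",
    "kd_knn",
    "run_scaling_benchmark",
    "benchmark_to_csv",
]


def brute_force_knn(
    records: Mapping[str, np.ndarray],
    metric: Metric,
    query,
    k: int,
    exclude_id: str | None = None,
) -> SearchResult:
    """Exact k-NN by full scan; always evaluates exactly n distances.

    Ranking and tie-breaking (ascending distance, then lexicographic sample
    id) are identical to the tree search — this is the oracle all exactness
    tests compare against.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    q = np.asarray(query, dtype=np.float64)
    best: list[tuple[float, str]] = []
    n = 0
    for sid, vec in records.items():
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != q.shape:
            raise DimensionError(
                f"record {sid!r} has shape {vec.shape}, query {q.shape}"
            )
        d = metric(q, vec)
        n += 1
        if exclude_id is not None and d == 0.0 and sid == exclude_id:
            continue
        if len(best) == k and (d, sid) >= best[-1]:
            continue
        insort(best, (d, sid))
        if len(best) > k:
            best.pop()
    return SearchResult(hits=[(sid, d) for d, sid in best], n_distance_evals=n)


def kd_knn(records: Mapping[str, np.ndarray], query, k: int) -> SearchResult:
    """Exact k-NN via scipy's KD-tree (Euclidean only); comparator, not oracle.

    scipy does not expose its internal distance-evaluation count, so the
    result reports 0 evaluations; ties are re-broken lexicographically to
    match the package convention.
    """
    ids = list(records.keys())
    data = np.vstack([records[sid] for sid in ids])
    tree = cKDTree(data)
    k_eff = min(k, len(ids))
    dist, idx = tree.query(np.asarray(query, dtype=np.float64), k=k_eff)
    dist = np.atleast_1d(dist)
    idx = np.atleast_1d(idx)
    hits = sorted((float(d), ids[i]) for d, i in zip(dist, idx))
    return SearchResult(hits=[(sid, d) for d, sid in hits], n_distance_evals=0)


@dataclass(frozen=True)
class BenchmarkRecord:
    """Mean per-query distance-evaluation cost of one method at one size."""

    n: int
    dim: int
    method: str  # "vp", "kd" or "bf"
    mean_distance_evals: float
    n_queries: int
    seed: int
    mean_wall_ms: float = 0.0  # informational only; not a comparison surface


_BENCH_CLUSTERS = 20


def _cluster_sizes(total: int, n_clusters: int) -> tuple[int, ...]:
    per = total // n_clusters
    if per == 0:
        return (total,)
    sizes = [per] * (n_clusters - 1)
    sizes.append(total - per * (n_clusters - 1))
    return tuple(sizes)


def _clustered_instance(n: int, dim: int, n_queries: int, seed: int):
    """Clustered database of size n plus queries drawn from the same mixture."""

    def spec(total: int, s: int) -> SyntheticSpec:
        return SyntheticSpec(
            n_per_cluster=_cluster_sizes(total, _BENCH_CLUSTERS),
            n_features=dim,
            n_informative=dim,
            cluster_separation=6.0,
            noise_sd=1.0,
            n_crossers=0,
            n_outliers=0,
            seed=s,
        )

    matrix, _ = generate(spec(n, seed))
    queries, _ = generate(spec(n_queries, seed + 1))
    return matrix.vectors(), [queries.values[:, j] for j in range(queries.n_samples)]


def run_scaling_benchmark(
    sizes: list[int],
    dim: int = 10,
    n_queries: int = 100,
    seed: int = 0,
    k: int = 1,
    methods: tuple[str, ...] = ("bf", "kd", "vp"),
    cross_check: bool = True,
) -> list[BenchmarkRecord]:
    """Measure mean distance evaluations per query for each method and size.

    Uses clustered synthetic data in ``dim`` dimensions (matching the
    low-dimensional regime the tree is designed for).  With ``cross_check``
    on, every instance asserts that all requested methods return identical
    hit lists.  Deterministic given ``seed``.
    """
    if any(b <= a for a, b in zip(sizes, sizes[1:])) or any(s < 1 for s in sizes):
        raise ParameterError("sizes must be positive and strictly ascending")
    unknown = set(methods) - {"bf", "kd", "vp"}
    if unknown:
        raise ParameterError(f"unknown benchmark methods: {sorted(unknown)}")

    metric = get_metric("euclidean")
    out: list[BenchmarkRecord] = []
    for n in sizes:
        records, queries = _clustered_instance(n, dim, n_queries, seed + 7919 * n)
        results: dict[str, list[SearchResult]] = {}
        timings: dict[str, float] = {}
        if "vp" in methods:
            tree = build_tree(records, metric, seed=seed)
            t0 = time.perf_counter()
            results["vp"] = [search_knn(tree, q, k=k) for q in queries]
            timings["vp"] = time.perf_counter() - t0
        if "bf" in methods:
            t0 = time.perf_counter()
            results["bf"] = [brute_force_knn(records, metric, q, k=k) for q in queries]
            timings["bf"] = time.perf_counter() - t0
        if "kd" in methods:
            t0 = time.perf_counter()
            results["kd"] = [kd_knn(records, q, k=k) for q in queries]
            timings["kd"] = time.perf_counter() - t0

        if cross_check and len(results) > 1:
            ref_name = next(iter(results))
            for name, res in results.items():
                for a, b in zip(results[ref_name], res):
                    if a.sample_ids != b.sample_ids or not np.allclose(
                        a.distances, b.distances, rtol=1e-9, atol=1e-9
                    ):
                        raise AssertionError(
                            f"method {name} disagrees with {ref_name} at n={n}"
                        )

        for name, res in results.items():
            if name == "bf":
                mean_evals = float(n)  # full scan, by construction
            elif name == "kd":
                mean_evals = math.nan  # scipy does not expose its counter
            else:
                mean_evals = float(np.mean([r.n_distance_evals for r in res]))
            out.append(
                BenchmarkRecord(
                    n=n,
                    dim=dim,
                    method=name,
                    mean_distance_evals=mean_evals,
                    n_queries=n_queries,
                    seed=seed,
                    mean_wall_ms=1000.0 * timings[name] / max(1, n_queries),
                )
            )
    return out


def benchmark_to_csv(records: list[BenchmarkRecord]) -> str:
    """Render benchmark records as the CSV report interface."""
    lines = ["n,dim,method,mean_distance_evals,n_queries,seed"]
    for r in records:
        evals = "" if math.isnan(r.mean_distance_evals) else repr(r.mean_distance_evals)
        lines.append(f"{r.n},{r.dim},{r.method},{evals},{r.n_queries},{r.seed}")
    return "\n".join(lines) + "\n"
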