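"""Vantage-point tree: construction and exact pruned k-nearest-neighbor search.

Each node stores one record (the vantage point ``p``) together with the
median distance ``mu`` from ``p`` to the remaining records of its subtree
set.  Records closer than ``mu`` go to the left subtree, records at or
beyond ``mu`` to the right.  At query time the triangle inequality lets the
search fathom (discard) whole subtrees that provably cannot contain a record
closer than the current best radius ``tau``:

* left subtree fathomed when  d(p,q) >= mu + tau   (everything in it is
  strictly farther than tau from q);
* right subtree fathomed when d(p,q) + tau < mu    (likewise).

The right-side test is deliberately strict so that records at distance
exactly ``tau`` are never discarded; this keeps results bit-identical to a
brute-force scan even under distance ties, where the lexicographic id
tie-break may prefer a record at the boundary.

Search results are exact — any divergence from the brute-force oracle is a
defect, never an approximation.
"""

from __future__ import annotations

import enum
import math
from bisect import insort
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .datamodel import (
    DimensionError,
    Metric,
    ParameterError,
    SearchResult,
    ValidationError,
)

__all__ = [
    "VPNode",
    "VPTree",
    "SearchState",
    "FathomEvent",
    "PruneDecision",
    "build_tree",
    "select_median",
    "search_knn",
    "prune_decision",
]

_INF = math.inf


@dataclass
class VPNode:
    """One tree node: vantage record id, median radius, children.

    ``mu`` is ``None`` at leaves (no other records were left to split).
    Invariant: every record in ``left`` is strictly closer than ``mu`` to the
    vantage record, every record in ``right`` is at distance >= ``mu``.
    """

    vantage_id: str
    mu: float | None = None
    left: "VPNode | None" = None
    right: "VPNode | None" = None

    def iter_ids(self) -> Iterator[str]:
        """All record ids in this subtree (preorder)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node.vantage_id
            if node.right is not None:
                stack.append(node.right)
            if node.left is not None:
                stack.append(node.left)

    def subtree_size(self) -> int:
        return sum(1 for _ in self.iter_ids())


@dataclass
class VPTree:
    """The metric index: root node plus the record vectors it refers to."""

    root: VPNode | None
    metric: Metric
    vectors: dict[str, np.ndarray]
    rng_seed: int
    build_distance_evals: int = 0

    @property
    def n(self) -> int:
        return len(self.vectors)

    @property
    def dim(self) -> int | None:
        for v in self.vectors.values():
            return int(v.size)
        return None


class PruneDecision(enum.Enum):
    SEARCH_LEFT_ONLY = "search_left_only"
    SEARCH_RIGHT_ONLY = "search_right_only"
    SEARCH_BOTH = "search_both"

    @property
    def search_left(self) -> bool:
        return self is not PruneDecision.SEARCH_RIGHT_ONLY

    @property
    def search_right(self) -> bool:
        return self is not PruneDecision.SEARCH_LEFT_ONLY


def prune_decision(d_pq: float, mu: float, tau: float) -> PruneDecision:
    """Decide which subtrees of a node must still be searched.

    ``d_pq`` is the query's distance to the node's vantage record, ``mu`` the
    node's median radius and ``tau`` the current best (k-th best) distance,
    +inf while fewer than k candidates are known.  A fathomed subtree
    provably contains no record strictly closer than ``tau``.
    """
    if d_pq < 0 or mu < 0 or tau < 0:
        raise ParameterError("prune_decision arguments must be non-negative")
    fathom_left = d_pq >= mu + tau
    # Strict comparison: a record at distance exactly tau must stay reachable
    # so that lexicographic tie-breaking matches the brute-force oracle.
    fathom_right = d_pq + tau < mu
    if fathom_left and fathom_right:  # impossible for tau >= 0; guard anyway
        raise AssertionError("both subtrees fathomed — broken invariant")
    if fathom_left:
        return PruneDecision.SEARCH_RIGHT_ONLY
    if fathom_right:
        return PruneDecision.SEARCH_LEFT_ONLY
    return PruneDecision.SEARCH_BOTH


def select_median(distances) -> float:
    """Lower median of a non-empty multiset, in expected linear time.

    Returns the element of rank ceil(m/2) (1-based) of the sorted values, so
    the result is always an attained distance.
    """
    arr = np.asarray(distances, dtype=np.float64)
    if arr.size == 0:
        raise ParameterError("median of empty multiset is undefined")
    k = (arr.size - 1) // 2
    return float(np.partition(arr, k)[k])


def _validate_records(records: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    dim = None
    for sid, vec in records.items():
        arr = np.asarray(vec, dtype=np.float64)
        if arr.ndim != 1:
            raise DimensionError(f"record {sid!r} is not a vector")
        if dim is None:
            dim = arr.size
        elif arr.size != dim:
            raise DimensionError(
                f"record {sid!r} has length {arr.size}, expected {dim}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"record {sid!r} contains non-finite values")
        out[str(sid)] = arr
    return out


def build_tree(records: Mapping[str, np.ndarray], metric: Metric, seed: int = 0) -> VPTree:
    """Build a vantage-point tree over ``records``.

    The vantage point of each node is drawn uniformly at random from the
    node's record set (seeded, so identical inputs give identical trees);
    the median split sends records closer than ``mu`` left and the rest
    right.  Runs iteratively with an explicit work stack, so arbitrarily
    deep trees cannot overflow the interpreter stack.
    """
    vectors = _validate_records(records)
    rng = np.random.default_rng(seed)
    tree = VPTree(root=None, metric=metric, vectors=vectors, rng_seed=int(seed))
    ids = list(vectors.keys())
    if not ids:
        return tree

    evals = 0
    # Work items: (id subset, parent node, "left"/"right"/None for root).
    stack: list[tuple[list[str], VPNode | None, str | None]] = [(ids, None, None)]
    while stack:
        subset, parent, side = stack.pop()
        vi = int(rng.integers(len(subset)))
        vantage = subset[vi]
        rest = subset[:vi] + subset[vi + 1 :]
        node = VPNode(vantage_id=vantage)
        if rest:
            vvec = vectors[vantage]
            dists = np.empty(len(rest))
            for i, sid in enumerate(rest):
                dists[i] = metric(vvec, vectors[sid])
            evals += len(rest)
            mu = select_median(dists)
            node.mu = mu
            left_ids = [sid for sid, d in zip(rest, dists) if d < mu]
            right_ids = [sid for sid, d in zip(rest, dists) if d >= mu]
            if left_ids:
                stack.append((left_ids, node, "left"))
            if right_ids:
                stack.append((right_ids, node, "right"))
        if parent is None:
            tree.root = node
        elif side == "left":
            parent.left = node
        else:
            parent.right = node
    tree.build_distance_evals = evals
    return tree


@dataclass
class SearchState:
    """Mutable state of one k-NN search.

    ``best`` holds at most k ``(distance, sample_id)`` candidates in sorted
    order; ``tau`` is the k-th best distance once k candidates are known and
    +inf before that, and only ever shrinks.
    """

    k: int
    best: list[tuple[float, str]] = field(default_factory=list)
    evals: int = 0
    tau_trace: list[float] = field(default_factory=list)

    @property
    def tau(self) -> float:
        if len(self.best) >= self.k:
            return self.best[self.k - 1][0]
        return _INF

    def offer(self, distance: float, sample_id: str) -> None:
        if len(self.best) == self.k and (distance, sample_id) >= self.best[-1]:
            return
        insort(self.best, (distance, sample_id))
        if len(self.best) > self.k:
            self.best.pop()


@dataclass(frozen=True)
class FathomEvent:
    """Audit record: a subtree discarded at a given tau.

    Soundness contract: no record inside ``subtree`` was strictly closer to
    the query than ``tau`` at the moment of fathoming.
    """

    subtree: VPNode
    side: str  # "left" or "right" child of the node that triggered the cut
    tau: float
    d_pq: float
    mu: float


def search_knn(
    tree: VPTree,
    query,
    k: int = 10,
    exclude_id: str | None = None,
    audit: list[FathomEvent] | None = None,
    state_out: list[SearchState] | None = None,
) -> SearchResult:
    """Exact k-nearest-neighbor search with triangle-inequality pruning.

    Returns exactly the k smallest-distance records (all of them if k exceeds
    the database size), ascending, ties broken lexicographically by sample
    id — always identical to a brute-force scan.  ``exclude_id`` drops a
    distance-0 hit whose id matches (self-match suppression).  Pass a list
    as ``audit`` to collect :class:`FathomEvent` records for soundness
    verification, or ``state_out`` to capture the final search state.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if tree.root is None:
        return SearchResult(hits=[], n_distance_evals=0)
    q = np.asarray(query, dtype=np.float64)
    dim = tree.dim
    if q.ndim != 1 or q.size != dim:
        raise DimensionError(
            f"query has shape {q.shape}, tree vectors have length {dim}"
        )

    metric = tree.metric
    vectors = tree.vectors
    state = SearchState(k=k)

    # Stack entries carry the parent's (d_pq, mu, side) so that a subtree
    # pushed before tau shrank can still be fathomed when popped.
    stack: list[tuple[VPNode, float | None, float | None, str | None]] = [
        (tree.root, None, None, None)
    ]
    while stack:
        node, pd, pmu, side = stack.pop()
        tau = state.tau
        if pd is not None:
            # Re-check the fathoming condition with the current (smaller) tau.
            if side == "left" and pd >= pmu + tau:
                if audit is not None:
                    audit.append(FathomEvent(node, "left", tau, pd, pmu))
                continue
            if side == "right" and pd + tau < pmu:
                if audit is not None:
                    audit.append(FathomEvent(node, "right", tau, pd, pmu))
                continue

        d_pq = metric(q, vectors[node.vantage_id])
        state.evals += 1
        if not (exclude_id is not None and d_pq == 0.0 and node.vantage_id == exclude_id):
            state.offer(d_pq, node.vantage_id)
        state.tau_trace.append(state.tau)

        if node.mu is None:
            continue
        tau = state.tau
        decision = prune_decision(d_pq, node.mu, tau)
        near_left = d_pq < node.mu
        children = []  # pushed far-side first so the near side is popped first
        order = ("right", "left") if near_left else ("left", "right")
        for child_side in order:
            child = node.left if child_side == "left" else node.right
            if child is None:
                continue
            searched = (
                decision.search_left if child_side == "left" else decision.search_right
            )
            if searched:
                children.append((child, d_pq, node.mu, child_side))
            elif audit is not None:
                audit.append(FathomEvent(child, child_side, tau, d_pq, node.mu))
        stack.extend(children)

    if state_out is not None:
        state_out.append(state)
    hits = [(sid, d) for d, sid in state.best]
    return SearchResult(hits=hits, n_distance_evals=state.evals)
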