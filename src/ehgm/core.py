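"""Domain types for hypergraph matching problems.

A matching problem asks for an injective map from ``n1`` model vertices
onto ``n2`` observed points (``n1 <= n2``) minimizing a sum of hyperedge
dissimilarity costs.  A degree-``d`` dissimilarity tensor assigns a
nonnegative cost to each (vertex ``d``-tuple, point ``d``-tuple)
correspondence; the full objective is the sum over all tensors and all
in-scope vertex tuples of the cost at the assigned point tuples.

Vertices are indexed 0..n1-1 *in branch order*: the branch-and-bound
solver assigns them in consecutive groups of ``k``.  Vertex tuples are
canonically strictly increasing in this order.  All indices are 0-based
in code; file formats and documentation use 1-based indices, converted
only at the I/O boundary.

This module also provides an exhaustive brute-force solver used as the
ground-truth oracle for the branch-and-bound search.
"""

from __future__ import annotations

import bisect
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Assignment",
    "DissimilarityTensor",
    "MatchingProblem",
    "SolutionPool",
    "count_branch_steps",
    "branch_permutation_count",
    "evaluate_objective",
    "enumerate_assignments",
    "brute_force_solve",
    "dump_problem",
]


@dataclass(frozen=True)
class Assignment:
    """An injective (partial) map from vertices to point indices.

    ``points[v]`` is the point index assigned to vertex ``v``; vertices
    are covered in branch order, so a partial assignment of depth ``s``
    covers exactly vertices ``0..s-1``.
    """

    points: tuple[int, ...]

    def __post_init__(self) -> None:
        pts = tuple(int(p) for p in self.points)
        object.__setattr__(self, "points", pts)
        if len(set(pts)) != len(pts):
            raise ValueError("assignment is not injective: duplicate point index")
        if any(p < 0 for p in pts):
            raise ValueError("point indices must be nonnegative")

    @property
    def depth(self) -> int:
        return len(self.points)

    def is_complete(self, n1: int) -> bool:
        return self.depth == n1

    def extended(self, extra: Sequence[int]) -> "Assignment":
        return Assignment(self.points + tuple(extra))

    def as_dict(self) -> dict[int, int]:
        return dict(enumerate(self.points))


class DissimilarityTensor:
    """Degree-``d`` hyperedge cost function over a sparse vertex scope.

    Costs may be given as a dict keyed by ``(vertex_tuple, point_tuple)``
    (typical for randomly generated test instances) or as a callable
    ``cost(vertex_tuple, point_tuple) -> float`` (typical for geometric
    models, where the table would be huge).  Callable costs are memoized.

    Nonnegativity is a hard contract: the branch-and-bound pruning bound
    (accumulated partial cost) is a valid lower bound only if every cost
    increment is >= 0.  Dict entries are checked at construction; callable
    results are checked at every evaluation.
    """

    def __init__(
        self,
        degree: int,
        scope: Iterable[tuple[int, ...]],
        cost: Mapping[tuple, float] | Callable[[tuple, tuple], float],
        mode: str = "precomputed",
        memoize: bool = True,
    ) -> None:
        if degree < 1:
            raise ValueError("tensor degree must be >= 1")
        if mode not in ("precomputed", "lazy"):
            raise ValueError("mode must be 'precomputed' or 'lazy'")
        self.degree = int(degree)
        self.mode = mode
        scope_t = []
        for vt in scope:
            vt = tuple(int(v) for v in vt)
            if len(vt) != degree:
                raise ValueError(f"scope tuple {vt} has wrong length for degree {degree}")
            if any(a >= b for a, b in zip(vt, vt[1:])):
                raise ValueError(f"vertex tuple {vt} must be strictly increasing in branch order")
            scope_t.append(vt)
        self.scope: tuple[tuple[int, ...], ...] = tuple(sorted(scope_t))
        self._scope_set = frozenset(self.scope)
        if callable(cost):
            self._table = None
            self._fn = cost
            self._memo: dict | None = {} if memoize else None
        else:
            table = {}
            for (vt, pt), c in cost.items():
                c = float(c)
                if not math.isfinite(c) or c < 0.0:
                    raise ValueError(
                        f"dissimilarity cost for {vt}->{pt} is {c}; costs must be finite and >= 0"
                    )
                if tuple(vt) not in self._scope_set:
                    raise ValueError(f"cost entry for out-of-scope vertex tuple {vt}")
                table[(tuple(vt), tuple(pt))] = c
            self._table = table
            self._fn = None
            self._memo = None

    def covers(self, vertex_tuple: tuple[int, ...]) -> bool:
        return vertex_tuple in self._scope_set

    def cost_of(self, vertex_tuple: tuple[int, ...], point_tuple: tuple[int, ...]) -> float:
        if vertex_tuple not in self._scope_set:
            raise KeyError(f"undefined hyperedge cost: vertex tuple {vertex_tuple} not in scope")
        if len(point_tuple) != self.degree or len(set(point_tuple)) != self.degree:
            raise ValueError(f"point tuple {point_tuple} must hold {self.degree} distinct indices")
        if self._table is not None:
            try:
                return self._table[(vertex_tuple, point_tuple)]
            except KeyError:
                raise KeyError(
                    f"undefined hyperedge cost: no entry for {vertex_tuple} -> {point_tuple}"
                ) from None
        if self._memo is not None:
            key = (vertex_tuple, point_tuple)
            c = self._memo.get(key)
            if c is not None:
                return c
        c = float(self._fn(vertex_tuple, point_tuple))
        if not math.isfinite(c) or c < 0.0:
            raise ValueError(
                f"dissimilarity callback returned {c} for {vertex_tuple}->{point_tuple}; "
                "costs must be finite and >= 0"
            )
        if self._memo is not None:
            self._memo[key] = c
        return c


class MatchingProblem:
    """A hypergraph matching instance: sizes, branch size, and tensors.

    Branch ``b`` (0-based, of ``M = n1/k`` branches) assigns vertices
    ``b*k .. b*k+k-1``.  Tensors of degree <= 2k must be mode
    'precomputed' (they steer the branch queues); higher degrees must be
    'lazy' (they are only consulted once enough vertices are committed).
    """

    def __init__(
        self,
        n1: int,
        n2: int,
        k: int,
        tensors: Sequence[DissimilarityTensor],
        vertex_labels: Sequence[str] | None = None,
    ) -> None:
        if n1 < 1 or n2 < 1 or k < 1:
            raise ValueError("n1, n2 and k must be positive")
        if n1 > n2:
            raise ValueError(f"need n1 <= n2, got n1={n1}, n2={n2}")
        count_branch_steps(n1, k)  # raises on indivisibility
        self.n1, self.n2, self.k = int(n1), int(n2), int(k)
        by_degree: dict[int, list[DissimilarityTensor]] = {}
        for t in tensors:
            if t.degree > n1:
                raise ValueError(f"tensor degree {t.degree} exceeds n1={n1}")
            expected = "precomputed" if t.degree <= 2 * k else "lazy"
            if t.mode != expected:
                raise ValueError(
                    f"degree-{t.degree} tensor must be mode '{expected}' for k={k}"
                )
            for vt in t.scope:
                if vt[-1] >= n1:
                    raise ValueError(f"vertex tuple {vt} out of range for n1={n1}")
            by_degree.setdefault(t.degree, []).append(t)
        self.tensors: dict[int, tuple[DissimilarityTensor, ...]] = {
            d: tuple(ts) for d, ts in sorted(by_degree.items())
        }
        if vertex_labels is not None and len(vertex_labels) != n1:
            raise ValueError("vertex_labels must have length n1")
        self.vertex_labels = tuple(vertex_labels) if vertex_labels is not None else None

    @property
    def n_branches(self) -> int:
        return self.n1 // self.k

    def branch_vertices(self, b: int) -> tuple[int, ...]:
        if not 0 <= b < self.n_branches:
            raise IndexError(f"branch index {b} out of range")
        return tuple(range(b * self.k, (b + 1) * self.k))

    @property
    def branches(self) -> tuple[tuple[int, ...], ...]:
        return tuple(self.branch_vertices(b) for b in range(self.n_branches))

    def all_tensors(self) -> Iterator[DissimilarityTensor]:
        for d in sorted(self.tensors):
            yield from self.tensors[d]


class SolutionPool:
    """The ``x`` lowest-cost complete assignments, sorted ascending.

    Ties in cost are broken lexicographically on the point-index tuple;
    an entry equal in cost to the worst retained solution is admitted
    only if lexicographically smaller, keeping pools deterministic.
    """

    def __init__(self, capacity: int) -> None:
        if capacity < 1:
            raise ValueError("pool capacity must be >= 1")
        self.capacity = int(capacity)
        self._entries: list[tuple[float, tuple[int, ...]]] = []

    def offer(self, assignment: Assignment, cost: float) -> bool:
        key = (float(cost), assignment.points)
        if len(self._entries) == self.capacity and key >= self._entries[-1]:
            return False
        if key in self._entries:  # pools hold pairwise distinct assignments
            return False
        bisect.insort(self._entries, key)
        if len(self._entries) > self.capacity:
            self._entries.pop()
        return True

    @property
    def bound(self) -> float:
        """Cost of the worst retained solution; +inf until the pool fills."""
        if len(self._entries) < self.capacity:
            return math.inf
        return self._entries[-1][0]

    @property
    def entries(self) -> list[tuple[Assignment, float]]:
        return [(Assignment(pts), c) for c, pts in self._entries]

    def __len__(self) -> int:
        return len(self._entries)

    def best(self) -> tuple[Assignment, float]:
        if not self._entries:
            raise ValueError("pool is empty")
        c, pts = self._entries[0]
        return Assignment(pts), c


def count_branch_steps(n1: int, k: int) -> int:
    """Number of branch steps M = n1/k; errors unless k divides n1."""
    if n1 < 1 or k < 1:
        raise ValueError("n1 and k must be >= 1")
    if n1 % k != 0:
        raise ValueError(f"branch size must divide vertex count (k={k}, n1={n1})")
    return n1 // k


def branch_permutation_count(n2: int, k: int) -> int:
    """Number of ordered k-tuples of distinct points: n2!/(n2-k)!."""
    if k < 1 or n2 < 1:
        raise ValueError("n2 and k must be >= 1")
    if k > n2:
        raise ValueError(f"branch size k={k} exceeds point count n2={n2}")
    out = 1
    for i in range(k):
        out *= n2 - i
    return out


def evaluate_objective(problem: MatchingProblem, assignment: Assignment) -> float:
    """Full objective: sum over all tensors and in-scope vertex tuples."""
    if not assignment.is_complete(problem.n1):
        raise ValueError(
            f"assignment of depth {assignment.depth} is incomplete for n1={problem.n1}"
        )
    pts = assignment.points
    total = 0.0
    for tensor in problem.all_tensors():
        for vt in tensor.scope:
            pt = tuple(pts[v] for v in vt)
            total += tensor.cost_of(vt, pt)
    return total


def _check_seeds(n1: int, n2: int, seeds: Mapping[int, int] | None) -> dict[int, int]:
    seeds = dict(seeds or {})
    for v, p in seeds.items():
        if not (0 <= v < n1 and 0 <= p < n2):
            raise ValueError(f"seed {v}->{p} out of range (n1={n1}, n2={n2})")
    if len(set(seeds.values())) != len(seeds):
        raise ValueError("conflicting seeds: a point index is used twice")
    return seeds


def enumerate_assignments(
    problem: MatchingProblem, seeds: Mapping[int, int] | None = None
) -> Iterator[Assignment]:
    """Yield every injective completion of ``seeds`` exactly once.

    Enumeration is lexicographic in the point tuple.  Points reserved by
    seeds for later vertices are never offered to free vertices.
    """
    n1, n2 = problem.n1, problem.n2
    seeds = _check_seeds(n1, n2, seeds)
    reserved = set(seeds.values())

    def rec(v: int, chosen: list[int], used: set[int]) -> Iterator[tuple[int, ...]]:
        if v == n1:
            yield tuple(chosen)
            return
        if v in seeds:
            options = [seeds[v]]
        else:
            options = [p for p in range(n2) if p not in used and p not in reserved]
        for p in options:
            if p in used:
                continue
            chosen.append(p)
            used.add(p)
            yield from rec(v + 1, chosen, used)
            used.discard(p)
            chosen.pop()

    for pts in rec(0, [], set()):
        yield Assignment(pts)


def brute_force_solve(
    problem: MatchingProblem,
    seeds: Mapping[int, int] | None = None,
    x: int = 1,
    max_enumeration: int = 1_000_000,
) -> SolutionPool:
    """Exhaustive oracle: the x lowest-cost complete assignments.

    Guarded against large instances; use the branch-and-bound solver for
    anything beyond ~1e6 completions.
    """
    seeds = _check_seeds(problem.n1, problem.n2, seeds)
    s = len(seeds)
    count = 1
    for i in range(problem.n1 - s):
        count *= (problem.n2 - s) - i
    if count > max_enumeration:
        raise ValueError(
            f"enumeration count {count} exceeds guard {max_enumeration}; "
            "use the exact branch-and-bound solver instead"
        )
    pool = SolutionPool(x)
    for assignment in enumerate_assignments(problem, seeds):
        pool.offer(assignment, evaluate_objective(problem, assignment))
    return pool


def dump_problem(problem: MatchingProblem) -> str:
    """Structured-text debug dump of all table-backed tensor entries.

    One line per entry: ``degree  v1..vd -> p1..pd : cost`` with 1-based
    indices (the documented external convention).  Callable tensors are
    summarized by degree and scope size only.
    """
    lines = [f"matching-problem n1={problem.n1} n2={problem.n2} k={problem.k}"]
    for tensor in problem.all_tensors():
        if tensor._table is None:
            lines.append(
                f"tensor degree={tensor.degree} mode={tensor.mode} "
                f"scope={len(tensor.scope)} (callable costs)"
            )
            continue
        for (vt, pt), c in sorted(tensor._table.items()):
            vs = ",".join(str(v + 1) for v in vt)
            ps = ",".join(str(p + 1) for p in pt)
            lines.append(f"{tensor.degree}  {vs} -> {ps} : {c:.12g}")
    return "\n".join(lines) + "\n"
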