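"""Shared test utilities: random instance builders and independent
oracles kept deliberately separate from the package's bookkeeping."""

from __future__ import annotations

import itertools

import numpy as np

from ehgm.core import DissimilarityTensor, MatchingProblem


def random_problem(
    n1: int,
    n2: int,
    k: int,
    degrees,
    rng: np.random.Generator,
    high_degree_scope: int = 5,
) -> MatchingProblem:
    """Random instance with uniform [0, 1) costs stored as plain dicts.

    Degrees 1 and 2 get full scope; higher degrees get a random subset
    of vertex tuples (full tables would be enormous).
    """
    tensors = []
    for d in degrees:
        scope = list(itertools.combinations(range(n1), d))
        if d > 2 and len(scope) > high_degree_scope:
            idx = rng.choice(len(scope), size=high_degree_scope, replace=False)
            scope = [scope[i] for i in sorted(idx)]
        costs = {}
        for vt in scope:
            for pt in itertools.permutations(range(n2), d):
                costs[(vt, pt)] = float(rng.uniform(0.0, 1.0))
        mode = "precomputed" if d <= 2 * k else "lazy"
        tensors.append(DissimilarityTensor(d, scope, costs, mode=mode))
    return MatchingProblem(n1, n2, k, tensors)


def nested_loop_objective(problem: MatchingProblem, points: tuple[int, ...]) -> float:
    """Plain nested-loop evaluation of the matching objective, written
    independently of the tensor bookkeeping: for every degree, iterate
    all strictly-increasing vertex tuples and accumulate the cost of
    the assigned point tuple when the tensor defines it."""
    total = 0.0
    n1 = problem.n1
    for d, tensors in problem.tensors.items():
        for vt in itertools.combinations(range(n1), d):
            pt = tuple(points[v] for v in vt)
            for tensor in tensors:
                if tensor.covers(vt):
                    total += tensor.cost_of(vt, pt)
    return total


def mirror_relabel(points: tuple[int, ...]) -> tuple[int, ...]:
    """Swap the left/right nuclei of every pair (vertices 2q, 2q+1)."""
    out = list(points)
    for q in range(len(points) // 2):
        out[2 * q], out[2 * q + 1] = out[2 * q + 1], out[2 * q]
    return tuple(out)


def single_pair_perturbations(points: tuple[int, ...]):
    """All assignments one 'pair move' away from ``points``: exchanging
    the point tuples of two pairs, or flipping left/right within one."""
    n_pairs = len(points) // 2
    for q in range(n_pairs):
        out = list(points)
        out[2 * q], out[2 * q + 1] = out[2 * q + 1], out[2 * q]
        yield tuple(out)
    for qa in range(n_pairs):
        for qb in range(qa + 1, n_pairs):
            out = list(points)
            out[2 * qa], out[2 * qb] = out[2 * qb], out[2 * qa]
            out[2 * qa + 1], out[2 * qb + 1] = out[2 * qb + 1], out[2 * qa + 1]
            yield tuple(out)
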