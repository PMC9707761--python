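"""Pure 3-D geometry of bilaterally paired nuclei.

A posture is a chain of lateral (left, right) nucleus pairs along the
embryo's body.  The features here quantify local shape — pair widths,
side chord lengths, midpoint spacing, bend and twist angles, and plane
intersection angles — and are the raw material of the matching models.
All of them are invariant under simultaneous rigid motion of the input
nuclei; the signed axial twist additionally flips sign under reflection,
which is what lets a model tell a posture from its mirror image.

Conventions: coordinates in micrometers; angles in degrees; pair
arguments are ordered along the body in *branch order* (posterior to
anterior, tail first); a pair's axis points left to right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CANONICAL_PAIR_NAMES",
    "LabeledPosture",
    "PairFrame",
    "pair_frame",
    "lateral_pair_distance",
    "side_chord_length",
    "pair_distance_ratio",
    "midpoint_distance",
    "side_cosine_similarity",
    "axial_twist_angle",
    "lateral_axial_twist_angle",
    "midpoint_bend_angle",
    "planar_intersection_angle",
    "posture_sum_features",
    "SUM_FEATURE_FAMILIES",
]

# Anterior-to-posterior pair naming; Q (the neuroblast pair) is present
# only in late development (post-Q stage, 11 pairs / 22 nuclei).
CANONICAL_PAIR_NAMES = ("H0", "H1", "H2", "V1", "V2", "V3", "V4", "V5", "Q", "V6", "T")

_DEGENERACY_TOL = 1e-12


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("coordinates must be finite")
    return v


def _pair(pair) -> tuple[np.ndarray, np.ndarray]:
    left, right = pair
    return _as_vec(left), _as_vec(right)


@dataclass(frozen=True)
class LabeledPosture:
    """Named lateral pairs, anterior to posterior, at one time point.

    ``names`` must be an order-respecting subsequence of the canonical
    eleven pair names (full embryos have 10 pre-Q or 11 post-Q pairs;
    reduced synthetic worms may carry fewer).  ``time`` is the
    normalized developmental time in [0, 1].
    """

    names: tuple[str, ...]
    left: np.ndarray  # (n_pairs, 3) micrometers
    right: np.ndarray
    time: float

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        object.__setattr__(self, "names", tuple(self.names))
        n = len(self.names)
        if n < 3:
            raise ValueError("a posture needs at least 3 pairs")
        if left.shape != (n, 3) or right.shape != (n, 3):
            raise ValueError("left/right must be (n_pairs, 3) coordinate arrays")
        if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
            raise ValueError("coordinates must be finite")
        idx = []
        for name in self.names:
            if name not in CANONICAL_PAIR_NAMES:
                raise ValueError(f"unknown pair name {name!r}")
            idx.append(CANONICAL_PAIR_NAMES.index(name))
        if any(a >= b for a, b in zip(idx, idx[1:])):
            raise ValueError("pair names must run anterior to posterior without repeats")
        nuclei = np.vstack([left, right])
        d = np.linalg.norm(nuclei[:, None, :] - nuclei[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.min(d) <= 0.0:
            raise ValueError("no two nuclei may coincide")

    @property
    def n_pairs(self) -> int:
        return len(self.names)

    def branch_pairs(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """Pairs in branch (posterior-to-anterior, tail-first) order."""
        return [
            (self.names[i], self.left[i], self.right[i])
            for i in range(self.n_pairs - 1, -1, -1)
        ]

    def branch_nuclei(self) -> np.ndarray:
        """(2 * n_pairs, 3) nuclei in branch-vertex order (L then R per pair)."""
        out = []
        for _, lft, rgt in self.branch_pairs():
            out.append(lft)
            out.append(rgt)
        return np.array(out)


@dataclass(frozen=True)
class PairFrame:
    """Local frame of a pair: midpoint, unit left-to-right axis, and unit
    forward direction toward the next pair's midpoint."""

    midpoint: np.ndarray
    axis: np.ndarray
    forward: np.ndarray


def pair_frame(pair, next_pair) -> PairFrame:
    l0, r0 = _pair(pair)
    l1, r1 = _pair(next_pair)
    mid0 = 0.5 * (l0 + r0)
    mid1 = 0.5 * (l1 + r1)
    axis = r0 - l0
    na = np.linalg.norm(axis)
    if na <= _DEGENERACY_TOL:
        raise ValueError("degenerate pair: zero-length left-right axis")
    fwd = mid1 - mid0
    nf = np.linalg.norm(fwd)
    if nf <= _DEGENERACY_TOL:
        raise ValueError("degenerate frame: coincident midpoints")
    return PairFrame(mid0, axis / na, fwd / nf)


def lateral_pair_distance(left, right) -> float:
    """Euclidean distance between the two nuclei of a lateral pair."""
    return float(np.linalg.norm(_as_vec(left) - _as_vec(right)))


def side_chord_length(a, b) -> float:
    """Chord length between successive nuclei along one side."""
    return float(np.linalg.norm(_as_vec(a) - _as_vec(b)))


def pair_distance_ratio(pair_i, pair_j) -> float:
    """Width ratio of two pairs, the (more posterior) first argument in
    the numerator.  Errors on a zero-width denominator pair."""
    li, ri = _pair(pair_i)
    lj, rj = _pair(pair_j)
    dj = float(np.linalg.norm(lj - rj))
    if dj <= _DEGENERACY_TOL:
        raise ValueError("degenerate pair: zero lateral distance in denominator")
    return float(np.linalg.norm(li - ri)) / dj


def midpoint_distance(pair_i, pair_j) -> float:
    li, ri = _pair(pair_i)
    lj, rj = _pair(pair_j)
    return float(np.linalg.norm(0.5 * (li + ri) - 0.5 * (lj + rj)))


def side_cosine_similarity(pair_i, pair_j) -> float:
    """Cosine between the left-side chord and the right-side chord of the
    same body segment, in [-1, 1]."""
    li, ri = _pair(pair_i)
    lj, rj = _pair(pair_j)
    cl = lj - li
    cr = rj - ri
    nl, nr = np.linalg.norm(cl), np.linalg.norm(cr)
    if nl <= _DEGENERACY_TOL or nr <= _DEGENERACY_TOL:
        raise ValueError("degenerate segment: zero-length side chord")
    return float(np.clip(np.dot(cl, cr) / (nl * nr), -1.0, 1.0))


def axial_twist_angle(pair_i, pair_j) -> float:
    """Signed dihedral angle (degrees, (-180, 180]) between the two pair
    axes about the midpoint-to-midpoint chord.

    Zero for coplanar untwisted successive pairs; flips sign under
    mirror reflection of all nuclei.
    """
    li, ri = _pair(pair_i)
    lj, rj = _pair(pair_j)
    ai = ri - li
    aj = rj - lj
    u = 0.5 * (lj + rj) - 0.5 * (li + ri)
    nu = np.linalg.norm(u)
    if np.linalg.norm(ai) <= _DEGENERACY_TOL or np.linalg.norm(aj) <= _DEGENERACY_TOL:
        raise ValueError("degenerate pair axis")
    if nu <= _DEGENERACY_TOL:
        raise ValueError("degenerate midpoint chord")
    u = u / nu
    ai = ai / np.linalg.norm(ai)
    aj = aj / np.linalg.norm(aj)
    y = float(np.dot(np.cross(ai, aj), u))
    x = float(np.dot(ai, aj) - np.dot(ai, u) * np.dot(aj, u))
    phi = math.degrees(math.atan2(y, x))
    if phi <= -180.0:
        phi += 360.0
    return phi


def lateral_axial_twist_angle(pair_i, pair_j) -> float:
    """Unsigned angle (degrees, [0, 180]) between the two pair axes."""
    li, ri = _pair(pair_i)
    lj, rj = _pair(pair_j)
    ai = ri - li
    aj = rj - lj
    ni, nj = np.linalg.norm(ai), np.linalg.norm(aj)
    if ni <= _DEGENERACY_TOL or nj <= _DEGENERACY_TOL:
        raise ValueError("degenerate pair axis")
    c = np.clip(np.dot(ai, aj) / (ni * nj), -1.0, 1.0)
    return math.degrees(math.acos(c))


def midpoint_bend_angle(pair_i, pair_j, pair_k) -> float:
    """Interior angle (degrees, [0, 180]) at the middle pair's midpoint,
    over three successive pair midpoints; 180 for a locally straight
    body, decreasing with local bending."""
    mids = []
    for pair in (pair_i, pair_j, pair_k):
        lft, rgt = _pair(pair)
        mids.append(0.5 * (lft + rgt))
    u = mids[0] - mids[1]
    v = mids[2] - mids[1]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= _DEGENERACY_TOL or nv <= _DEGENERACY_TOL:
        raise ValueError("coincident midpoints")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(c))


def _fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Total-least-squares plane normal of >= 3 points (smallest
    principal axis); errors if the points are (near-)collinear."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= _DEGENERACY_TOL or s[1] <= 1e-9 * s[0]:
        raise ValueError("rank-deficient point set: no well-defined plane")
    return vt[-1]


def planar_intersection_angle(pair_i, pair_j, pair_k) -> float:
    """Angle (degrees, folded into [0, 90]) between the best-fit planes
    of the two consecutive pair quads (i u j) and (j u k)."""
    li, ri = _pair(pair_i)
    lj, rj = _pair(pair_j)
    lk, rk = _pair(pair_k)
    n1 = _fit_plane_normal(np.array([li, ri, lj, rj]))
    n2 = _fit_plane_normal(np.array([lj, rj, lk, rk]))
    c = np.clip(abs(float(np.dot(n1, n2))), 0.0, 1.0)
    return math.degrees(math.acos(c))


SUM_FEATURE_FAMILIES = (
    "sum_pair_ratio",
    "sum_midpoint_distance",
    "sum_side_cosine",
    "sum_axial_twist",
    "sum_lateral_twist",
    "sum_bend_angle",
    "sum_planar_angle",
)


def posture_sum_features(pairs: Sequence) -> dict[str, float]:
    """Posture-wide sums of the local pair features.

    ``pairs`` is the chain of (left, right) coordinate pairs in branch
    order.  For each local feature family the value is the sum over all
    consecutive positions along the body; one scalar per family.
    """
    pairs = [tuple(p) for p in pairs]
    n = len(pairs)
    if n < 3:
        raise ValueError("posture-wide sums need at least 3 pairs")
    out = {f: 0.0 for f in SUM_FEATURE_FAMILIES}
    for q in range(n - 1):
        out["sum_pair_ratio"] += pair_distance_ratio(pairs[q], pairs[q + 1])
        out["sum_midpoint_distance"] += midpoint_distance(pairs[q], pairs[q + 1])
        out["sum_side_cosine"] += side_cosine_similarity(pairs[q], pairs[q + 1])
        out["sum_axial_twist"] += axial_twist_angle(pairs[q], pairs[q + 1])
        out["sum_lateral_twist"] += lateral_axial_twist_angle(pairs[q], pairs[q + 1])
    for q in range(n - 2):
        out["sum_bend_angle"] += midpoint_bend_angle(pairs[q], pairs[q + 1], pairs[q + 2])
        out["sum_planar_angle"] += planar_intersection_angle(
            pairs[q], pairs[q + 1], pairs[q + 2]
        )
    return out
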