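"""Posture templates and the Sides / Pairs / Posture matching models.

A *template* records, for each geometric feature at each body position,
the expected value and spread as functions of normalized developmental
time t in [0, 1] (the embryo elongates, so bend angles open up and
chord lengths grow over development).  Templates are estimated from a
corpus of labeled postures, optionally holding out one embryo.

A *model* turns an unlabeled point-set plus a template into a matching
problem.  All models share the degree-2 chord families; the
hypergraphical ones add pair-quad (degree-4) and pair-triplet
(degree-6) angle features, and the richest adds a single maximum-degree
hyperedge scoring posture-wide feature sums over the complete
assignment:

* ``Sides``   — degree 2 only: standardized lateral pair distances and
  left/right side chord lengths (a graph matching model).
* ``Pairs``   — adds degree 4 (width ratio, midpoint spacing, side
  cosine, signed and unsigned twist) and degree 6 (midpoint bend,
  planar intersection) hyperedges over consecutive pairs/triplets.
* ``Posture`` — additionally one lazy degree-n1 hyperedge whose cost is
  the standardized posture-wide sum of each Pairs feature family,
  evaluable only when the assignment completes.

Each feature contributes ``weight * ((value - mean(t)) / sd(t))**2``, a
squared z-score: smooth, nonnegative, and additive — so every compiled
tensor satisfies the solver's nonnegativity contract.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import DissimilarityTensor, MatchingProblem
from .features import (
    CANONICAL_PAIR_NAMES,
    SUM_FEATURE_FAMILIES,
    LabeledPosture,
    axial_twist_angle,
    lateral_axial_twist_angle,
    lateral_pair_distance,
    midpoint_bend_angle,
    midpoint_distance,
    pair_distance_ratio,
    planar_intersection_angle,
    posture_sum_features,
    side_chord_length,
    side_cosine_similarity,
)

__all__ = [
    "PostureTemplate",
    "ModelSpec",
    "sides_spec",
    "pairs_spec",
    "posture_spec",
    "pair_names_for",
    "posture_feature_table",
    "fit_templates",
    "standardized_cost",
    "build_problem",
]

DEGREE2_FAMILIES = ("lateral", "chord_left", "chord_right")
DEGREE4_FAMILIES = (
    "pair_ratio",
    "midpoint_distance",
    "side_cosine",
    "axial_twist",
    "lateral_twist",
)
DEGREE6_FAMILIES = ("bend_angle", "planar_angle")

# Relative floor on template spreads: prevents infinite costs when a
# corpus feature is (near-)deterministic, e.g. the tail pair width.
SD_FLOOR_FRACTION = 1e-6


def pair_names_for(n_pairs: int) -> tuple[str, ...]:
    """Canonical anterior-to-posterior names for full-size embryos."""
    if n_pairs == 10:
        return tuple(n for n in CANONICAL_PAIR_NAMES if n != "Q")
    if n_pairs == 11:
        return CANONICAL_PAIR_NAMES
    raise ValueError(f"full embryos have 10 (pre-Q) or 11 (post-Q) pairs, got {n_pairs}")


def posture_feature_table(posture: LabeledPosture) -> dict[tuple[str, str], float]:
    """All model feature values of a labeled posture, keyed by
    (family, body-position).  Positions are named by the pairs involved
    in branch (posterior-to-anterior) order, e.g. ``"T-V6"``."""
    chain = posture.branch_pairs()
    names = [c[0] for c in chain]
    pairs = [(c[1], c[2]) for c in chain]
    n = len(pairs)
    out: dict[tuple[str, str], float] = {}
    for q in range(n):
        out[("lateral", names[q])] = lateral_pair_distance(*pairs[q])
    for q in range(n - 1):
        key = f"{names[q]}-{names[q + 1]}"
        out[("chord_left", key)] = side_chord_length(pairs[q][0], pairs[q + 1][0])
        out[("chord_right", key)] = side_chord_length(pairs[q][1], pairs[q + 1][1])
        out[("pair_ratio", key)] = pair_distance_ratio(pairs[q], pairs[q + 1])
        out[("midpoint_distance", key)] = midpoint_distance(pairs[q], pairs[q + 1])
        out[("side_cosine", key)] = side_cosine_similarity(pairs[q], pairs[q + 1])
        out[("axial_twist", key)] = axial_twist_angle(pairs[q], pairs[q + 1])
        out[("lateral_twist", key)] = lateral_axial_twist_angle(pairs[q], pairs[q + 1])
    for q in range(n - 2):
        key = f"{names[q]}-{names[q + 1]}-{names[q + 2]}"
        out[("bend_angle", key)] = midpoint_bend_angle(pairs[q], pairs[q + 1], pairs[q + 2])
        out[("planar_angle", key)] = planar_intersection_angle(
            pairs[q], pairs[q + 1], pairs[q + 2]
        )
    for fam, val in posture_sum_features(pairs).items():
        out[(fam, "all")] = val
    return out


class PostureTemplate:
    """Per-feature, per-position time courses of mean and spread.

    Mean and sd are piecewise-linear in normalized time with knots at
    deciles; sd is floored at a small positive epsilon so standardized
    costs stay finite.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> None:
        self.entries: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, (knots, means, sds) in entries.items():
            knots = np.asarray(knots, dtype=float)
            means = np.asarray(means, dtype=float)
            sds = np.asarray(sds, dtype=float)
            if not (knots.shape == means.shape == sds.shape) or knots.ndim != 1:
                raise ValueError(f"template entry {key}: knots/means/sds must align")
            if np.any(sds <= 0.0):
                raise ValueError(f"template entry {key}: sd must be positive everywhere")
            self.entries[(str(key[0]), str(key[1]))] = (knots, means, sds)

    def keys(self):
        return self.entries.keys()

    def mean(self, family: str, position: str, t: float) -> float:
        knots, means, _ = self._entry(family, position)
        return float(np.interp(t, knots, means))

    def sd(self, family: str, position: str, t: float) -> float:
        knots, _, sds = self._entry(family, position)
        return float(np.interp(t, knots, sds))

    def _entry(self, family: str, position: str):
        try:
            return self.entries[(family, position)]
        except KeyError:
            raise KeyError(f"template has no entry for ({family!r}, {position!r})") from None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("family\tposition\tt\tmean\tsd\n")
            for (family, position), (knots, means, sds) in sorted(self.entries.items()):
                for t, m, s in zip(knots, means, sds):
                    fh.write(f"{family}\t{position}\t{t:.12g}\t{m:.12g}\t{s:.12g}\n")

    @classmethod
    def read(cls, path) -> "PostureTemplate":
        rows: dict[tuple[str, str], list[tuple[float, float, float]]] = {}
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header != ["family", "position", "t", "mean", "sd"]:
                raise ValueError(f"unrecognized template header: {header}")
            for line in fh:
                family, position, t, m, s = line.rstrip("\n").split("\t")
                rows.setdefault((family, position), []).append(
                    (float(t), float(m), float(s))
                )
        entries = {}
        for key, triples in rows.items():
            triples.sort()
            arr = np.array(triples)
            entries[key] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(entries)


def fit_templates(
    corpus: Iterable,
    holdout: str | None = None,
    knots: Sequence[float] | None = None,
) -> PostureTemplate:
    """Estimate a time-dependent template from a labeled corpus.

    ``corpus`` items are ``(time, posture)`` or ``(time, posture,
    embryo_id)``; samples from the held-out embryo are excluded
    entirely.  For each feature and position, samples are binned to the
    nearest knot (deciles by default); per-bin sample mean and sd define
    the piecewise-linear time courses.  Bins with fewer than two samples
    borrow the corpus-wide sd (with a warning); empty bins are filled by
    interpolation from occupied ones.  All sds are floored at
    ``SD_FLOOR_FRACTION`` of the feature family's corpus-wide sd (or an
    absolute 1e-6 when the family is deterministic).
    """
    samples = []
    for item in corpus:
        if len(item) == 3:
            t, posture, embryo = item
        else:
            t, posture = item
            embryo = None
        if holdout is not None and embryo == holdout:
            continue
        samples.append((float(t), posture))
    if not samples:
        raise ValueError("empty corpus (after holdout exclusion)")
    times = np.array([t for t, _ in samples])
    if knots is None:
        knots = np.linspace(0.0, 1.0, 11)
    knots = np.asarray(knots, dtype=float)

    values: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for t, posture in samples:
        for key, val in posture_feature_table(posture).items():
            values.setdefault(key, []).append((t, val))

    family_sd: dict[str, float] = {}
    for (family, _), pairs in values.items():
        family_sd.setdefault(family, 0.0)
    for family in family_sd:
        pooled = np.array(
            [v for (fam, _), pairs in values.items() if fam == family for _, v in pairs]
        )
        family_sd[family] = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0

    entries = {}
    for key, pairs in values.items():
        family = key[0]
        tv = np.array([t for t, _ in pairs])
        xv = np.array([v for _, v in pairs])
        bins = np.argmin(np.abs(tv[:, None] - knots[None, :]), axis=1)
        means = np.full(knots.shape, np.nan)
        sds = np.full(knots.shape, np.nan)
        global_sd = float(np.std(xv, ddof=1)) if xv.size > 1 else 0.0
        for b in range(knots.size):
            sel = xv[bins == b]
            if sel.size == 0:
                continue
            means[b] = float(np.mean(sel))
            if sel.size >= 2:
                sds[b] = float(np.std(sel, ddof=1))
            else:
                warnings.warn(
                    f"template bin t={knots[b]:.2f} for {key} has a single sample; "
                    "borrowing the corpus-wide sd",
                    stacklevel=2,
                )
                sds[b] = global_sd
        occupied = ~np.isnan(means)
        if not occupied.any():
            raise ValueError(f"no samples for template entry {key}")
        means = np.interp(knots, knots[occupied], means[occupied])
        sds = np.interp(knots, knots[occupied], sds[occupied])
        floor = SD_FLOOR_FRACTION * family_sd[family]
        if floor <= 0.0:
            floor = 1e-6
        sds = np.maximum(sds, floor)
        entries[key] = (knots.copy(), means, sds)
    return PostureTemplate(entries)


def standardized_cost(value: float, mean: float, sd: float, weight: float = 1.0) -> float:
    """Squared z-score cost ``weight * ((value - mean)/sd)**2``."""
    if sd <= 0.0:
        raise ValueError("template invariant violated: sd must exceed the positive floor")
    if weight < 0.0:
        raise ValueError("feature weights must be >= 0")
    z = (value - mean) / sd
    return weight * z * z


@dataclass(frozen=True)
class ModelSpec:
    """Which feature families a model includes, with per-family weights.

    ``Sides`` uses only degree-2 families; ``Pairs`` adds the degree-4
    and degree-6 families; ``Posture`` additionally scores the
    posture-wide sums through a single degree-n1 hyperedge.
    """

    name: str
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ("Sides", "Pairs", "Posture"):
            raise ValueError(f"unknown model {self.name!r}")
        allowed = set(DEGREE2_FAMILIES)
        if self.name in ("Pairs", "Posture"):
            allowed |= set(DEGREE4_FAMILIES) | set(DEGREE6_FAMILIES)
        if self.name == "Posture":
            allowed |= set(SUM_FEATURE_FAMILIES)
        object.__setattr__(
            self, "weights", {f: 1.0 for f in sorted(allowed)} | dict(self.weights)
        )
        for f, w in self.weights.items():
            if f not in allowed:
                raise ValueError(f"family {f!r} is not part of the {self.name} model")
            if w < 0:
                raise ValueError("weights must be >= 0")

    def families(self, degree_group: Sequence[str]) -> list[str]:
        return [f for f in degree_group if f in self.weights]


def sides_spec(**weights) -> ModelSpec:
    return ModelSpec("Sides", weights)


def pairs_spec(**weights) -> ModelSpec:
    return ModelSpec("Pairs", weights)


def posture_spec(**weights) -> ModelSpec:
    return ModelSpec("Posture", weights)


def build_problem(
    points: np.ndarray,
    n_pairs: int,
    template: PostureTemplate,
    time: float,
    spec: ModelSpec,
    pair_names: Sequence[str] | None = None,
) -> MatchingProblem:
    """Compile a model into a matching problem over an unlabeled point-set.

    Branch order runs tail-first (T, V6, [Q], V5, ... H0) with branch
    size k=2: vertex 2q is the left and 2q+1 the right nucleus of the
    q-th branch pair.  Extra points (n2 > n1) are simply left unmatched.
    The template is evaluated at the frame's normalized developmental
    ``time``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n2, 3) array")
    if pair_names is None:
        pair_names = pair_names_for(n_pairs)
    pair_names = tuple(pair_names)
    if len(pair_names) != n_pairs:
        raise ValueError("pair_names length must equal n_pairs")
    n1 = 2 * n_pairs
    n2 = points.shape[0]
    if n2 < n1:
        raise ValueError(f"need at least {n1} points for {n_pairs} pairs, got {n2}")
    branch_names = tuple(reversed(pair_names))  # posterior -> anterior
    k = 2
    t = float(time)

    def seg_key(q: int) -> str:
        return f"{branch_names[q]}-{branch_names[q + 1]}"

    def tri_key(q: int) -> str:
        return f"{branch_names[q]}-{branch_names[q + 1]}-{branch_names[q + 2]}"

    def ms(family: str, position: str) -> tuple[float, float, float]:
        return (
            template.mean(family, position, t),
            template.sd(family, position, t),
            spec.weights[family],
        )

    tensors = []

    # --- degree 2: lateral widths + side chords -------------------------
    deg2_key: dict[tuple[int, int], tuple[str, str]] = {}
    for q in range(n_pairs):
        deg2_key[(2 * q, 2 * q + 1)] = ("lateral", branch_names[q])
    for q in range(n_pairs - 1):
        deg2_key[(2 * q, 2 * q + 2)] = ("chord_left", seg_key(q))
        deg2_key[(2 * q + 1, 2 * q + 3)] = ("chord_right", seg_key(q))
    deg2_params = {vt: ms(fam, pos) for vt, (fam, pos) in deg2_key.items()}

    def deg2_cost(vt, pt):
        mean, sd, w = deg2_params[vt]
        d = float(np.linalg.norm(points[pt[0]] - points[pt[1]]))
        return standardized_cost(d, mean, sd, w)

    tensors.append(
        DissimilarityTensor(2, deg2_key.keys(), deg2_cost, mode="precomputed")
    )

    # --- degree 4: consecutive pair quads -------------------------------
    quad_fams = spec.families(DEGREE4_FAMILIES)
    if quad_fams:
        quad_params = {}
        for q in range(n_pairs - 1):
            vt = (2 * q, 2 * q + 1, 2 * q + 2, 2 * q + 3)
            quad_params[vt] = {fam: ms(fam, seg_key(q)) for fam in quad_fams}

        def deg4_cost(vt, pt):
            pi = (points[pt[0]], points[pt[1]])
            pj = (points[pt[2]], points[pt[3]])
            vals = {
                "pair_ratio": pair_distance_ratio,
                "midpoint_distance": midpoint_distance,
                "side_cosine": side_cosine_similarity,
                "axial_twist": axial_twist_angle,
                "lateral_twist": lateral_axial_twist_angle,
            }
            total = 0.0
            for fam, (mean, sd, w) in quad_params[vt].items():
                total += standardized_cost(vals[fam](pi, pj), mean, sd, w)
            return total

        tensors.append(
            DissimilarityTensor(4, quad_params.keys(), deg4_cost, mode="precomputed")
        )

    # --- degree 6: consecutive pair triplets (lazy: 6 > 2k) -------------
    tri_fams = spec.families(DEGREE6_FAMILIES)
    if tri_fams:
        tri_params = {}
        for q in range(n_pairs - 2):
            vt = tuple(range(2 * q, 2 * q + 6))
            tri_params[vt] = {fam: ms(fam, tri_key(q)) for fam in tri_fams}

        def deg6_cost(vt, pt):
            pi = (points[pt[0]], points[pt[1]])
            pj = (points[pt[2]], points[pt[3]])
            pk = (points[pt[4]], points[pt[5]])
            vals = {
                "bend_angle": midpoint_bend_angle,
                "planar_angle": planar_intersection_angle,
            }
            total = 0.0
            for fam, (mean, sd, w) in tri_params[vt].items():
                total += standardized_cost(vals[fam](pi, pj, pk), mean, sd, w)
            return total

        tensors.append(DissimilarityTensor(6, tri_params.keys(), deg6_cost, mode="lazy"))

    # --- degree n1: posture-wide sums (Posture model only) --------------
    sum_fams = spec.families(SUM_FEATURE_FAMILIES)
    if sum_fams:
        full_vt = tuple(range(n1))
        sum_params = {fam: ms(fam, "all") for fam in sum_fams}

        def full_cost(vt, pt):
            pairs = [(points[pt[2 * q]], points[pt[2 * q + 1]]) for q in range(n_pairs)]
            sums = posture_sum_features(pairs)
            total = 0.0
            for fam, (mean, sd, w) in sum_params.items():
                total += standardized_cost(sums[fam], mean, sd, w)
            return total

        tensors.append(DissimilarityTensor(n1, [full_vt], full_cost, mode="lazy"))

    labels = []
    for name in branch_names:
        labels.extend([f"{name}L", f"{name}R"])
    return MatchingProblem(n1, n2, k, tensors, vertex_labels=labels)
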