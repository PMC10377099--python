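"""Pareto-optimal hyperparameter selection over enumerated candidates.

A candidate couples a named hyperparameter setting with a vector of objective
values (each marked minimize or maximize). A candidate dominates another when
it is at least as good in every objective and strictly better in one; the
Pareto front is the non-dominated subset. A weighted scalarization
(alpha * loss-like objective + beta * size-like objective, after min-max
normalization over the candidate set) picks one compromise point from the
front.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObjectivePoint",
    "ScalarizationWeights",
    "dominates",
    "pareto_front",
    "scalarize",
    "select_config",
    "points_to_json",
    "points_from_json",
]


@dataclass(frozen=True)
class ObjectivePoint:
    """One hyperparameter setting with its measured objective vector."""

    params: dict
    objectives: tuple[float, ...]
    directions: tuple[str, ...] = ()

    def __post_init__(self):
        obj = tuple(float(v) for v in self.objectives)
        if not obj or not all(np.isfinite(obj)):
            raise ValueError("objectives must be non-empty and finite")
        dirs = tuple(self.directions) or ("minimize",) * len(obj)
        if len(dirs) != len(obj) or any(d not in ("minimize", "maximize") for d in dirs):
            raise ValueError("directions must match objectives and be minimize/maximize")
        object.__setattr__(self, "objectives", obj)
        object.__setattr__(self, "directions", dirs)


@dataclass(frozen=True)
class ScalarizationWeights:
    """alpha weights the loss-like objective, beta the parameter-count objective."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or (self.alpha == 0 and self.beta == 0):
            raise ValueError("alpha, beta must be >= 0 and not both zero")


def _signed(p: ObjectivePoint) -> np.ndarray:
    # flip maximize objectives so "smaller is better" uniformly
    sign = np.array([1.0 if d == "minimize" else -1.0 for d in p.directions])
    return sign * np.asarray(p.objectives)


def dominates(p: ObjectivePoint, q: ObjectivePoint) -> bool:
    """True iff p is at least as good as q everywhere and strictly better once."""
    if p.directions != q.directions:
        raise ValueError("points have different objective directions")
    a, b = _signed(p), _signed(q)
    return bool(np.all(a <= b) and np.any(a < b))


def pareto_front(points: list[ObjectivePoint]) -> list[ObjectivePoint]:
    """The non-dominated subset, in input order; duplicate vectors all survive."""
    if not points:
        raise ValueError("need at least one candidate")
    dirs = points[0].directions
    if any(p.directions != dirs for p in points):
        raise ValueError("all candidates must share objective directions")
    mat = np.stack([_signed(p) for p in points])  # (n, M)
    front = []
    for i, p in enumerate(points):
        others = np.delete(mat, i, axis=0)
        dominated = np.any(
            np.all(others <= mat[i], axis=1) & np.any(others < mat[i], axis=1)
        )
        if not dominated:
            front.append(p)
    return front


def scalarize(
    p: ObjectivePoint, w: ScalarizationWeights, candidates: list[ObjectivePoint]
) -> float:
    """alpha * f1 + beta * f2 after min-max normalizing each objective.

    Normalization ranges come from ``candidates`` (the pool being compared);
    mixing a raw loss with a raw parameter count would let the larger-scaled
    objective swamp the other.
    """
    if len(p.objectives) != 2:
        raise ValueError("scalarization is defined for exactly 2 objectives")
    if any(d != "minimize" for d in p.directions):
        raise ValueError("scalarization expects both objectives minimize-directed")
    mat = np.stack([np.asarray(c.objectives, dtype=float) for c in candidates])
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    f = (np.asarray(p.objectives) - lo) / span
    return float(w.alpha * f[0] + w.beta * f[1])


def select_config(
    candidates: list[ObjectivePoint],
    w: ScalarizationWeights,
    feasible=None,
) -> ObjectivePoint:
    """Best compromise: scalarized argmin restricted to the Pareto front.

    ``feasible`` is an optional predicate applied before front extraction.
    Ties break by lower first objective, then input order.
    """
    pool = [p for p in candidates if feasible(p)] if feasible else list(candidates)
    if not pool:
        raise ValueError("no feasible candidates")
    front = pareto_front(pool)
    best, best_key = None, None
    for p in front:
        key = (scalarize(p, w, pool), p.objectives[0])
        if best_key is None or key < best_key:
            best, best_key = p, key
    return best


def points_to_json(points: list[ObjectivePoint], path) -> None:
    rows = [
        {"params": p.params, "objectives": list(p.objectives),
         "directions": list(p.directions)}
        for p in points
    ]
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=2)


def points_from_json(path) -> list[ObjectivePoint]:
    with open(path) as fh:
        rows = json.load(fh)
    return [
        ObjectivePoint(
            params=r.get("params", {}),
            objectives=tuple(r["objectives"]),
            directions=tuple(r.get("directions", ())),
        )
        for r in rows
    ]
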