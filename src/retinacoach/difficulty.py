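"""Automatic case-difficulty scoring for fundus images.

The difficulty of a case combines two components:

* **Probability difficulty** — how unsure the multilabel classifier is.  With
  per-class probabilities ``p_C(x)`` and the membership rule ``p_C >= 0.5``,

      prob_difficulty = several + Σ_{p_C>=0.5} (1 - p_C) + Σ_{p_C<0.5} p_C

  where ``several`` is 1 when more than one class is predicted.  A single
  fully confident class gives 0.

* **Neighbor difficulty** — a silhouette-style measure over the k most
  similar reference images (cosine distance between encoder embeddings,
  k = 9 by default).  Let NC be the neighbors sharing at least one class
  with the prediction, ``a`` their mean distance, and ``b`` the smallest
  per-foreign-class mean distance, attained by class C_min.  Then

      neighbors_difficulty = -(|NC|·b - |NC_min|·a) / (|NC_min|·max(a, b))

  A neighborhood dominated by same-class images at short range is easy
  (negative values); foreign-class-dominated neighborhoods are hard.  The
  degenerate cases are pinned to the metric's extremes: all neighbors share
  a class -> -k, none do -> +k.

Both components are min–max normalised to [0, 1] against a calibration set;
their sum in [0, 2] is banded as easy (<= 0.5), medium (in (0.5, 1.5]) or
difficult (> 1.5) and scored 1/3/5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple
import warnings

import numpy as np

from .taxonomy import difficulty_score

__all__ = [
    "Neighbor",
    "NeighborSet",
    "Calibration",
    "DifficultyResult",
    "prob_difficulty",
    "find_neighbors",
    "neighbors_difficulty",
    "total_difficulty",
    "band_of",
]

PREDICT_THRESHOLD = 0.5


def prob_difficulty(probs: Sequence[float]) -> float:
    """Confidence component of the difficulty metric (see module docstring)."""
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    predicted = p >= PREDICT_THRESHOLD
    several = 1.0 if predicted.sum() > 1 else 0.0
    return float(several + np.sum(1.0 - p[predicted]) + np.sum(p[~predicted]))


@dataclass(frozen=True)
class Neighbor:
    ref_id: str
    labels: frozenset
    distance: float  # cosine distance, 1 - similarity, in [0, 2]


@dataclass
class NeighborSet:
    """Top-k neighborhood of a query, partitioned against its prediction."""

    k: int
    neighbors: List[Neighbor]
    predicted: Set[str]

    @property
    def same_class(self) -> List[Neighbor]:
        """NC: neighbors sharing at least one predicted class."""
        return [n for n in self.neighbors if n.labels & self.predicted]

    @property
    def foreign_by_class(self) -> Dict[str, List[Neighbor]]:
        """NC_j: foreign neighbors grouped under each of their classes."""
        groups: Dict[str, List[Neighbor]] = {}
        for n in self.neighbors:
            if not (n.labels & self.predicted):
                for c in sorted(n.labels):
                    groups.setdefault(c, []).append(n)
        return groups


def find_neighbors(
    query: np.ndarray,
    ref_embeddings: np.ndarray,
    ref_labels: Sequence[Set[str]],
    ref_ids: Sequence[str] | None = None,
    predicted: Set[str] = frozenset(),
    k: int = 9,
) -> NeighborSet:
    """Top-k reference images by cosine similarity to the query embedding.

    Ties are broken by stable reference order.  If the reference holds fewer
    than k images, all of them are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ref = np.asarray(ref_embeddings, dtype=float)
    if ref.ndim != 2 or ref.shape[0] == 0:
        raise ValueError("reference must be a non-empty 2-d array")
    if ref.shape[0] != len(ref_labels):
        raise ValueError("embeddings and labels disagree in length")
    if ref_ids is None:
        ref_ids = [str(i) for i in range(ref.shape[0])]
    q = np.asarray(query, dtype=float)
    sims = (ref @ q) / (
        np.linalg.norm(ref, axis=1) * np.linalg.norm(q) + 1e-12
    )
    if ref.shape[0] < k:
        warnings.warn(
            f"reference holds {ref.shape[0]} < k={k} images; returning all"
        )
    # mergesort is stable: equal similarities keep reference order
    order = np.argsort(-sims, kind="stable")[:k]
    neighbors = [
        Neighbor(ref_id=str(ref_ids[i]), labels=frozenset(ref_labels[i]),
                 distance=float(1.0 - sims[i]))
        for i in order
    ]
    return NeighborSet(k=k, neighbors=neighbors, predicted=set(predicted))


def neighbors_difficulty(ns: NeighborSet) -> float:
    """Silhouette-style neighborhood component (see module docstring)."""
    n = len(ns.neighbors)
    if n == 0:
        raise ValueError("empty neighbor set")
    same = ns.same_class
    foreign = ns.foreign_by_class
    if not foreign:  # every neighbor shares a predicted class
        return float(-n)
    if not same:  # no neighbor shares a predicted class
        return float(n)
    a = float(np.mean([nb.distance for nb in same]))
    best_class, best_mean = None, np.inf
    for cls in sorted(foreign):
        mean = float(np.mean([nb.distance for nb in foreign[cls]]))
        if mean < best_mean:
            best_class, best_mean = cls, mean
    b = best_mean
    n_min = len(foreign[best_class])
    denom = n_min * max(a, b)
    if denom == 0.0:  # all distances zero: no separation information
        return 0.0
    return float(-(len(same) * b - n_min * a) / denom)


@dataclass
class Calibration:
    """Min–max normalisation bounds for the two difficulty components.

    Fitted once on a declared calibration set (by default the reference
    test-set difficulty values) and persisted, so new cases score stably.
    """

    prob_bounds: Tuple[float, float]
    neighbor_bounds: Tuple[float, float]

    def __post_init__(self):
        for lo, hi in (self.prob_bounds, self.neighbor_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid calibration bounds ({lo}, {hi})")

    @classmethod
    def fit(cls, prob_values: Sequence[float],
            neighbor_values: Sequence[float]) -> "Calibration":
        return cls(
            prob_bounds=(float(np.min(prob_values)), float(np.max(prob_values))),
            neighbor_bounds=(float(np.min(neighbor_values)),
                             float(np.max(neighbor_values))),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"prob_bounds": list(self.prob_bounds),
                       "neighbor_bounds": list(self.neighbor_bounds)}, fh)

    @classmethod
    def load(cls, path) -> "Calibration":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(prob_bounds=tuple(doc["prob_bounds"]),
                   neighbor_bounds=tuple(doc["neighbor_bounds"]))


def _normalise(value: float, bounds: Tuple[float, float]) -> float:
    lo, hi = bounds
    return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def band_of(total: float) -> str:
    """Band the normalised total: [0,0.5] easy, (0.5,1.5] medium, else hard."""
    if total <= 0.5:
        return "easy"
    if total <= 1.5:
        return "medium"
    return "difficult"


@dataclass(frozen=True)
class DifficultyResult:
    prob_component: float
    neighbor_component: float
    norm_prob: float
    norm_neighbor: float
    total: float
    band: str
    score: int


def total_difficulty(prob: float, neighbor: float,
                     calibration: Calibration) -> DifficultyResult:
    """Normalise, sum, band, and score the two difficulty components."""
    norm_p = _normalise(prob, calibration.prob_bounds)
    norm_n = _normalise(neighbor, calibration.neighbor_bounds)
    total = norm_p + norm_n
    band = band_of(total)
    return DifficultyResult(
        prob_component=float(prob),
        neighbor_component=float(neighbor),
        norm_prob=norm_p,
        norm_neighbor=norm_n,
        total=total,
        band=band,
        score=difficulty_score(band),
    )
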