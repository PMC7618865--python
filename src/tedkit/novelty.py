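"""Novelty triage for unlabelled domains.

Cluster representatives with no CATH label are routed through three gates,
in order: a compactness (globularity) filter discards poor-quality,
non-protein-like choppings; an internal-symmetry gate sequesters repeat
architectures (symmetry Z-score above 9); the remainder are ranked by a
density-based anomaly score over structure-embedding vectors, scaled to
[0, 100] so that scores close to 100 mark the most novel domains.

The anomaly score is a leave-one-out k-nearest-neighbour ECDF: a query's
distance to its k-th nearest reference is placed on the empirical
distribution of the references' own k-NN distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import SymmetryResult

__all__ = [
    "EmbeddingVector",
    "NoveltyScore",
    "knn_novelty",
    "reference_knn_distances",
    "symmetry_gate",
    "triage_unlabelled",
]

K_DEFAULT = 5
Z_MIN_DEFAULT = 9.0
GLOB_MAX_DEFAULT = 1.5


@dataclass(frozen=True)
class EmbeddingVector:
    domain_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "vector", np.asarray(self.vector, dtype=float).ravel()
        )


@dataclass(frozen=True)
class NoveltyScore:
    domain_id: str
    score: float  # [0, 100]; near 100 = most novel
    knn_dist: float


def reference_knn_distances(refs: Sequence[EmbeddingVector], k: int) -> np.ndarray:
    """Leave-one-out k-NN distance of every reference to the other references."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(refs) <= k:
        raise ValueError(f"need more than k={k} references, got {len(refs)}")
    mat = np.stack([r.vector for r in refs])
    if mat.ndim != 2:
        raise ValueError("reference vectors must share dimensionality")
    d = cdist(mat, mat)
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    return d[:, k - 1]


def knn_novelty(
    query: EmbeddingVector,
    refs: Sequence[EmbeddingVector],
    k: int = K_DEFAULT,
    ref_knn: np.ndarray | None = None,
) -> NoveltyScore:
    """Density-based novelty of a query embedding against a reference set.

    ``score = 100 × ECDF(knn_dist)`` where the (right-continuous) ECDF is
    built from the references' own leave-one-out k-NN distances.  A query
    farther from all references than any reference is from its peers scores
    100; a query inside a dense region scores near 0.  ``ref_knn`` may carry
    precomputed reference distances to amortise batch scoring.
    """
    if ref_knn is None:
        ref_knn = reference_knn_distances(refs, k)
    mat = np.stack([r.vector for r in refs])
    if query.vector.shape[0] != mat.shape[1]:
        raise ValueError(
            f"query dimension {query.vector.shape[0]} != reference dimension {mat.shape[1]}"
        )
    d = np.linalg.norm(mat - query.vector, axis=1)
    d.sort()
    knn_dist = float(d[k - 1])
    score = 100.0 * float((ref_knn <= knn_dist).mean())
    return NoveltyScore(domain_id=query.domain_id, score=score, knn_dist=knn_dist)


def symmetry_gate(sym: SymmetryResult, z_min: float = Z_MIN_DEFAULT) -> str:
    """Route by internal symmetry: Z strictly greater than ``z_min`` goes to
    the repeat category, anything else stays a novel-fold candidate."""
    return "repeat_category" if sym.zscore > z_min else "novel_candidate"


def triage_unlabelled(
    cluster_reps: Sequence[Mapping],
    refs: Sequence[EmbeddingVector],
    k: int = K_DEFAULT,
    z_min: float = Z_MIN_DEFAULT,
    glob_max: float = GLOB_MAX_DEFAULT,
) -> dict:
    """Route unlabelled cluster representatives into exactly one bin each.

    Each representative record carries ``domain_id``, ``symmetry``
    (:class:`~tedkit.geometry.SymmetryResult`), ``globularity`` (float) and
    ``embedding`` (:class:`EmbeddingVector`).  Filters apply in order:
    quality (globularity > ``glob_max`` → discarded), then the symmetry
    gate, then novelty scoring for the survivors.
    """
    ref_knn = reference_knn_distances(refs, k) if cluster_reps else None
    discarded: list[str] = []
    repeats: list[str] = []
    novel: list[NoveltyScore] = []
    for rep in cluster_reps:
        did = rep["domain_id"]
        if rep["globularity"] > glob_max:
            discarded.append(did)
            continue
        if symmetry_gate(rep["symmetry"], z_min) == "repeat_category":
            repeats.append(did)
            continue
        novel.append(knn_novelty(rep["embedding"], refs, k, ref_knn=ref_knn))
    return {
        "discarded_poor_quality": discarded,
        "repeat_category": repeats,
        "novel_candidates": sorted(novel, key=lambda s: (-s.score, s.domain_id)),
    }
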