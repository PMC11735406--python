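"""Vietoris-Rips persistent homology in dimension 1.

A 1-D hole (a ring) appears in the filtration when an edge closes a cycle
(birth) and disappears when triangles fill it in (death). Features are
computed by the standard dimension-wise boundary-matrix reduction over Z/2:
union-find over edges identifies the cycle-creating (positive) edges, and
triangle columns -- represented as integer bitsets over edge indices -- are
reduced left-to-right in filtration order; a pairing (edge, triangle) with
death > birth is an H1 feature.

Point clouds are z-scored per dimension internally (latent spaces of
different models have arbitrary scale) and subsampled above a configurable
cap, since the triangle count grows as C(n, 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["PersistenceFeature", "persistence_h1", "most_persistent"]


@dataclass(frozen=True)
class PersistenceFeature:
    """One homology feature: (birth, death) filtration radii, length = death - birth."""

    dim: int
    birth: float
    death: float

    @property
    def length(self) -> float:
        return self.death - self.birth

    def __post_init__(self):
        if self.death < self.birth or self.birth < 0:
            raise ValueError("need death >= birth >= 0")


def _zscore(points: np.ndarray) -> np.ndarray:
    mean = points.mean(axis=0)
    sd = points.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (points - mean) / sd


def persistence_h1(points: np.ndarray, max_radius: float | None = None,
                   subsample: int | None = 100, seed: int = 0,
                   zscore: bool = True) -> list[PersistenceFeature]:
    """H1 persistence features of the Vietoris-Rips filtration of a point cloud.

    Fewer than 3 points yield no features. Edges/triangles with filtration
    value above `max_radius` are excluded; a cycle still open at `max_radius`
    is reported with death = inf.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError(f"points must be (n, d), got {points.shape}")
    n = points.shape[0]
    if n < 3:
        return []
    if subsample is not None and n > subsample:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=subsample, replace=False))
        points = points[idx]
        n = subsample
    if zscore:
        points = _zscore(points)
    dist = squareform(pdist(points))

    # edges sorted by filtration value (ties broken by vertex order)
    pairs = list(combinations(range(n), 2))
    edge_filt = np.array([dist[i, j] for i, j in pairs])
    if max_radius is not None:
        keep = edge_filt <= max_radius
        pairs = [p for p, k in zip(pairs, keep) if k]
        edge_filt = edge_filt[keep]
    order = np.argsort(edge_filt, kind="stable")
    edges = [pairs[k] for k in order]
    edge_filt = edge_filt[order]
    edge_index = {e: k for k, e in enumerate(edges)}

    # union-find: an edge joining two components kills an H0 class; an edge
    # inside one component creates a 1-cycle (positive edge, H1 birth candidate)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    positive = np.zeros(len(edges), dtype=bool)
    for k, (i, j) in enumerate(edges):
        ri, rj = find(i), find(j)
        if ri == rj:
            positive[k] = True
        else:
            parent[ri] = rj

    # triangles sorted by filtration (max edge length)
    tri = []
    for i, j, k in combinations(range(n), 3):
        f = max(dist[i, j], dist[i, k], dist[j, k])
        if max_radius is None or f <= max_radius:
            tri.append((f, i, j, k))
    tri.sort(key=lambda t: t[0])

    # reduce triangle boundary columns (bitsets over edge indices)
    lookup: dict[int, int] = {}           # low edge index -> reduced column
    pair_death: dict[int, float] = {}     # positive-edge index -> death filtration
    for f, i, j, k in tri:
        col = (1 << edge_index[(i, j)]) | (1 << edge_index[(i, k)]) | (1 << edge_index[(j, k)])
        while col:
            low = col.bit_length() - 1
            if low in lookup:
                col ^= lookup[low]
            else:
                lookup[low] = col
                pair_death[low] = f
                break

    features = []
    for k in np.flatnonzero(positive):
        birth = float(edge_filt[k])
        death = pair_death.get(int(k), np.inf)
        if death > birth:
            features.append(PersistenceFeature(dim=1, birth=birth, death=float(death)))
    return features


def most_persistent(features: list[PersistenceFeature]) -> tuple[float, float]:
    """(birth, length) of the longest-lived feature; ties go to the earliest birth."""
    if not features:
        raise ValueError("no persistence features given")
    best = max(features, key=lambda f: (f.length, -f.birth))
    return best.birth, best.length
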