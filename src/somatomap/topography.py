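"""Winner-takes-all maps and univariate remapping measures.

Quantifies somatotopic shifts via cluster-weighted centres of gravity,
signed graph-geodesic distances to the hand-border anchor, surface-area
coverage within the hand ROI, and the coverage laterality index
(deprived - intact) / (deprived + intact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csgraph

from .exceptions import (EmptyWinnerError, InconsistencyError,
                         InvalidParameterError, UnreachableError)
from .glm import ActivationMap
from .synthetic import FACE_CONDITIONS, RoiSet, SurfaceMesh

UNASSIGNED = -1


@dataclass
class WinnerMap:
    """Per-vertex categorical winner labels within an ROI.

    ``labels[i]`` indexes ``conditions`` for ROI vertex ``roi[i]``, or
    ``UNASSIGNED`` when the maximum statistic fell below the threshold.
    """

    roi: np.ndarray               # sorted vertex indices
    labels: np.ndarray            # same length as roi
    conditions: Tuple[str, ...]
    threshold_used: float

    def winners(self, condition: str) -> np.ndarray:
        """Sorted vertex indices won by ``condition``."""
        idx = self.conditions.index(condition)
        return self.roi[self.labels == idx]

    def winner_set(self, condition: str) -> frozenset:
        return frozenset(int(v) for v in self.winners(condition))


def winner_takes_all(maps: Mapping[str, ActivationMap], roi: np.ndarray,
                     threshold: float = 0.0,
                     conditions: Sequence[str] = FACE_CONDITIONS) -> WinnerMap:
    """Label each ROI vertex with the argmax condition (ties -> earlier
    condition in the fixed order); unassigned when the max < threshold."""
    conditions = tuple(conditions)
    missing = [c for c in conditions if c not in maps]
    if missing:
        raise InconsistencyError(f"missing activation maps for {missing}")
    roi = np.sort(np.asarray(roi, dtype=int))
    stat = np.vstack([maps[c].values[roi] for c in conditions])  # (C, |roi|)
    best = stat.argmax(axis=0)        # first max wins ties (fixed order)
    labels = np.where(stat.max(axis=0) >= threshold, best, UNASSIGNED)
    return WinnerMap(roi=roi, labels=labels, conditions=conditions,
                     threshold_used=threshold)


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """One third of incident triangle areas per vertex; sums to total area."""
    areas = np.zeros(mesh.n_vertices)
    tri_areas = mesh.triangle_areas()
    for k in range(3):
        np.add.at(areas, mesh.triangles[:, k], tri_areas / 3.0)
    return areas


def connected_clusters(wmap: WinnerMap, mesh: SurfaceMesh,
                       condition: str) -> List[np.ndarray]:
    """Connected components of a condition's winners under triangle-edge
    adjacency, sorted by descending total vertex area (ties: lowest vertex)."""
    win = wmap.winners(condition)
    if win.size == 0:
        return []
    sub = mesh.adjacency[np.ix_(win, win)]
    n_comp, comp = csgraph.connected_components(sub, directed=False)
    areas = vertex_areas(mesh)
    clusters = [win[comp == i] for i in range(n_comp)]
    clusters.sort(key=lambda c: (-areas[c].sum(), int(c.min())))
    return clusters


@dataclass
class CoGResult:
    condition: str
    position: np.ndarray          # 3D point, mm
    snapped_vertex: int
    total_weight: float           # mm^2
    n_clusters: int


def weighted_cog(wmap: WinnerMap, mesh: SurfaceMesh, condition: str,
                 statistic_weights: Optional[np.ndarray] = None) -> CoGResult:
    """Area-weighted centre of gravity pooled across all of the condition's
    winner clusters (larger clusters dominate by mass). Optionally weight by
    a per-vertex statistic as well. Snaps to the nearest winner vertex
    (lowest index on ties)."""
    win = wmap.winners(condition)
    if win.size == 0:
        raise EmptyWinnerError(f"condition {condition!r} has no winner vertices")
    w = vertex_areas(mesh)[win]
    if statistic_weights is not None:
        w = w * np.asarray(statistic_weights)[win]
    total = w.sum()
    if total <= 0:
        raise EmptyWinnerError(f"condition {condition!r} has zero total weight")
    pos = (mesh.vertices[win] * w[:, None]).sum(axis=0) / total
    d = np.linalg.norm(mesh.vertices[win] - pos, axis=1)
    snapped = int(win[np.argmin(d)])  # win sorted ascending -> lowest index tie
    return CoGResult(condition=condition, position=pos, snapped_vertex=snapped,
                     total_weight=float(total),
                     n_clusters=len(connected_clusters(wmap, mesh, condition)))


def geodesic_distance(mesh: SurfaceMesh, a: int, b: int) -> float:
    """Shortest-path length over the mesh edge graph (Euclidean weights)."""
    if a == b:
        return 0.0
    dist = csgraph.dijkstra(mesh.adjacency, directed=False, indices=a)
    if not np.isfinite(dist[b]):
        raise UnreachableError(f"vertices {a} and {b} are not connected")
    return float(dist[b])


@dataclass
class SignedDistance:
    condition: str
    value: float                  # mm; positive = medial to the anchor
    anchor_vertex: int


def signed_distance_to_anchor(cog: CoGResult, rois: RoiSet,
                              mesh: SurfaceMesh) -> SignedDistance:
    """Geodesic distance from the snapped CoG to the anchor midpoint, negated
    when the CoG lies lateral to the hand border (medial -> positive)."""
    anchor = rois.anchor_midpoint
    d = geodesic_distance(mesh, cog.snapped_vertex, anchor)
    lateral = mesh.axis[cog.snapped_vertex] > mesh.axis[anchor]
    return SignedDistance(condition=cog.condition,
                          value=-d if lateral else d,
                          anchor_vertex=anchor)


@dataclass
class LateralityIndex:
    condition: str
    deprived_pct: float
    intact_pct: float
    value: float
    degenerate: bool = False


def coverage_and_laterality(wmap_deprived: WinnerMap, wmap_intact: WinnerMap,
                            mesh: SurfaceMesh, hand_roi: np.ndarray,
                            ) -> Dict[str, LateralityIndex]:
    """Per condition, percentage of hand-ROI surface covered by its winners in
    each hemisphere and the laterality index (d - i)/(d + i); 0 and flagged
    degenerate when both coverages are zero."""
    hand_roi = np.asarray(hand_roi, dtype=int)
    if hand_roi.size == 0:
        raise InvalidParameterError("empty hand ROI")
    if wmap_deprived.conditions != wmap_intact.conditions:
        raise InconsistencyError("hemisphere winner maps disagree on conditions")
    areas = vertex_areas(mesh)
    hand_set = set(int(v) for v in hand_roi)
    total = areas[hand_roi].sum()

    def pct(wmap: WinnerMap, cond: str) -> float:
        win = [v for v in wmap.winners(cond) if int(v) in hand_set]
        return 100.0 * areas[win].sum() / total if win else 0.0

    out: Dict[str, LateralityIndex] = {}
    for cond in wmap_deprived.conditions:
        dp, ip = pct(wmap_deprived, cond), pct(wmap_intact, cond)
        if dp + ip > 0:
            out[cond] = LateralityIndex(cond, dp, ip, (dp - ip) / (dp + ip))
        else:
            out[cond] = LateralityIndex(cond, 0.0, 0.0, 0.0, degenerate=True)
    return out
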