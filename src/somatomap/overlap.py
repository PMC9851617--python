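"""Jaccard similarity between winner-takes-all maps.

The per-condition Jaccard index is the primitive; cross-group comparisons
average a target subject's map against every map of a reference group, with
leave-self-out when the target belongs to that group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np

from .exceptions import InconsistencyError, InvalidParameterError
from .topography import WinnerMap


@dataclass
class JaccardValue:
    value: float
    degenerate: bool = False      # both winner sets empty


def jaccard(map_a: WinnerMap, map_b: WinnerMap, condition: str) -> float:
    """|A ∩ B| / |A ∪ B| over the condition's winner vertex sets.

    Defined as 0 when both sets are empty (see :func:`jaccard_flagged`).
    """
    return jaccard_flagged(map_a, map_b, condition).value


def jaccard_flagged(map_a: WinnerMap, map_b: WinnerMap, condition: str) -> JaccardValue:
    if map_a.roi.shape != map_b.roi.shape or not np.array_equal(map_a.roi, map_b.roi):
        raise InconsistencyError("winner maps cover different ROIs")
    a = map_a.winner_set(condition)
    b = map_b.winner_set(condition)
    union = a | b
    if not union:
        return JaccardValue(0.0, degenerate=True)
    return JaccardValue(len(a & b) / len(union))


def cross_group_similarity(target_id: str, target_map: WinnerMap,
                           reference_maps: Mapping[str, WinnerMap],
                           condition: str,
                           leave_self_out: bool = True) -> Dict[str, float]:
    """Mean Jaccard of a target map against every reference subject's map.

    ``reference_maps`` maps subject id -> WinnerMap. When the target id is in
    the reference group and ``leave_self_out`` is set, it is excluded before
    averaging (intra-group similarity).
    """
    refs = {sid: m for sid, m in reference_maps.items()
            if not (leave_self_out and sid == target_id)}
    if not refs:
        raise InvalidParameterError("reference group empty after self exclusion")
    vals = [jaccard(target_map, m, condition) for m in refs.values()]
    return {"mean_jaccard": float(np.mean(vals)), "n_references": len(refs)}
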