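"""Permutation-based group statistics and outlier flagging.

Permutation tests stand in for parametric mixed-model inference: the
group x hemisphere interaction statistic is the between-group difference of
the mean within-subject (deprived - intact) difference, with the null built
by permuting group labels. p-values use the add-one rule
``p = (1 + #{|null| >= |observed|}) / (1 + n_perm)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidParameterError

logger = logging.getLogger(__name__)


def flag_outliers(values: Sequence[float]) -> np.ndarray:
    """Mask values further than 3 sample SDs from the mean (strict).

    Flagged values are reported, never silently removed. Constant input has
    SD 0 and flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InvalidParameterError("need at least 3 values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - x.mean()) > 3.0 * sd


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    null_distribution_size: int
    p_value: float
    seed: Optional[int] = None


def _add_one_p(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(np.abs(null) >= abs(observed) - 1e-12))
                 / (1 + null.size))


def perm_interaction_test(deprived: Sequence[float], intact: Sequence[float],
                          groups: Sequence[str], n_perm: int = 1000,
                          seed: int = 0, exact: bool = False,
                          statistic_name: str = "group_x_hemisphere",
                          ) -> PermutationResult:
    """Two-group x two-hemisphere interaction permutation test.

    ``deprived``/``intact`` are paired per-subject values; ``groups`` holds
    exactly two labels. The observed statistic is the difference between the
    two groups of the mean within-subject (deprived - intact) difference.
    ``exact`` enumerates every group-label assignment instead of sampling.
    """
    dep = np.asarray(deprived, dtype=float)
    inta = np.asarray(intact, dtype=float)
    labels = np.asarray(groups)
    if not (dep.shape == inta.shape == labels.shape):
        raise InvalidParameterError("deprived, intact and groups must align")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise InvalidParameterError("exactly two groups required")
    n_a = int((labels == uniq[0]).sum())
    n_b = int((labels == uniq[1]).sum())
    if min(n_a, n_b) < 2:
        raise InvalidParameterError("each group needs at least two subjects")
    if not exact and n_perm < 100:
        logger.warning("n_perm=%d is small; p-values will be coarse", n_perm)

    diffs = dep - inta
    n = diffs.size
    total = diffs.sum()

    def stat_from_sum_a(sum_a: np.ndarray) -> np.ndarray:
        return sum_a / n_a - (total - sum_a) / n_b

    observed = float(stat_from_sum_a(diffs[labels == uniq[0]].sum()))

    if exact:
        sums = np.array([diffs[list(c)].sum()
                         for c in combinations(range(n), n_a)])
        null = stat_from_sum_a(sums)
        n_used = null.size
    else:
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
        null = stat_from_sum_a(diffs[order].sum(axis=1))
        n_used = n_perm

    return PermutationResult(statistic_name=statistic_name, observed=observed,
                             null_distribution_size=n_used,
                             p_value=_add_one_p(null, observed),
                             seed=None if exact else seed)


def perm_group_diff(values_a: Sequence[float], values_b: Sequence[float],
                    n_perm: int = 1000, seed: int = 0,
                    statistic_name: str = "group_difference",
                    ) -> PermutationResult:
    """Two-sided permutation test on the difference of group means."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if min(a.size, b.size) < 2:
        raise InvalidParameterError("each group needs at least two values")
    pooled = np.concatenate([a, b])
    total = pooled.sum()
    observed = a.mean() - b.mean()
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)[:, :a.size]
    sum_a = pooled[order].sum(axis=1)
    null = sum_a / a.size - (total - sum_a) / b.size
    return PermutationResult(statistic_name=statistic_name,
                             observed=float(observed),
                             null_distribution_size=n_perm,
                             p_value=_add_one_p(null, observed), seed=seed)
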