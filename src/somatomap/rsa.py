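"""Cross-validated Mahalanobis (crossnobis) representational analysis.

Multidimensional noise normalisation from GLM residuals (shrinkage toward
the covariance diagonal, analytic optimal lambda), the unbiased crossnobis
RDM over run folds, scalar dissimilarity summaries, and classical MDS for
visualisation. Crossnobis distances are unbiased: their expectation is zero
when two true patterns are identical, so negative values are legitimate
noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg

from .exceptions import (CrossValidationError, InconsistencyError,
                         InvalidParameterError)

logger = logging.getLogger(__name__)


@dataclass
class NoiseCov:
    matrix: np.ndarray
    shrinkage_lambda: float
    source_dof: int


def _shrinkage_lambda(resid: np.ndarray, cov: np.ndarray) -> float:
    """Analytic optimal shrinkage of off-diagonal covariance entries toward
    zero (Schafer & Strimmer 2005), computed from centred residuals."""
    T, P = resid.shape
    x = resid - resid.mean(axis=0)
    # w_t[i,j] = x_ti * x_tj ; var of s_ij across time points
    s = (x.T @ x) / (T - 1)
    w_mean = s * (T - 1) / T
    var_s = np.zeros((P, P))
    for t in range(T):
        dev = np.outer(x[t], x[t]) - w_mean
        var_s += dev * dev
    var_s *= T / ((T - 1) ** 3)
    off = ~np.eye(P, dtype=bool)
    denom = (s[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))


def estimate_noise_cov(residuals_per_run: Sequence[np.ndarray],
                       lam: Optional[float] = None,
                       variance_floor: float = 1e-10) -> NoiseCov:
    """Average run-wise sample covariances and shrink toward the diagonal.

    Each residual block is time x vertex. Zero-variance vertices get their
    diagonal floored (with a warning) so the result stays positive definite.
    """
    if not residuals_per_run:
        raise InvalidParameterError("need at least one run of residuals")
    P = residuals_per_run[0].shape[1]
    covs = []
    dof = 0
    for resid in residuals_per_run:
        T = resid.shape[0]
        if T < 2:
            raise InvalidParameterError("need more than one time point per run")
        if resid.shape[1] != P:
            raise InconsistencyError("runs disagree on vertex count")
        x = resid - resid.mean(axis=0)
        covs.append((x.T @ x) / (T - 1))
        dof += T - 1
    cov = np.mean(covs, axis=0)

    diag = np.diag(cov).copy()
    floor = variance_floor * max(diag.max(), 1.0)
    dead = diag < floor
    if dead.any():
        logger.warning("flooring %d zero-variance vertices in noise covariance",
                       int(dead.sum()))
        diag[dead] = floor
        cov = cov.copy()
        np.fill_diagonal(cov, diag)

    if lam is None:
        stacked = np.vstack([r - r.mean(axis=0) for r in residuals_per_run])
        lam = _shrinkage_lambda(stacked, cov)
    if not 0.0 <= lam <= 1.0:
        raise InvalidParameterError("lambda must lie in [0, 1]")
    shrunk = (1.0 - lam) * cov + lam * np.diag(np.diag(cov))
    return NoiseCov(matrix=shrunk, shrinkage_lambda=float(lam), source_dof=dof)


@dataclass
class RDM:
    conditions: Tuple[str, ...]
    d: np.ndarray                 # symmetric, zero diagonal; may be negative
    roi_label: str = ""
    subject_id: str = ""
    hemisphere: str = ""

    def entry(self, a: str, b: str) -> float:
        return float(self.d[self.conditions.index(a), self.conditions.index(b)])

    def to_long(self) -> List[Tuple[str, str, float]]:
        out = []
        for i, j in combinations(range(len(self.conditions)), 2):
            out.append((self.conditions[i], self.conditions[j], float(self.d[i, j])))
        return out


def crossnobis_rdm(betas_per_run: Sequence[np.ndarray], cov: NoiseCov,
                   conditions: Sequence[str], roi_label: str = "",
                   subject_id: str = "", hemisphere: str = "") -> RDM:
    """Unbiased crossnobis RDM.

    For conditions A, B with run-wise patterns ``b^m`` (condition x vertex):

        d(A,B) = mean over ordered run pairs m != n of
                 (b_A^m - b_B^m)' S^-1 (b_A^n - b_B^n) / P

    with S the shrunk noise covariance and P the vertex count, making RDMs
    comparable across ROI sizes.
    """
    R = len(betas_per_run)
    if R < 2:
        raise CrossValidationError("crossnobis needs at least two runs")
    conditions = tuple(conditions)
    C = len(conditions)
    P = betas_per_run[0].shape[1]
    for b in betas_per_run:
        if b.shape != (C, P):
            raise InconsistencyError("runs disagree on conditions or vertices")
    if cov.matrix.shape != (P, P):
        raise InconsistencyError("noise covariance dimension != vertex count")

    pairs = list(combinations(range(C), 2))
    # per run, all pairwise condition differences: (n_pairs, P)
    deltas = np.stack([np.stack([b[i] - b[j] for i, j in pairs])
                       for b in betas_per_run])          # (R, n_pairs, P)
    cho = linalg.cho_factor(cov.matrix)
    white = np.stack([linalg.cho_solve(cho, d.T).T for d in deltas])

    # sum over ordered m != n of <delta_m, white_n> without the double loop
    S_d = deltas.sum(axis=0)
    S_w = white.sum(axis=0)
    cross_all = (S_d * S_w).sum(axis=1)
    cross_same = (deltas * white).sum(axis=(0, 2))
    d_pairs = (cross_all - cross_same) / (R * (R - 1) * P)

    d = np.zeros((C, C))
    for (i, j), val in zip(pairs, d_pairs):
        d[i, j] = d[j, i] = val
    return RDM(conditions=conditions, d=d, roi_label=roi_label,
               subject_id=subject_id, hemisphere=hemisphere)


def mean_dissimilarity(rdm: RDM, pairs: Optional[Sequence[Tuple[str, str]]] = None,
                       ) -> float:
    """Arithmetic mean of selected off-diagonal RDM entries.

    Defaults to all unique pairs among the four face conditions present in
    the RDM (the six face-face pairs when no thumb is included).
    """
    if pairs is None:
        face = [c for c in rdm.conditions if c != "thumb"]
        pairs = list(combinations(face, 2))
    if not pairs:
        raise InvalidParameterError("empty pair subset")
    vals = []
    for a, b in pairs:
        if a == b:
            raise InvalidParameterError("diagonal pairs are not dissimilarities")
        vals.append(rdm.entry(a, b))
    return float(np.mean(vals))


def classical_mds(rdm: RDM, k: int) -> np.ndarray:
    """Classical (Torgerson) MDS of the RDM into k dimensions.

    Double-centres the squared-distance matrix, eigendecomposes, and keeps
    the top-k non-negative eigenpairs (negative eigenvalues clipped to zero
    and logged). Returns a (conditions, k) coordinate array.
    """
    C = len(rdm.conditions)
    if k >= C:
        raise InvalidParameterError("k must be smaller than the number of conditions")
    D2 = rdm.d ** 2
    J = np.eye(C) - np.ones((C, C)) / C
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if (vals[:k] < -1e-10).any():
        logger.info("clipping negative MDS eigenvalues: %s", vals[vals < 0])
    vals = np.clip(vals, 0.0, None)
    return vecs[:, :k] * np.sqrt(vals[:k])
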