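"""Minimal transparent block-design GLM.

Per-run ordinary least squares on HRF-convolved block regressors, plus
fixed-effects averaging of the run-wise estimates into per-condition
activation maps. Contrasts versus rest are the condition betas themselves
(implicit baseline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import (InconsistencyError, InvalidEventError,
                         InvalidParameterError, RankError)
from .synthetic import Run

NUISANCE_NAMES = ("constant", "drift")


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, scaled to unit peak.

    Difference of two gamma densities (peak ~5 s, undershoot ~15 s,
    undershoot ratio 1/6).
    """
    if tr <= 0:
        raise InvalidParameterError("tr must be positive")
    if duration < 24.0:
        raise InvalidParameterError("duration must cover the undershoot (>= 24 s)")
    t = np.arange(0.0, duration + 1e-9, tr)
    return _hrf_at(t)


def _hrf_at(t: np.ndarray) -> np.ndarray:
    peak = stats.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    matrix: np.ndarray            # (volumes, regressors)
    regressor_names: List[str]
    tr: float

    @property
    def n_conditions(self) -> int:
        return len(self.regressor_names) - sum(
            1 for n in self.regressor_names
            if n in NUISANCE_NAMES or n.endswith("_derivative"))

    def condition_columns(self) -> np.ndarray:
        return self.matrix[:, :self.n_conditions]


def build_design_matrix(events: Sequence[Tuple[str, float, float]], tr: float,
                        n_volumes: int,
                        conditions: Optional[Sequence[str]] = None,
                        add_derivatives: bool = False,
                        oversample: int = 16) -> DesignMatrix:
    """HRF-convolved boxcar per condition plus constant and linear drift.

    ``conditions`` fixes the column order; when omitted it is the order of
    first appearance in ``events``. Temporal-derivative columns are optional
    and appended after the nuisance block.
    """
    run_duration = n_volumes * tr
    for cond, onset, dur in events:
        if onset < 0 or onset + dur > run_duration + 1e-6:
            raise InvalidEventError(
                f"event {cond!r} at {onset}s (+{dur}s) outside run of {run_duration:.2f}s")

    if conditions is None:
        seen: List[str] = []
        for cond, _, _ in events:
            if cond not in seen:
                seen.append(cond)
        conditions = seen
    conditions = list(conditions)

    dt = tr / oversample
    n_fine = int(np.ceil(run_duration / dt)) + 1
    t_fine = np.arange(n_fine) * dt
    hrf = _hrf_at(np.arange(0.0, 32.0 + 1e-9, dt))
    vol_times = np.arange(n_volumes) * tr

    cols = []
    dcols = []
    for cond in conditions:
        box = np.zeros(n_fine)
        for c, onset, dur in events:
            if c == cond:
                box[(t_fine >= onset - 1e-9) & (t_fine < onset + dur - 1e-9)] = 1.0
        conv = np.convolve(box, hrf)[:n_fine] * dt  # approx continuous convolution
        col = np.interp(vol_times, t_fine, conv)
        cols.append(col)
        if add_derivatives:
            dcols.append(np.gradient(col, tr))

    T = n_volumes
    nuisance = [np.ones(T), np.linspace(-1.0, 1.0, T)]
    names = conditions + list(NUISANCE_NAMES)
    all_cols = cols + nuisance
    if add_derivatives:
        all_cols += dcols
        names += [f"{c}_derivative" for c in conditions]
    return DesignMatrix(matrix=np.column_stack(all_cols), regressor_names=names, tr=tr)


@dataclass
class GlmResult:
    betas: np.ndarray             # (conditions, vertices)
    residuals: np.ndarray         # (volumes, vertices)
    dof: int
    conditions: List[str]
    beta_var_unit: np.ndarray     # diag((X'X)^-1) for condition columns
    sigma2: np.ndarray            # per-vertex residual variance
    run_index: int = 0
    subject_id: str = ""
    hemisphere: str = ""


def fit_glm(run: Run, design: DesignMatrix) -> GlmResult:
    """Per-vertex OLS. Raises on rank-deficient designs."""
    X = design.matrix
    Y = run.data.T  # (T, V)
    if X.shape[0] != Y.shape[0]:
        raise InconsistencyError("design rows != run volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankError(f"design matrix rank {rank} < {X.shape[1]} columns")

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y                     # (K, V)
    resid = Y - X @ coef
    dof = X.shape[0] - rank
    n_cond = design.n_conditions
    sigma2 = (resid ** 2).sum(axis=0) / dof
    return GlmResult(
        betas=coef[:n_cond],
        residuals=resid,
        dof=dof,
        conditions=list(design.regressor_names[:n_cond]),
        beta_var_unit=np.diag(xtx_inv)[:n_cond].copy(),
        sigma2=sigma2,
        run_index=run.run_index,
        subject_id=run.subject_id,
        hemisphere=run.hemisphere,
    )


@dataclass
class ActivationMap:
    values: np.ndarray            # per mesh vertex
    condition: str
    kind: str                     # {"beta_mean", "t_like"}


def average_runs(results: Sequence[GlmResult],
                 kind: str = "t_like") -> Dict[str, ActivationMap]:
    """Fixed-effects average of run-wise betas into one map per condition.

    ``beta_mean`` is the plain mean of run betas; ``t_like`` divides it by
    the residual-derived standard error of that mean (the winner statistic).
    """
    if not results:
        raise InvalidParameterError("need at least one run")
    conds = results[0].conditions
    for r in results[1:]:
        if r.conditions != conds:
            raise InconsistencyError("runs disagree on conditions")
    if kind not in ("beta_mean", "t_like"):
        raise InvalidParameterError(f"unknown statistic kind {kind!r}")

    betas = np.stack([r.betas for r in results])       # (R, C, V)
    beta_mean = betas.mean(axis=0)
    if kind == "beta_mean":
        return {c: ActivationMap(beta_mean[i].copy(), c, kind)
                for i, c in enumerate(conds)}

    R = len(results)
    var_sum = np.zeros_like(beta_mean)
    for r in results:
        var_sum += np.outer(r.beta_var_unit, np.ones(r.sigma2.shape)) * r.sigma2
    se = np.sqrt(var_sum) / R
    se = np.maximum(se, 1e-12)
    t_like = beta_mean / se
    return {c: ActivationMap(t_like[i].copy(), c, kind) for i, c in enumerate(conds)}
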