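"""Descriptor-to-myelin statistics.

Two complementary views of how the hemodynamic descriptors relate to
regional myelin content across a cohort:

- a Spearman rank-correlation matrix over all variables, with
  Benjamini-Hochberg adjustment of the unique off-diagonal p-values;
- per-region stepwise multiple linear regression of myelin on the three
  descriptors (bidirectional selection with entry/removal p thresholds,
  the convention of the classic stepwise routines), reported with
  per-coefficient t tests and an F test of the final model against the
  constant model.

Ordinary least squares fits are delegated to statsmodels; the selection
loop, the exact small-n Spearman p-values and the matrix bookkeeping are
implemented here.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationMatrix",
    "StepwiseModel",
    "spearman_matrix",
    "bh_adjust",
    "stepwise_regression",
    "f_test_vs_constant",
    "DESCRIPTORS",
]

logger = logging.getLogger(__name__)

DESCRIPTORS = ("n_active_pixels", "delta_cbv_pct", "rise_time_s")
EXACT_P_MAX_N = 8  # below this, Spearman p by full permutation enumeration


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with raw and adjusted p-values."""

    variables: tuple[str, ...]
    rho: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    n_pairs: np.ndarray  # complete observations per pair
    method: str = "spearman"
    adjustment: str = "benjamini-hochberg"

    def to_frame(self) -> pd.DataFrame:
        """Long-format (var_a, var_b, rho, p_raw, p_adj, n) table of unique pairs."""
        rows = []
        k = len(self.variables)
        for i, j in itertools.combinations(range(k), 2):
            rows.append({
                "var_a": self.variables[i],
                "var_b": self.variables[j],
                "rho": self.rho[i, j],
                "p_raw": self.p_raw[i, j],
                "p_adjusted": self.p_adjusted[i, j],
                "n": int(self.n_pairs[i, j]),
            })
        return pd.DataFrame(rows)


@dataclass
class StepwiseModel:
    """Final model of a stepwise selection run for one myelin region."""

    response: str
    selected_predictors: tuple[str, ...]
    intercept: float
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    t_pvalues: dict[str, float]
    f_statistic: float
    f_p_vs_constant: float
    n_used: int
    n_dropped_missing: int
    settings: dict = field(default_factory=dict)
    _results: object = None  # statsmodels results of the final fit

    @property
    def is_constant(self) -> bool:
        return not self.selected_predictors


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by enumerating all permutations of one rank vector."""
    n = len(rx)
    sx = rx - rx.mean()
    denom = math.sqrt(float((sx ** 2).sum()) * float(((ry - ry.mean()) ** 2).sum()))
    if denom == 0:
        return float("nan")
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        r = float(sx @ (np.asarray(perm) - ry.mean())) / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return float("nan"), float("nan"), n
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        logger.warning("spearman: constant variable, correlation undefined")
        return float("nan"), float("nan"), n
    rho, p = scipy.stats.spearmanr(xs, ys)
    if n < EXACT_P_MAX_N:
        rx = scipy.stats.rankdata(xs)
        ry = scipy.stats.rankdata(ys)
        p = _exact_spearman_p(rx, ry, rho)
    return float(rho), float(p), n


def spearman_matrix(table: pd.DataFrame, variables: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise-complete Spearman matrix with BH-adjusted p-values.

    Rank correlations use midranks for ties; p-values come from the
    t approximation for n >= 8 and the exact permutation distribution for
    smaller pair counts.  Only the unique off-diagonal pairs enter the
    Benjamini-Hochberg family.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(variables)
    if k < 2:
        raise ValueError("need at least two variables")
    rho = np.eye(k)
    p_raw = np.zeros((k, k))
    n_pairs = np.zeros((k, k), dtype=int)
    for i in range(k):
        n_pairs[i, i] = table[variables[i]].notna().sum()
    for i, j in itertools.combinations(range(k), 2):
        r, p, n = _spearman_pair(
            table[variables[i]].to_numpy(dtype=float),
            table[variables[j]].to_numpy(dtype=float),
        )
        rho[i, j] = rho[j, i] = r
        p_raw[i, j] = p_raw[j, i] = p
        n_pairs[i, j] = n_pairs[j, i] = n
    iu = np.triu_indices(k, 1)
    flat = p_raw[iu]
    adj_flat = np.full_like(flat, np.nan)
    ok = np.isfinite(flat)
    if ok.any():
        adj_flat[ok] = bh_adjust(flat[ok])
    p_adj = np.zeros((k, k))
    p_adj[iu] = adj_flat
    p_adj = p_adj + p_adj.T
    return CorrelationMatrix(tuple(variables), rho, p_raw, p_adj, n_pairs)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted ascending, ``adj_(i) = min_{j>=i} m * p_(j) / j`` capped at 1,
    mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _fit_ols(y: np.ndarray, x: np.ndarray, names: list[str]):
    design = sm.add_constant(pd.DataFrame(x, columns=list(names)), has_constant="add")
    return sm.OLS(y, design).fit()


def stepwise_regression(
    table: pd.DataFrame,
    response: str,
    candidates: tuple[str, ...] = DESCRIPTORS,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    backward_only: bool = False,
) -> StepwiseModel:
    """Stepwise OLS of ``response`` on the descriptor candidates.

    Bidirectional selection starting from the constant model: at each
    round, the candidate whose coefficient would have the smallest p-value
    is added if that p-value is below ``p_enter``; then any retained
    predictor whose p-value exceeds ``p_remove`` is removed (worst first).
    ``backward_only`` starts instead from the full model and only removes.
    Rows with missing values in the response or any candidate are excluded
    listwise.  Collinear candidates are dropped with a warning.
    """
    if not 0 <= p_enter <= 1 or not 0 <= p_remove <= 1:
        raise ValueError("p thresholds must lie in [0, 1]")
    cols = [response, *candidates]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"columns not in table: {missing_cols}")
    data = table[cols].apply(pd.to_numeric, errors="coerce")
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    if n_dropped:
        logger.info("stepwise(%s): %d rows dropped for missing values", response, n_dropped)
    n = len(complete)
    if n <= len(candidates) + 2:
        raise ValueError(f"need more than {len(candidates) + 2} complete rows, got {n}")
    y = complete[response].to_numpy()

    usable = []
    for c in candidates:
        x = complete[c].to_numpy()
        trial = np.column_stack([complete[u].to_numpy() for u in usable] + [x, np.ones(n)])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            logger.warning("stepwise(%s): dropping collinear candidate %s", response, c)
            continue
        usable.append(c)

    current: list[str] = list(usable) if backward_only else []
    seen = set()
    for _ in range(4 * len(usable) + 4):
        state = tuple(sorted(current))
        if state in seen:
            break
        seen.add(state)
        changed = False
        if not backward_only:
            best_p, best_c = None, None
            for c in usable:
                if c in current:
                    continue
                res = _fit_ols(y, complete[current + [c]].to_numpy(), current + [c])
                p = res.pvalues[c]
                if best_p is None or p < best_p:
                    best_p, best_c = p, c
            if best_c is not None and best_p < p_enter:
                current.append(best_c)
                changed = True
        while current:
            res = _fit_ols(y, complete[current].to_numpy(), current)
            pvals = res.pvalues[current]
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                current.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    settings = {"p_enter": p_enter, "p_remove": p_remove, "backward_only": backward_only}
    if not current:
        logger.info("stepwise(%s): no predictor entered; constant model", response)
        const_res = sm.OLS(y, np.ones((n, 1))).fit()
        return StepwiseModel(
            response=response, selected_predictors=(),
            intercept=float(const_res.params[0]), estimates={}, standard_errors={},
            t_pvalues={}, f_statistic=float("nan"), f_p_vs_constant=1.0,
            n_used=n, n_dropped_missing=n_dropped, settings=settings, _results=const_res,
        )
    res = _fit_ols(y, complete[current].to_numpy(), current)
    return StepwiseModel(
        response=response,
        selected_predictors=tuple(current),
        intercept=float(res.params["const"]),
        estimates={c: float(res.params[c]) for c in current},
        standard_errors={c: float(res.bse[c]) for c in current},
        t_pvalues={c: float(res.pvalues[c]) for c in current},
        f_statistic=float(res.fvalue),
        f_p_vs_constant=float(res.f_pvalue),
        n_used=n,
        n_dropped_missing=n_dropped,
        settings=settings,
        _results=res,
    )


def f_test_vs_constant(model: StepwiseModel) -> float:
    """p-value of the F test of the final model against the constant model."""
    if model.is_constant:
        raise ValueError("model has no predictors; F test against itself is undefined")
    return model.f_p_vs_constant
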