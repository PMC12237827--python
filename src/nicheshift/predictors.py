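"""Predictor screening: permutation importance and collinearity filtering.

A preliminary suitability model fitted on the native population scores each
candidate climate variable by permutation importance (1 minus the correlation
between intact and column-shuffled predictions, averaged over iterations).
Collinear pairs (|r| >= 0.7) are then resolved greedily, dropping the
lower-importance member, so the retained set feeds the ensemble models
without redundancy. Pearson's r is used for a pair only when both variables
pass a Shapiro-Wilk normality check; otherwise Spearman's rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import ClimateStack
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)

_SHAPIRO_CAP = 5000  # Shapiro-Wilk loses calibration above ~5000 samples


class EmptyDataError(ValueError):
    pass


@dataclass
class ImportanceTable:
    """Variable -> importance value (IV) in [0, 1]."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        for name, iv in self.entries.items():
            if not 0 <= iv <= 1:
                raise ValueError(f"IV out of [0,1] for {name}: {iv}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"variable": list(self.entries), "IV": list(self.entries.values())}
        )
        return df.sort_values(["IV", "variable"], ascending=[False, True]).reset_index(
            drop=True
        )


def extract_env(occ: OccurrenceSet, stack: ClimateStack) -> np.ndarray:
    """(n_points, V) environment matrix at the points' cells.

    Off-grid and nodata points are dropped with a logged count.
    """
    if len(occ) == 0:
        raise EmptyDataError("no occurrence points to extract")
    row, col = stack.grid.cell_of(occ.lon, occ.lat)
    on = row >= 0
    on[on] &= ~stack.nodata_mask[row[on], col[on]]
    dropped = int((~on).sum())
    if dropped:
        logger.warning("extract_env: dropped %d off-grid/nodata points", dropped)
    if not on.any():
        raise EmptyDataError("all points fall off-grid or on nodata")
    return stack.env_at(row[on], col[on])


def permutation_importance(
    model,
    env: np.ndarray,
    variable_names: list[str],
    n_iter: int = 5,
    seed: int = 0,
) -> ImportanceTable:
    """IV(v) = 1 - mean_k cor(score(X), score(X with column v shuffled)).

    ``model`` must expose ``predict_score(env) -> scores in [0,1]``.
    Negative IVs are clipped to 0; constant predictions yield all-zero IVs
    with a warning.
    """
    env = np.asarray(env, dtype=float)
    rng = np.random.default_rng(seed)
    base = np.asarray(model.predict_score(env), dtype=float)
    if np.std(base) == 0:
        logger.warning("constant predictions: importance undefined, returning zeros")
        return ImportanceTable({v: 0.0 for v in variable_names})
    entries = {}
    for j, name in enumerate(variable_names):
        cors = []
        for _ in range(n_iter):
            shuffled = env.copy()
            shuffled[:, j] = rng.permutation(shuffled[:, j])
            pred = np.asarray(model.predict_score(shuffled), dtype=float)
            if np.std(pred) == 0:
                cors.append(0.0)
            else:
                cors.append(float(np.corrcoef(base, pred)[0, 1]))
        iv = float(np.clip(1.0 - np.mean(cors), 0.0, 1.0))
        entries[name] = 0.0 if iv < 1e-10 else iv
    return ImportanceTable(entries)


def _is_normal(x: np.ndarray, alpha: float = 0.05, seed: int = 0) -> bool:
    if np.ptp(x) == 0:
        return False
    if x.size > _SHAPIRO_CAP:
        x = np.random.default_rng(seed).choice(x, _SHAPIRO_CAP, replace=False)
    return stats.shapiro(x).pvalue > alpha


def correlation_matrix(
    env: np.ndarray, variable_names: list[str] | None = None, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation with a per-pair method choice.

    Pearson when both members of the pair pass Shapiro-Wilk normality at
    ``alpha`` (checked per variable, applied per pair); Spearman otherwise.
    Constant columns get coefficient 0 with a warning. Returns (coefficients,
    method flags) as DataFrames indexed by variable name.
    """
    env = np.asarray(env, dtype=float)
    if env.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    v = env.shape[1]
    names = variable_names or [f"v{j}" for j in range(v)]
    normal = [_is_normal(env[:, j], alpha) for j in range(v)]
    corr = np.eye(v)
    method = np.full((v, v), "pearson", dtype=object)
    for i in range(v):
        for j in range(i + 1, v):
            xi, xj = env[:, i], env[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                logger.warning("constant column in pair (%s, %s); r set to 0", names[i], names[j])
                r, m = 0.0, "undefined"
            elif normal[i] and normal[j]:
                r, m = stats.pearsonr(xi, xj)[0], "pearson"
            else:
                r, m = stats.spearmanr(xi, xj)[0], "spearman"
            corr[i, j] = corr[j, i] = r
            method[i, j] = method[j, i] = m
    return (
        pd.DataFrame(corr, index=names, columns=names),
        pd.DataFrame(method, index=names, columns=names),
    )


def collinearity_filter(
    corr: pd.DataFrame, iv: ImportanceTable, threshold: float = 0.7
) -> list[str]:
    """Drop the lower-IV member of each |r| >= threshold pair, worst pair
    first, until no retained pair is collinear. Returns the retained
    variables ordered by descending IV (name order on ties)."""
    names = list(corr.index)
    if set(names) != set(iv.entries):
        raise ValueError("correlation matrix and importance table cover different variables")
    retained = set(names)
    c = corr.to_numpy()
    idx = {n: k for k, n in enumerate(names)}
    while True:
        worst, worst_r = None, threshold
        for a in sorted(retained):
            for b in sorted(retained):
                if a >= b:
                    continue
                r = abs(c[idx[a], idx[b]])
                if r >= worst_r and (worst is None or r > worst_r):
                    worst, worst_r = (a, b), r
        if worst is None:
            break
        a, b = worst
        # drop the lower-IV member; name order breaks IV ties (keep earlier)
        drop = b if (iv.entries[a], a) >= (iv.entries[b], b) else a
        if iv.entries[a] == iv.entries[b]:
            drop = max(a, b)
        retained.discard(drop)
        logger.info("collinearity: dropped %s (|r|=%.3f with %s)", drop, worst_r, a if drop == b else b)
    out = sorted(retained, key=lambda n: (-iv.entries[n], n))
    # defining postcondition: no retained pair is collinear
    for a in out:
        for b in out:
            if a < b:
                assert abs(c[idx[a], idx[b]]) < threshold
    return out
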