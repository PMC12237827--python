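"""Ensemble suitability modelling for one population (native or introduced).

The model follows standard ensemble SDM practice: presences plus randomly
drawn pseudo-absences (PAs), several algorithms fitted per PA replicate,
member reliability measured by stratified 5-fold cross-validation (AUC and
TSS averaged over folds), members failing the AUC >= 0.8 / TSS >= 0.6 gates
excluded, and the survivors combined with TSS-proportional weights. The
ensemble suitability surface is binarised at the threshold maximising
sensitivity + specificity (MSS) to produce the potential-range mask.

:class:`EnsembleSDM` is the model object; :meth:`EnsembleSDM.fit` returns an
:class:`EnsembleSDMResults` carrying the member table, weights, evaluation
metrics and prediction methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .grids import ClimateStack, RangeMask, SuitabilityMap
from .occurrences import OccurrenceSet
from .predictors import extract_env

logger = logging.getLogger(__name__)

DEFAULT_ALGORITHMS = ("glm", "glm_quadratic", "random_forest", "gbm", "envelope")


class UndefinedMetricError(ValueError):
    """AUC/TSS need both classes present."""


class NoValidModelError(RuntimeError):
    """Every ensemble member failed the reliability gates."""


@dataclass
class ModelEval:
    """Evaluation of one scored presence/absence set at the MSS threshold."""

    auc: float
    tss: float
    sensitivity: float
    specificity: float
    mss_threshold: float


# --- metrics ------------------------------------------------------------------


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC: P(presence outscores absence), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both presences and absences")
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def mss_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, ModelEval]:
    """Threshold maximising sensitivity + specificity.

    Candidates are midpoints between consecutive distinct sorted scores plus
    the extremes; the lowest maximising threshold is returned. Cells score as
    presence when score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("MSS needs both presences and absences")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2
    candidates = np.concatenate([[distinct[0] - 1e-9], mids, [distinct[-1] + 1e-9]])
    best_t, best_eval = None, None
    for t in candidates:
        pred = scores >= t
        sens = float((pred & labels).sum() / n_pos)
        spec = float((~pred & ~labels).sum() / n_neg)
        if best_eval is None or sens + spec > best_eval.sensitivity + best_eval.specificity + 1e-12:
            best_t = float(t)
            best_eval = ModelEval(
                auc=np.nan, tss=sens + spec - 1.0,
                sensitivity=sens, specificity=spec, mss_threshold=float(t),
            )
    best_eval.auc = auc(scores, labels)
    return best_t, best_eval


# --- data assembly ------------------------------------------------------------


def generate_pseudo_absences(
    occ: OccurrenceSet,
    stack: ClimateStack,
    n_reps: int = 5,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per replicate, an (n_PA, V) environment matrix of pseudo-absences.

    n_PA matches the presence count when it exceeds 1000, else 1000. Cells
    are drawn uniformly without replacement from off-nodata cells that hold
    no presence; draws are deterministic under (seed, replicate).
    """
    rows, cols = stack.valid_cells()
    prow, pcol = stack.grid.cell_of(occ.lon, occ.lat)
    presence_flat = set(map(tuple, np.column_stack([prow, pcol]).tolist()))
    free = np.array(
        [k for k, rc in enumerate(zip(rows.tolist(), cols.tolist())) if rc not in presence_flat]
    )
    if free.size == 0:
        raise ValueError("no non-presence cells available for pseudo-absences")
    n_presence = len(occ)
    n_pa = n_presence if n_presence > 1000 else 1000
    if n_pa > free.size:
        logger.warning("capping pseudo-absences at %d available cells", free.size)
        n_pa = free.size
    reps = []
    for r in range(n_reps):
        rng = np.random.default_rng((seed, r))
        pick = rng.choice(free, size=n_pa, replace=False)
        reps.append(stack.env_at(rows[pick], cols[pick]))
    return reps


def kfold_split(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold label per row, stratified by presence/absence.

    Falls back to unstratified folds (with a warning) when a class has fewer
    than k members.
    """
    labels = np.asarray(labels).astype(bool)
    n = labels.size
    if n < k:
        raise ValueError("need at least k rows")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if labels.sum() < k or (~labels).sum() < k:
        logger.warning("a class has < %d members; unstratified folds", k)
        order = rng.permutation(n)
        folds[order] = np.arange(n) % k
        return folds
    for cls in (True, False):
        idx = np.nonzero(labels == cls)[0]
        order = rng.permutation(idx.size)
        folds[idx[order]] = np.arange(idx.size) % k
    return folds


# --- members ------------------------------------------------------------------


class EnvelopeModel:
    """Rectilinear percentile climate envelope.

    Scores 1 inside the presence 5-95% envelope on every variable and
    declines linearly outside, reaching 0 one envelope-width beyond it;
    per-variable scores multiply.
    """

    def __init__(self, lo_pct: float = 5.0, hi_pct: float = 95.0):
        self.lo_pct, self.hi_pct = lo_pct, hi_pct

    def fit(self, x: np.ndarray, y: np.ndarray):
        pres = np.asarray(x, dtype=float)[np.asarray(y).astype(bool)]
        self.lo_ = np.percentile(pres, self.lo_pct, axis=0)
        self.hi_ = np.percentile(pres, self.hi_pct, axis=0)
        self.width_ = np.maximum(self.hi_ - self.lo_, 1e-12)
        return self

    def predict_score(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        excess = np.maximum.reduce([
            (self.lo_ - x) / self.width_,
            (x - self.hi_) / self.width_,
            np.zeros_like(x),
        ])
        return np.prod(np.clip(1.0 - excess, 0.0, 1.0), axis=1)


class SklearnMember:
    """Adapter giving sklearn classifiers the predict_score interface."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, x, y):
        self.estimator.fit(x, np.asarray(y).astype(int))
        return self

    def predict_score(self, x):
        return self.estimator.predict_proba(np.atleast_2d(x))[:, 1]


def fit_member(x: np.ndarray, y: np.ndarray, algorithm: str, seed: int = 0):
    """Fit one ensemble member; returns an object with predict_score."""
    if algorithm == "glm":
        est = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000, C=1.0))
        member = SklearnMember(est)
    elif algorithm == "glm_quadratic":
        est = make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(max_iter=1000, C=1.0),
        )
        member = SklearnMember(est)
    elif algorithm == "random_forest":
        est = RandomForestClassifier(
            n_estimators=100, min_samples_leaf=5, random_state=seed, n_jobs=1
        )
        member = SklearnMember(est)
    elif algorithm == "gbm":
        est = GradientBoostingClassifier(
            n_estimators=100, max_depth=3, random_state=seed
        )
        member = SklearnMember(est)
    elif algorithm == "envelope":
        member = EnvelopeModel()
    else:
        raise ValueError(f"unknown algorithm: {algorithm}")
    return member.fit(x, y)


# --- ensemble model object ----------------------------------------------------


@dataclass
class EnsembleSDM:
    """Ensemble suitability model for one population.

    Parameters
    ----------
    occ : presences of one population (already cleaned/rarefied).
    stack : calibration climate stack; its extent is the accessible area.
    variables : retained predictor names (default: all stack layers).
    algorithms : member algorithms (default five spanning statistical, ML
        and envelope families).
    n_pa_reps : pseudo-absence replicates.
    k : cross-validation folds.
    auc_min, tss_min : reliability gates.
    gate_mode : "any" excludes a member failing either gate; "all" only
        members failing both.
    """

    occ: OccurrenceSet
    stack: ClimateStack
    variables: list[str] | None = None
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    n_pa_reps: int = 5
    k: int = 5
    auc_min: float = 0.8
    tss_min: float = 0.6
    gate_mode: str = "any"

    def __post_init__(self) -> None:
        if self.variables is None:
            self.variables = list(self.stack.layer_names)
        self._var_idx = [self.stack.layer_names.index(v) for v in self.variables]

    def _env(self, full: np.ndarray) -> np.ndarray:
        return full[:, self._var_idx]

    def fit(self, seed: int = 0) -> "EnsembleSDMResults":
        presence_env = self._env(extract_env(self.occ, self.stack))
        pa_reps = [self._env(e) for e in generate_pseudo_absences(
            self.occ, self.stack, self.n_pa_reps, seed
        )]
        rows = []
        fitted = {}
        for rep, pa_env in enumerate(pa_reps):
            x = np.vstack([presence_env, pa_env])
            y = np.concatenate([np.ones(len(presence_env)), np.zeros(len(pa_env))])
            folds = kfold_split(y, self.k, seed=(seed * 1009 + rep) % 2**31)
            for alg in self.algorithms:
                aucs, tsss = [], []
                for f in range(self.k):
                    tr, te = folds != f, folds == f
                    try:
                        m = fit_member(x[tr], y[tr], alg, seed=(seed + rep) % 2**31)
                    except Exception as exc:  # singular design etc.
                        logger.warning("member %s rep %d fold %d failed: %s", alg, rep, f, exc)
                        continue
                    s = m.predict_score(x[te])
                    aucs.append(auc(s, y[te]))
                    _, ev = mss_threshold(s, y[te])
                    tsss.append(ev.tss)
                if not aucs:
                    rows.append((alg, rep, np.nan, np.nan, False, 0.0))
                    continue
                cv_auc, cv_tss = float(np.mean(aucs)), float(np.mean(tsss))
                final = fit_member(x, y, alg, seed=(seed + rep) % 2**31)
                fitted[(alg, rep)] = final
                rows.append((alg, rep, cv_auc, cv_tss, True, 0.0))
        members = pd.DataFrame(
            rows, columns=["algorithm", "replicate", "auc", "tss", "fitted", "weight"]
        )
        members = _gate_and_weight(members, self.auc_min, self.tss_min, self.gate_mode)
        return EnsembleSDMResults(
            model=self,
            members=members,
            fitted=fitted,
            presence_env=presence_env,
            pa_envs=pa_reps,
        )


def _gate_and_weight(
    members: pd.DataFrame, auc_min: float, tss_min: float, gate_mode: str
) -> pd.DataFrame:
    members = members.copy()
    fail_auc = members["auc"] < auc_min
    fail_tss = members["tss"] < tss_min
    failed = (fail_auc | fail_tss) if gate_mode == "any" else (fail_auc & fail_tss)
    failed |= ~members["fitted"] | members["auc"].isna()
    members["retained"] = ~failed
    if not members["retained"].any():
        raise NoValidModelError(
            "all ensemble members failed the AUC/TSS reliability gates"
        )
    w = members["tss"].where(members["retained"], 0.0).clip(lower=0.0)
    total = w.sum()
    if total <= 0:  # retained members but all TSS 0: equal weights
        w = members["retained"].astype(float)
        total = w.sum()
    members["weight"] = w / total
    return members


def gate_and_weight(
    members: pd.DataFrame, auc_min: float = 0.8, tss_min: float = 0.6,
    gate_mode: str = "any",
) -> pd.DataFrame:
    """Apply reliability gates and TSS-proportional weights to a member table
    with columns algorithm, replicate, auc, tss (and optionally fitted)."""
    members = members.copy()
    if "fitted" not in members:
        members["fitted"] = True
    if "weight" not in members:
        members["weight"] = 0.0
    return _gate_and_weight(members, auc_min, tss_min, gate_mode)


@dataclass
class EnsembleSDMResults:
    """Fitted ensemble: member table, weights, prediction and binarisation."""

    model: EnsembleSDM
    members: pd.DataFrame
    fitted: dict[tuple[str, int], object]
    presence_env: np.ndarray
    pa_envs: list[np.ndarray]
    _mss: tuple[float, ModelEval] | None = field(default=None, repr=False)

    @property
    def weights(self) -> pd.Series:
        return self.members.set_index(["algorithm", "replicate"])["weight"]

    def predict_score(self, env: np.ndarray) -> np.ndarray:
        """Weighted-mean member score for (n, V) environment rows."""
        env = np.atleast_2d(np.asarray(env, dtype=float))
        out = np.zeros(env.shape[0])
        for (alg, rep), w in self.weights.items():
            if w > 0:
                out += w * np.asarray(self.fitted[(alg, rep)].predict_score(env))
        return out

    def predict(self, stack: ClimateStack | None = None) -> SuitabilityMap:
        """Ensemble suitability surface over the stack (default: calibration)."""
        stack = stack or self.model.stack
        idx = [stack.layer_names.index(v) for v in self.model.variables]
        rows, cols = stack.valid_cells()
        scores = self.predict_score(stack.env_at(rows, cols)[:, idx])
        values = np.zeros(stack.grid.shape)
        values[rows, cols] = np.clip(scores, 0.0, 1.0)
        return SuitabilityMap(stack.grid, values, stack.nodata_mask.copy())

    def ensemble_mss(self) -> tuple[float, ModelEval]:
        """MSS threshold of the ensemble scores on pooled presences + PAs."""
        if self._mss is None:
            pa = np.vstack(self.pa_envs)
            scores = np.concatenate(
                [self.predict_score(self.presence_env), self.predict_score(pa)]
            )
            labels = np.concatenate([np.ones(len(self.presence_env)), np.zeros(len(pa))])
            self._mss = mss_threshold(scores, labels)
        return self._mss

    def range_mask(self, stack: ClimateStack | None = None,
                   threshold: float | None = None) -> RangeMask:
        """Binary potential range at the MSS threshold (or an explicit one)."""
        if threshold is None:
            threshold, _ = self.ensemble_mss()
        return binarize(self.predict(stack), threshold)

    def summary(self) -> str:
        t, ev = self.ensemble_mss()
        lines = [
            "Ensemble SDM results",
            "====================",
            f"presences: {len(self.presence_env)}   "
            f"PA replicates: {len(self.pa_envs)} x {len(self.pa_envs[0])}",
            f"members retained: {int(self.members['retained'].sum())}/{len(self.members)}"
            f"   gates: AUC >= {self.model.auc_min}, TSS >= {self.model.tss_min}",
            f"ensemble MSS threshold: {t:.3f}  (sens {ev.sensitivity:.3f}, "
            f"spec {ev.specificity:.3f}, TSS {ev.tss:.3f}, AUC {ev.auc:.3f})",
            "",
            self.members.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


def binarize(smap: SuitabilityMap, threshold: float) -> RangeMask:
    """Cells with suitability >= threshold (nodata cells false)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    values = (smap.values >= threshold) & ~smap.nodata_mask
    return RangeMask(smap.grid, values)
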