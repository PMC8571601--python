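"""Candidate-model tuning grid and evaluation metrics.

Feature-class × regularization-multiplier grids are evaluated under
10-fold random or 4-quadrant spatial-block cross-validation, scored by
test AUC, AUC_DIFF (overfitting), the 10% training-omission rate, and the
sample-size-corrected Akaike criterion (AICc) computed from the raw Gibbs
likelihood over landscape cells. Two selection rules are provided: lowest
AICc, and the sequential rule (lowest 10% omission, then highest test AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grid import LayerStack
from .maxent import FeatureSpec, SuitabilityModel, fit as fit_model
from .occurrences import OccurrenceSet

#: Canonical feature-class sets, simplest first (tie-break order).
FEATURE_GRID = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")
#: Regularization multipliers 0.5 … 8.0 in 0.5 steps.
RM_GRID = tuple(np.arange(0.5, 8.01, 0.5).round(1))
CV_SCHEMES = ("kfold10", "spatial_block")


def partition(presences: OccurrenceSet, scheme: str, seed: int,
              n_folds: int = 10) -> np.ndarray:
    """Assign a cross-validation fold id to every presence.

    ``kfold10``: random folds of near-equal size. ``spatial_block``: four
    folds split at the median longitude and median latitude (quadrants).
    """
    n = len(presences)
    if scheme == "kfold10":
        if n < n_folds:
            raise ValueError(f"{n} presences < {n_folds} folds")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(order, n_folds)):
            folds[chunk] = f
        return folds
    if scheme == "spatial_block":
        if n < 4:
            raise ValueError(f"{n} presences < 4 spatial blocks")
        med_lon = float(np.median(presences.lons))
        med_lat = float(np.median(presences.lats))
        east = presences.lons >= med_lon
        north = presences.lats >= med_lat
        return (2 * north + east).astype(int)
    raise ValueError(f"unknown CV scheme: {scheme!r}")


def auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-based AUC: probability a random positive outranks a random
    negative, ties counted ½ (Mann–Whitney form)."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score vectors must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def tss(tp: int, fn: int, tn: int, fp: int) -> float:
    """True Skill Statistic: sensitivity + specificity − 1."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("TSS undefined with an empty class")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def mtss_threshold(presence_scores: np.ndarray,
                   background_scores: np.ndarray) -> float:
    """Threshold maximizing training sensitivity (presences ≥ t) plus
    specificity (background < t), scanned over the distinct observed
    scores; ties resolved to the lowest such threshold."""
    pres = np.asarray(presence_scores, float)
    bg = np.asarray(background_scores, float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score vectors must be non-empty")
    cand = np.unique(np.concatenate([pres, bg]))
    sens = (pres[None, :] >= cand[:, None]).mean(axis=1)
    spec = (bg[None, :] < cand[:, None]).mean(axis=1)
    total = sens + spec
    return float(cand[np.argmax(total)])


def omission10(train_scores: np.ndarray, test_scores: np.ndarray,
               q: float = 0.10) -> float:
    """Fraction of test presences scoring below the threshold that omits
    the lowest ``q`` of training presences (linear-interpolated quantile)."""
    train = np.asarray(train_scores, float)
    test = np.asarray(test_scores, float)
    if train.size == 0 or test.size == 0:
        raise ValueError("both score vectors must be non-empty")
    t = np.quantile(train, q, method="linear")
    return float(np.mean(test < t))


def aicc(model: SuitabilityModel, presences: OccurrenceSet,
         stack: LayerStack) -> float:
    """Sample-size-corrected AIC from the raw Gibbs likelihood.

    ln L = Σ over presence cells of ln(raw(x)/Σ_cells raw); k counts the
    non-zero coefficients; n is the presence-cell count. Undefined (error)
    when n ≤ k + 1.
    """
    sub = stack.subset(model.var_names)
    ok = ~sub.union_nodata
    X_cells = np.column_stack([sub[v].values[ok] for v in model.var_names])
    eta_cells = model.linear_predictor(X_cells)
    log_z = logsumexp(eta_cells)
    X_pres, _, _ = sub.values_at(presences.lons, presences.lats, model.var_names)
    eta_pres = model.linear_predictor(X_pres)
    ln_l = float((eta_pres - log_z).sum())
    k = model.k_params
    n = len(eta_pres)
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} presences ≤ k+1={k + 1}")
    return 2 * k - 2 * ln_l + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class CandidateResult:
    """One tuning-grid cell: feature classes × RM × CV scheme."""

    feature_classes: str
    rm: float
    cv_scheme: str
    mean_test_auc: float
    train_auc: float
    auc_diff: float
    or10: float
    aicc: float
    k_params: int

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_candidate(presences: OccurrenceSet, background: OccurrenceSet,
                       stack: LayerStack, feature_classes: str, rm: float,
                       cv_scheme: str, seed: int,
                       var_names: list[str] | None = None,
                       **fit_kw) -> CandidateResult:
    """Cross-validate one (feature set, RM) combination.

    Per-fold models score test presences against the fixed background;
    reported metrics are fold means. AICc and k come from a full-data fit.
    """
    spec = FeatureSpec.from_string(feature_classes)
    n_folds = 10 if cv_scheme == "kfold10" else 4
    folds = partition(presences, cv_scheme, seed, n_folds=n_folds)
    test_aucs, train_aucs, or10s = [], [], []
    for f in np.unique(folds):
        train = presences.subset(folds != f)
        test = presences.subset(folds == f)
        if len(test) == 0 or len(train) == 0:
            continue
        m = fit_model(train, background, stack, spec=spec, rm=rm,
                      var_names=var_names, **fit_kw)
        bg_scores = m.score_points(background, stack, "raw")
        tr_scores = m.score_points(train, stack, "raw")
        te_scores = m.score_points(test, stack, "raw")
        train_aucs.append(auc(tr_scores, bg_scores))
        test_aucs.append(auc(te_scores, bg_scores))
        or10s.append(omission10(tr_scores, te_scores))
    full = fit_model(presences, background, stack, spec=spec, rm=rm,
                     var_names=var_names, **fit_kw)
    try:
        a = aicc(full, presences, stack)
    except ValueError:
        a = float("inf")
    mean_test = float(np.mean(test_aucs))
    mean_train = float(np.mean(train_aucs))
    return CandidateResult(
        feature_classes=FeatureSpec.from_string(feature_classes).tag,
        rm=float(rm), cv_scheme=cv_scheme,
        mean_test_auc=mean_test, train_auc=mean_train,
        auc_diff=mean_train - mean_test,
        or10=float(np.mean(or10s)), aicc=float(a), k_params=full.k_params)


def tune(presences: OccurrenceSet, background: OccurrenceSet,
         stack: LayerStack, feature_grid=FEATURE_GRID, rm_grid=RM_GRID,
         schemes=CV_SCHEMES, seed: int = 0,
         var_names: list[str] | None = None, **fit_kw) -> list[CandidateResult]:
    """Evaluate the full candidate grid; returns one result per
    FC × RM × CV-scheme combination."""
    out = []
    for scheme in schemes:
        for fc in feature_grid:
            for rm in rm_grid:
                out.append(evaluate_candidate(
                    presences, background, stack, fc, rm, scheme, seed,
                    var_names=var_names, **fit_kw))
    return out


def results_table(results: list[CandidateResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def _complexity(fc: str) -> int:
    try:
        return FEATURE_GRID.index(fc)
    except ValueError:
        return len(FEATURE_GRID) + len(fc)


def select(results: list[CandidateResult], criterion: str) -> CandidateResult:
    """Pick the optimal candidate.

    ``aicc_min``: lowest AICc. ``sequential``: lowest 10% omission rate,
    then highest mean test AUC. Ties in both: lower RM, then simpler
    feature set.
    """
    if not results:
        raise ValueError("no candidate results")
    tiebreak = lambda r: (r.rm, _complexity(r.feature_classes))
    if criterion == "aicc_min":
        return min(results, key=lambda r: (r.aicc, *tiebreak(r)))
    if criterion == "sequential":
        return min(results, key=lambda r: (r.or10, -r.mean_test_auc, *tiebreak(r)))
    raise ValueError(f"unknown selection criterion: {criterion!r}")
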