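"""Two-step predictor screening.

Step 1: replicated preliminary fits on bootstrap resamples of the
presences; keep variables whose mean permutation contribution exceeds a
percentage threshold. Step 2: pairwise Spearman rank correlation over
shared valid raster cells; greedily drop the lower-priority member of any
pair with |ρ| above the cutoff (priority defaults to descending mean
contribution, keeping the stronger variable of a correlated pair).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .grid import LayerStack
from .maxent import FeatureSpec, fit, percent_contribution
from .occurrences import OccurrenceSet


@dataclass
class ScreenReport:
    mean_contribution: dict[str, float]
    retained_after_contribution: list[str]
    correlation_matrix: pd.DataFrame
    final_variables: list[str]
    dropped_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "mean_contribution": self.mean_contribution,
                "retained_after_contribution": self.retained_after_contribution,
                "correlation_matrix": self.correlation_matrix.to_dict(),
                "final_variables": self.final_variables,
                "dropped_pairs": [list(t) for t in self.dropped_pairs],
            }, fh, indent=1)


def contribution_filter(presences: OccurrenceSet, background: OccurrenceSet,
                        stack: LayerStack, n_replicates: int = 5,
                        threshold_pct: float = 3.0, seed: int = 0,
                        spec: FeatureSpec | str = "LQH", rm: float = 1.0,
                        var_names: list[str] | None = None,
                        **fit_kw) -> tuple[list[str], dict[str, float]]:
    """Mean permutation contribution over bootstrap-replicated fits; keep
    variables above ``threshold_pct``. Returns (kept names, mean %)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be ≥ 1")
    var_names = var_names or stack.names
    rng = np.random.default_rng(seed)
    acc = {v: 0.0 for v in var_names}
    for rep in range(n_replicates):
        idx = rng.integers(0, len(presences), size=len(presences))
        boot = presences.subset(idx)
        model = fit(boot, background, stack, spec=spec, rm=rm,
                    var_names=var_names, **fit_kw)
        contrib = percent_contribution(model, boot, background, stack,
                                       seed=int(rng.integers(2**31)))
        for v, c in contrib.items():
            acc[v] += c / n_replicates
    kept = [v for v in var_names if acc[v] > threshold_pct]
    if not kept:
        raise ValueError(
            f"no variable exceeds the {threshold_pct}% contribution threshold")
    return kept, acc


def spearman_matrix(stack: LayerStack, names: list[str]) -> pd.DataFrame:
    """Pairwise Spearman ρ over shared valid cells (ties: average ranks)."""
    X = stack.valid_values(names)
    if len(names) == 1:
        rho = np.ones((1, 1))
    else:
        rho, _ = spearmanr(X)
        rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=names, columns=names)


def spearman_prune(stack: LayerStack, candidates: list[str],
                   cutoff: float = 0.7,
                   priority: list[str] | None = None,
                   ) -> tuple[list[str], list[tuple[str, str, float]], pd.DataFrame]:
    """Greedy correlation pruning.

    Walks candidates in priority order, keeping a variable only if its
    |ρ| with every already-kept variable is ≤ cutoff. The result depends
    only on the priority list, not the candidate input order. Returns
    (kept, dropped (kept_name, dropped_name, ρ) pairs, ρ matrix).
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    priority = priority if priority is not None else list(candidates)
    missing = set(candidates) - set(priority)
    if missing:
        raise ValueError(f"priority list omits candidate(s): {sorted(missing)}")
    corr = spearman_matrix(stack, sorted(candidates))
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for v in priority:
        if v not in candidates:
            continue
        conflict = None
        for k in kept:
            rho = float(corr.loc[v, k])
            if abs(rho) > cutoff:
                conflict = (k, v, rho)
                break
        if conflict is None:
            kept.append(v)
        else:
            dropped.append(conflict)
    return kept, dropped, corr


def screen_variables(presences: OccurrenceSet, background: OccurrenceSet,
                     stack: LayerStack, n_replicates: int = 5,
                     threshold_pct: float = 3.0, rho_cutoff: float = 0.7,
                     seed: int = 0, var_names: list[str] | None = None,
                     **fit_kw) -> ScreenReport:
    """Full two-step screen: contribution filter, then Spearman pruning
    with priority = descending mean contribution."""
    kept, contrib = contribution_filter(
        presences, background, stack, n_replicates=n_replicates,
        threshold_pct=threshold_pct, seed=seed, var_names=var_names, **fit_kw)
    priority = sorted(kept, key=lambda v: -contrib[v])
    final, dropped, corr = spearman_prune(stack, kept, cutoff=rho_cutoff,
                                          priority=priority)
    return ScreenReport(mean_contribution=contrib,
                        retained_after_contribution=kept,
                        correlation_matrix=corr, final_variables=final,
                        dropped_pairs=dropped)
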