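"""Presence-background maximum-entropy suitability model.

The model is the classic Gibbs/log-linear density over landscape cells:
``P(cell x) = exp(η(x)) / Σ_b exp(η(b))`` with η a sparse linear function of
transformed environmental features. Fitting maximizes the L1-penalized mean
presence log-likelihood over the background-cell state space — the convex
"infinitely weighted logistic" objective — by proximal gradient (FISTA)
with backtracking; the contract is the objective, not the algorithm.

Outputs follow the standard conventions: a *raw* score normalized to mean 1
over the training background, and the *cloglog* transform
``1 − exp(−e^H · p(x))`` (H the entropy of the fitted distribution over
background cells), a monotone map into [0, 1] read as habitat suitability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .grid import Grid, LayerStack
from .occurrences import OccurrenceSet

FEATURE_CLASSES = ("L", "Q", "H", "P", "T")


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach the objective tolerance."""

    def __init__(self, message: str, last_objective: float):
        super().__init__(message)
        self.last_objective = last_objective


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature transforms to expand each predictor into.

    classes: subset of {L, Q, H, P, T} — linear, quadratic, hinge,
    product, threshold. Hinge/threshold knots are evenly spaced on the
    training range. With ``clamp``, inputs are truncated to the training
    range before expansion (always on for projection to new conditions).
    """

    classes: frozenset = frozenset("LQHPT")
    n_hinge_knots: int = 30
    n_threshold_knots: int = 30
    clamp: bool = True

    def __post_init__(self):
        cls = frozenset(self.classes)
        object.__setattr__(self, "classes", cls)
        unknown = cls - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature class tag(s): {sorted(unknown)}")
        if not cls:
            raise ValueError("at least one feature class required")
        if "H" in cls and self.n_hinge_knots < 2:
            raise ValueError("n_hinge_knots must be ≥ 2 when hinges are used")
        if "T" in cls and self.n_threshold_knots < 2:
            raise ValueError("n_threshold_knots must be ≥ 2 when thresholds are used")

    @classmethod
    def from_string(cls, tag: str, **kw) -> "FeatureSpec":
        return cls(classes=frozenset(tag.upper()), **kw)

    @property
    def tag(self) -> str:
        return "".join(c for c in FEATURE_CLASSES if c in self.classes)


def _scale(X: np.ndarray, mins: np.ndarray, maxs: np.ndarray, clamp: bool) -> np.ndarray:
    span = np.where(maxs > mins, maxs - mins, 1.0)
    z = (X - mins) / span
    if clamp:
        z = np.clip(z, 0.0, 1.0)
    return z


def expand_matrix(X: np.ndarray, spec: FeatureSpec,
                  mins: np.ndarray, maxs: np.ndarray) -> tuple[np.ndarray, list[dict]]:
    """Expand raw predictor matrix (n × p) into the feature matrix (n × J).

    Returns the matrix and per-feature metadata (class, source variable
    index/indices, knot, direction).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = _scale(X, mins, maxs, spec.clamp)
    n, p = z.shape
    cols: list[np.ndarray] = []
    meta: list[dict] = []
    if "L" in spec.classes:
        for i in range(p):
            cols.append(z[:, i])
            meta.append({"class": "L", "vars": (i,)})
    if "Q" in spec.classes:
        for i in range(p):
            cols.append(z[:, i] ** 2)
            meta.append({"class": "Q", "vars": (i,)})
    if "P" in spec.classes:
        for i in range(p):
            for j in range(i + 1, p):
                cols.append(z[:, i] * z[:, j])
                meta.append({"class": "P", "vars": (i, j)})
    if "H" in spec.classes:
        nh = spec.n_hinge_knots
        fwd_knots = np.linspace(0.0, 1.0, nh, endpoint=False)
        rev_knots = fwd_knots + 1.0 / nh
        for i in range(p):
            for k in fwd_knots:
                cols.append(np.maximum(0.0, (z[:, i] - k) / (1.0 - k)))
                meta.append({"class": "H", "vars": (i,), "knot": float(k),
                             "direction": "forward"})
            for k in rev_knots:
                cols.append(np.maximum(0.0, (k - z[:, i]) / k))
                meta.append({"class": "H", "vars": (i,), "knot": float(k),
                             "direction": "reverse"})
    if "T" in spec.classes:
        nt = spec.n_threshold_knots
        knots = np.linspace(0.0, 1.0, nt + 2)[1:-1]
        for i in range(p):
            for k in knots:
                cols.append((z[:, i] > k).astype(float))
                meta.append({"class": "T", "vars": (i,), "knot": float(k)})
    return np.column_stack(cols), meta


def expand_features(values: np.ndarray, spec: FeatureSpec,
                    mins: np.ndarray, maxs: np.ndarray) -> np.ndarray:
    """Feature vector for a single observation (see :func:`expand_matrix`)."""
    F, _ = expand_matrix(np.atleast_2d(values), spec, np.asarray(mins, float),
                         np.asarray(maxs, float))
    return F[0]


# Per-class base penalties, interpolated on presence sample size. Fixed,
# documented table in the spirit of the published MaxEnt defaults.
_BASE_PENALTY = {
    "L": ([10.0, 30.0, 100.0], [1.0, 0.2, 0.05]),
    "Q": ([10.0, 30.0, 100.0], [1.0, 0.2, 0.05]),
    "P": ([10.0, 17.0, 30.0], [2.6, 1.6, 1.0]),
    "T": ([10.0, 100.0], [2.0, 1.0]),
    "H": ([10.0, 10.0], [0.5, 0.5]),
}


def _penalties(meta: list[dict], F_bg: np.ndarray, rm: float, m: int) -> np.ndarray:
    """λ_j = rm · base(class, n_presence) · s_j, with s_j the feature's
    standard deviation over the background (floored at 1e-3).

    Because the sampling noise of the presence feature means decays like
    1/√n while λ stays fixed, uninformative features are driven exactly to
    zero once the presence sample is large enough.
    """
    s = np.maximum(F_bg.std(axis=0), 1e-3)
    base = np.empty(len(meta))
    for j, fm in enumerate(meta):
        xs, ys = _BASE_PENALTY[fm["class"]]
        base[j] = np.interp(float(m), xs, ys)
    return rm * base * s


@dataclass
class SuitabilityModel:
    """Fitted presence-background Gibbs model.

    ``beta`` is the (sparse) coefficient vector over expanded features;
    normalizers and knots are stored so predictions on new layer stacks
    are reproducible. ``entropy`` is the Shannon entropy (nats) of the
    fitted distribution over the N training background cells; the cloglog
    transform uses ``e^(entropy − ln N)``.
    """

    var_names: list[str]
    spec: FeatureSpec
    beta: np.ndarray
    feature_meta: list[dict]
    mins: np.ndarray
    maxs: np.ndarray
    rm: float
    log_z_mean: float        # ln of mean_b exp(η): raw = exp(η − log_z_mean)
    entropy: float           # H of fitted distribution over background cells
    n_background: int
    n_presence: int
    penalties: np.ndarray = field(repr=False, default=None)
    converged_objective: float = float("nan")
    n_iterations: int = 0

    @property
    def k_params(self) -> int:
        return int(np.count_nonzero(self.beta))

    @property
    def entropy_rel_uniform(self) -> float:
        """H − ln N: the cloglog exponent on the mean-1 raw scale."""
        return self.entropy - np.log(self.n_background)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        F, _ = expand_matrix(X, self.spec, self.mins, self.maxs)
        return F @ self.beta

    def raw(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.linear_predictor(X) - self.log_z_mean)

    def cloglog(self, X: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.exp(self.entropy_rel_uniform) * self.raw(X))

    def cloglog_from_raw(self, raw: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.exp(self.entropy_rel_uniform) * raw)

    def score_points(self, occ: OccurrenceSet, stack: LayerStack,
                     output: str = "cloglog") -> np.ndarray:
        X, _, _ = stack.subset(self.var_names).values_at(occ.lons, occ.lats,
                                                         self.var_names)
        return self.cloglog(X) if output == "cloglog" else self.raw(X)

    def predict(self, stack: LayerStack, output: str = "cloglog") -> Grid:
        """Project the model over a layer stack; nodata propagated."""
        missing = [v for v in self.var_names if v not in stack]
        if missing:
            raise KeyError(f"stack is missing model variable(s): {missing}")
        sub = stack.subset(self.var_names)
        ok = ~sub.union_nodata
        X = np.column_stack([sub[v].values[ok] for v in self.var_names])
        if output == "raw":
            scores = self.raw(X)
        elif output == "cloglog":
            scores = self.cloglog(X)
        else:
            raise ValueError(f"unknown output format: {output!r}")
        vals = np.zeros(sub.shape, dtype=float)
        vals[ok] = scores
        return sub.template.copy_with(vals, mask=sub.union_nodata)

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str) -> None:
        payload = {
            "var_names": self.var_names,
            "spec": {"classes": self.spec.tag,
                     "n_hinge_knots": self.spec.n_hinge_knots,
                     "n_threshold_knots": self.spec.n_threshold_knots,
                     "clamp": self.spec.clamp},
            "beta": self.beta.tolist(),
            "feature_meta": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in fm.items()}
                for fm in self.feature_meta
            ],
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "rm": self.rm,
            "log_z_mean": self.log_z_mean,
            "entropy": self.entropy,
            "entropy_rel_uniform": self.entropy_rel_uniform,
            "n_background": self.n_background,
            "n_presence": self.n_presence,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SuitabilityModel":
        with open(path) as fh:
            d = json.load(fh)
        spec = FeatureSpec.from_string(d["spec"]["classes"],
                                       n_hinge_knots=d["spec"]["n_hinge_knots"],
                                       n_threshold_knots=d["spec"]["n_threshold_knots"],
                                       clamp=d["spec"]["clamp"])
        meta = [{k: (tuple(v) if k == "vars" else v) for k, v in fm.items()}
                for fm in d["feature_meta"]]
        return cls(var_names=d["var_names"], spec=spec,
                   beta=np.asarray(d["beta"]), feature_meta=meta,
                   mins=np.asarray(d["mins"]), maxs=np.asarray(d["maxs"]),
                   rm=d["rm"], log_z_mean=d["log_z_mean"], entropy=d["entropy"],
                   n_background=d["n_background"], n_presence=d["n_presence"])


def _training_data(presences: OccurrenceSet, background: OccurrenceSet,
                   stack: LayerStack, var_names: list[str] | None):
    """Collapse points to unique cells; background includes presence cells.

    Returns (X_bg, presence_row_idx, var_names): presences index into the
    background matrix rows.
    """
    var_names = var_names or stack.names
    sub = stack.subset(var_names)
    tpl = sub.template

    def cells_of(occ):
        out = []
        for lo, la in zip(occ.lons, occ.lats):
            r, c = tpl.cell_of(lo, la)
            if not sub.union_nodata[r, c]:
                out.append((r, c))
        return out

    pres_cells = sorted(set(cells_of(presences)))
    if not pres_cells:
        raise ValueError("no presence falls on a valid cell")
    bg_cells = sorted(set(cells_of(background)) | set(pres_cells))
    index = {cell: i for i, cell in enumerate(bg_cells)}
    rows = np.array([rc[0] for rc in bg_cells])
    cols = np.array([rc[1] for rc in bg_cells])
    X_bg = np.column_stack([sub[v].values[rows, cols] for v in var_names])
    pres_idx = np.array([index[c] for c in pres_cells])
    return X_bg, pres_idx, var_names


def _fista(F_bg: np.ndarray, pres_idx: np.ndarray, lam: np.ndarray,
           tol: float, max_iter: int) -> tuple[np.ndarray, float, int]:
    """Minimize −mean_presence(η) + ln mean_bg(exp η) + Σ λ|β| by FISTA
    with backtracking and adaptive restart."""
    n_feat = F_bg.shape[1]
    F_p_mean = F_bg[pres_idx].mean(axis=0)
    logN = np.log(F_bg.shape[0])

    def smooth(beta):
        eta = F_bg @ beta
        return float(-(eta[pres_idx]).mean() + logsumexp(eta) - logN)

    def grad(beta):
        eta = F_bg @ beta
        w = softmax(eta)
        return -F_p_mean + w @ F_bg, float(-(eta[pres_idx]).mean()
                                           + logsumexp(eta) - logN)

    def total(beta, g=None):
        return (smooth(beta) if g is None else g) + float(lam @ np.abs(beta))

    beta = np.zeros(n_feat)
    y = beta.copy()
    t = 1.0
    L = 1.0
    f_prev = total(beta, 0.0)
    best_f = f_prev
    for it in range(1, max_iter + 1):
        gy, fy = grad(y)
        while True:
            step = 1.0 / L
            cand = y - step * gy
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * lam, 0.0)
            diff = cand - y
            f_cand = smooth(cand)
            if f_cand <= fy + gy @ diff + 0.5 * L * (diff @ diff) + 1e-12:
                break
            L *= 2.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        f_total = f_cand + float(lam @ np.abs(cand))
        if f_total > f_prev:          # adaptive restart on objective increase
            y = beta.copy()
            t = 1.0
            continue
        y = cand + ((t - 1.0) / t_next) * (cand - beta)
        beta = cand
        t = t_next
        L *= 0.9
        if abs(f_prev - f_total) < tol:
            return beta, f_total, it
        f_prev = f_total
        best_f = min(best_f, f_total)
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (objective {best_f:.10g})",
        best_f)


def fit(presences: OccurrenceSet, background: OccurrenceSet, stack: LayerStack,
        spec: FeatureSpec | str = "LQHPT", rm: float = 1.0,
        var_names: list[str] | None = None, tol: float = 1e-7,
        max_iter: int = 20000) -> SuitabilityModel:
    """Fit the penalized Gibbs model.

    Presence and background points are collapsed to unique raster cells;
    presence cells are included in the background (the standard
    presence-background convention). Per-feature penalty
    ``λ_j = rm · base(class, n_presence) · s_j`` with s_j the feature's
    background standard deviation. Deterministic given inputs.
    """
    if isinstance(spec, str):
        spec = FeatureSpec.from_string(spec)
    if rm <= 0:
        raise ValueError("regularization multiplier must be positive")
    X_bg, pres_idx, var_names = _training_data(presences, background, stack,
                                               var_names)
    m = len(pres_idx)
    if m < 10:
        raise ValueError(f"need ≥ 10 presence cells, got {m}")
    mins = X_bg.min(axis=0)
    maxs = X_bg.max(axis=0)
    F_bg, meta = expand_matrix(X_bg, spec, mins, maxs)
    lam = _penalties(meta, F_bg, rm, m)
    beta, f_final, n_iter = _fista(F_bg, pres_idx, lam, tol, max_iter)

    eta = F_bg @ beta
    log_z_sum = float(logsumexp(eta))
    logp = eta - log_z_sum
    p = np.exp(logp)
    entropy = float(-(p * logp).sum())
    return SuitabilityModel(
        var_names=list(var_names), spec=spec, beta=beta, feature_meta=meta,
        mins=mins, maxs=maxs, rm=rm,
        log_z_mean=log_z_sum - np.log(len(eta)),
        entropy=entropy, n_background=len(eta), n_presence=m,
        penalties=lam, converged_objective=f_final, n_iterations=n_iter)


def training_gain(model: SuitabilityModel, X_bg: np.ndarray,
                  pres_idx: np.ndarray) -> float:
    """Unpenalized training gain: mean presence log-density relative to the
    uniform model, ``mean_p η − ln(mean_b e^η)``."""
    F, _ = expand_matrix(X_bg, model.spec, model.mins, model.maxs)
    eta = F @ model.beta
    return float(eta[pres_idx].mean() - (logsumexp(eta) - np.log(len(eta))))


def percent_contribution(model: SuitabilityModel, presences: OccurrenceSet,
                         background: OccurrenceSet, stack: LayerStack,
                         seed: int = 0, n_permutations: int = 10) -> dict[str, float]:
    """Permutation importance as percent contribution summing to 100.

    Drop in training gain when one variable's values are permuted across
    all training cells (mean over permutations), floored at 0 and
    normalized to 100.
    """
    X_bg, pres_idx, var_names = _training_data(presences, background, stack,
                                               model.var_names)
    rng = np.random.default_rng(seed)
    gain0 = training_gain(model, X_bg, pres_idx)
    drops = np.zeros(len(var_names))
    for v in range(len(var_names)):
        acc = 0.0
        for _ in range(n_permutations):
            Xp = X_bg.copy()
            Xp[:, v] = Xp[rng.permutation(len(Xp)), v]
            acc += gain0 - training_gain(model, Xp, pres_idx)
        drops[v] = max(acc / n_permutations, 0.0)
    total = drops.sum()
    if total <= 0:
        pct = np.full(len(var_names), 100.0 / len(var_names))
    else:
        pct = 100.0 * drops / total
    return dict(zip(var_names, pct))


def jackknife(presences: OccurrenceSet, background: OccurrenceSet,
              stack: LayerStack, spec: FeatureSpec | str = "LQHPT",
              rm: float = 1.0, var_names: list[str] | None = None,
              **fit_kw) -> dict[str, tuple[float, float]]:
    """Leave-one-out / only-one variable importance.

    For each variable returns (gain_without, gain_only): the unpenalized
    training gain of a model refit excluding the variable and of a model
    using it alone.
    """
    var_names = var_names or stack.names
    if len(var_names) < 2:
        raise ValueError("jackknife needs ≥ 2 variables")
    out: dict[str, tuple[float, float]] = {}
    for v in var_names:
        rest = [w for w in var_names if w != v]
        m_without = fit(presences, background, stack, spec=spec, rm=rm,
                        var_names=rest, **fit_kw)
        Xw, pw, _ = _training_data(presences, background, stack, rest)
        g_without = training_gain(m_without, Xw, pw)
        m_only = fit(presences, background, stack, spec=spec, rm=rm,
                     var_names=[v], **fit_kw)
        Xo, po, _ = _training_data(presences, background, stack, [v])
        g_only = training_gain(m_only, Xo, po)
        out[v] = (g_without, g_only)
    return out
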