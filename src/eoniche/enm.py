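"""Presence-background ecological niche modeling (maxnet-style).

Pipeline: spatially thin occurrences to the predictor grid, delimit a
calibration region (great-circle buffer or bounding box), sample background
points, screen predictors (near-zero variance, Spearman collinearity), expand
features (linear / quadratic / product / hinge), fit an L1-penalized
presence-background exponential model, tune feature class and regularization
multiplier by cross-validated AUC and omission rate, threshold at the 10th
percentile of training-presence suitability (P10), build bootstrap ensembles,
project onto target climates, and rank predictors by permutation importance.

The fitted model is the Gibbs distribution over the background sample:
maximizing the penalized log-likelihood

    max_beta  mean_presence(eta) - log mean_background(exp(eta))
              - sum_j lambda_j |beta_j|,        eta = X beta,

solved here by FISTA (proximal gradient with backtracking).  Suitability is
reported on the cloglog scale, 1 - exp(-exp(H) * raw(x)), where raw is the
background-normalized density and H its entropy over background points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

__all__ = [
    "ModelConfig",
    "FeatureExpansion",
    "NicheModel",
    "EvaluationResult",
    "thin_occurrences",
    "build_region",
    "sample_background",
    "extract_values",
    "screen_predictors",
    "fit_model",
    "evaluate",
    "tune",
    "default_config_grid",
    "bootstrap_ensemble",
    "project",
    "permutation_importance",
]

EARTH_RADIUS_KM = 6371.0

# complexity ranking used by the simplicity-preferring selection rule
_FC_ORDER = ["l", "lq", "lh", "lqh", "lqph"]


# ---------------------------------------------------------------------------
# Occurrence processing and calibration region
# ---------------------------------------------------------------------------

def _cell_indices(points: pd.DataFrame, lon: np.ndarray, lat: np.ndarray):
    ii = np.abs(points["lon"].to_numpy()[:, None] - lon[None, :]).argmin(axis=1)
    jj = np.abs(points["lat"].to_numpy()[:, None] - lat[None, :]).argmin(axis=1)
    return ii, jj


def thin_occurrences(points: pd.DataFrame, stack: xr.Dataset) -> pd.DataFrame:
    """Keep at most one occurrence per predictor-grid cell.

    Points are snapped to their containing cell; within a cell the first
    point in a deterministic (lon, lat) sort is kept, so the result does not
    depend on input order.
    """
    if len(points) == 0:
        raise ValueError("no occurrences to thin")
    pts = points.sort_values(["lon", "lat"], kind="mergesort").reset_index(drop=True)
    ii, jj = _cell_indices(pts, stack["lon"].values, stack["lat"].values)
    cell = jj * stack["lon"].size + ii
    keep = pd.Series(cell).duplicated(keep="first").to_numpy() == False  # noqa: E712
    return pts.loc[keep].reset_index(drop=True)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (spherical Earth, radius 6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.deg2rad, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def build_region(
    points: pd.DataFrame,
    stack: xr.Dataset,
    mode: str = "buffer_km",
    param: float | None = None,
) -> xr.DataArray:
    """Boolean calibration-region mask on the predictor grid.

    ``buffer_km``: cells whose center lies within ``param`` km (great-circle,
    default 450) of the nearest occurrence.  ``bounding_box``: cells inside
    the lon/lat envelope of the points, padded by ``param`` degrees (default
    0, the tight box).  Occurrence cells are always inside the mask.
    """
    if len(points) == 0:
        raise ValueError("no points to build a region from")
    lon = stack["lon"].values
    lat = stack["lat"].values
    if mode == "buffer_km":
        radius = 450.0 if param is None else float(param)
        glon, glat = np.meshgrid(lon, lat)
        mask = np.zeros(glon.shape, dtype=bool)
        for _, p in points.iterrows():
            d = haversine_km(glon, glat, p["lon"], p["lat"])
            mask |= d <= radius
    elif mode == "bounding_box":
        pad = 0.0 if param is None else float(param)
        lon_ok = (lon >= points["lon"].min() - pad) & (lon <= points["lon"].max() + pad)
        lat_ok = (lat >= points["lat"].min() - pad) & (lat <= points["lat"].max() + pad)
        mask = lat_ok[:, None] & lon_ok[None, :]
    else:
        raise ValueError(f"unknown region mode {mode!r}")
    ii, jj = _cell_indices(points, lon, lat)
    mask[jj, ii] = True
    return xr.DataArray(mask, dims=("lat", "lon"), coords={"lat": lat, "lon": lon})


def sample_background(
    region: xr.DataArray,
    n: int = 15000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Uniform random background points over the region's cells.

    Sampling is without replacement when the region has at least ``n`` cells,
    otherwise with replacement (with a warning).
    """
    mask = region.values.astype(bool)
    jj, ii = np.nonzero(mask)
    if jj.size == 0:
        raise ValueError("calibration region is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if jj.size >= n:
        pick = rng.choice(jj.size, size=n, replace=False)
    else:
        warnings.warn(
            f"region has {jj.size} cells < n={n}; sampling with replacement",
            stacklevel=2,
        )
        pick = rng.choice(jj.size, size=n, replace=True)
    return pd.DataFrame(
        {"lon": region["lon"].values[ii[pick]], "lat": region["lat"].values[jj[pick]]}
    )


def extract_values(
    stack: xr.Dataset, points: pd.DataFrame, variables: list[str] | None = None
) -> np.ndarray:
    """Matrix of predictor values (points x variables) at containing cells."""
    variables = variables or list(stack.data_vars)
    ii, jj = _cell_indices(points, stack["lon"].values, stack["lat"].values)
    cols = [stack[v].values[jj, ii] for v in variables]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Predictor screening
# ---------------------------------------------------------------------------

def screen_predictors(
    stack: xr.Dataset,
    region: xr.DataArray | None = None,
    n_cells: int = 10000,
    r_max: float = 0.80,
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Drop near-zero-variance predictors, then greedily resolve collinearity.

    Spearman correlations are computed from ``n_cells`` randomly sampled
    region cells.  While any pair has |r| >= ``r_max``, the member of the
    worst-offending pair with the larger mean absolute correlation to all
    remaining predictors is removed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(stack.data_vars)
    if region is None:
        mask = np.ones((stack["lat"].size, stack["lon"].size), dtype=bool)
    else:
        mask = region.values.astype(bool)
    jj, ii = np.nonzero(mask)
    take = rng.choice(jj.size, size=min(n_cells, jj.size), replace=False)
    X = np.column_stack([stack[v].values[jj[take], ii[take]] for v in names])
    ok_rows = np.isfinite(X).all(axis=1)
    X = X[ok_rows]

    # near-zero variance: sd negligible relative to the value scale
    sds = X.std(axis=0)
    scale = np.abs(X).mean(axis=0) + 1.0
    keep = [i for i in range(len(names)) if sds[i] > 1e-8 * scale[i]]
    if not keep:
        raise ValueError("all predictors are (near-)constant")
    X = X[:, keep]
    names = [names[i] for i in keep]
    if len(names) == 1:
        return names

    corr = spearmanr(X).statistic
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 0.0)
    corr = np.abs(corr)
    alive = list(range(len(names)))
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() < r_max:
            break
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        ia, ib = alive[a], alive[b]
        drop = ia if sub[a].mean() >= sub[b].mean() else ib
        alive.remove(drop)
    if not alive:
        raise ValueError("all predictors removed by the correlation filter")
    return [names[i] for i in alive]


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

@dataclass
class FeatureExpansion:
    """Maxnet-style feature construction fitted on background statistics.

    Raw variables are min-max scaled to [0, 1] using background minima and
    maxima; quadratic features are squares, product features all pairwise
    products, and hinge features forward/reverse ramps over ``n_knots``
    evenly spaced quantiles of the scaled background values.
    """

    variables: list[str]
    fc: str
    n_knots: int = 20
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None
    knots: np.ndarray | None = None  # (nvar, n_knots) on the scaled axis
    feature_class: list[str] = field(default_factory=list)
    feature_var: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fc or any(c not in "lqph" for c in self.fc):
            raise ValueError(f"invalid feature-class string {self.fc!r}")

    def fit(self, background: np.ndarray) -> "FeatureExpansion":
        self.mins = background.min(axis=0)
        self.maxs = background.max(axis=0)
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        scaled = (background - self.mins) / span
        if "h" in self.fc:
            qs = np.linspace(0.0, 1.0, self.n_knots + 2)[1:-1]
            self.knots = np.quantile(scaled, qs, axis=0).T  # (nvar, n_knots)
        self._index_features()
        return self

    def _index_features(self) -> None:
        nv = len(self.variables)
        cls, var = [], []
        if "l" in self.fc:
            cls += ["l"] * nv
            var += list(range(nv))
        if "q" in self.fc:
            cls += ["q"] * nv
            var += list(range(nv))
        if "p" in self.fc:
            if nv < 2:
                warnings.warn("product features need >= 2 variables; skipped",
                              stacklevel=3)
            else:
                for i in range(nv):
                    for j in range(i + 1, nv):
                        cls.append("p")
                        var.append(i)  # representative variable
        if "h" in self.fc:
            for i in range(nv):
                cls += ["h"] * (2 * self.n_knots)
                var += [i] * (2 * self.n_knots)
        self.feature_class = cls
        self.feature_var = var

    @property
    def n_features(self) -> int:
        return len(self.feature_class)

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        Z = np.clip((X - self.mins) / span, 0.0, 1.0)
        blocks = []
        if "l" in self.fc:
            blocks.append(Z)
        if "q" in self.fc:
            blocks.append(Z**2)
        if "p" in self.fc and Z.shape[1] >= 2:
            nv = Z.shape[1]
            prods = [Z[:, i] * Z[:, j] for i in range(nv) for j in range(i + 1, nv)]
            blocks.append(np.column_stack(prods))
        if "h" in self.fc:
            for i in range(Z.shape[1]):
                k = self.knots[i]  # (n_knots,)
                x = Z[:, [i]]
                fwd = np.clip((x - k[None, :]) / np.maximum(1.0 - k[None, :], 1e-9),
                              0.0, None)
                rev = np.clip((k[None, :] - x) / np.maximum(k[None, :], 1e-9),
                              0.0, None)
                blocks.append(np.column_stack([fwd, rev]))
        return np.column_stack(blocks)


# per-feature-class base penalties; divided by sqrt(n_presences) and
# multiplied by the regularization multiplier
_BASE_PENALTY = {"l": 0.1, "q": 0.1, "p": 0.2, "h": 0.5}


def penalty_weights(expansion: FeatureExpansion, reg: float, n_presences: int) -> np.ndarray:
    base = np.array([_BASE_PENALTY[c] for c in expansion.feature_class])
    return reg * base / np.sqrt(max(n_presences, 1))


# ---------------------------------------------------------------------------
# Penalized presence-background fit (FISTA)
# ---------------------------------------------------------------------------

def _pb_loss_grad(beta, Xp, Xb):
    """Smooth part of the loss and its gradient."""
    eta_p = Xp @ beta
    eta_b = Xb @ beta
    mx = eta_b.max()
    w = np.exp(eta_b - mx)
    zs = w.sum()
    loss = -eta_p.mean() + mx + np.log(zs / Xb.shape[0])
    grad = -Xp.mean(axis=0) + (Xb.T @ (w / zs))
    return loss, grad


def _soft_threshold(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def fit_l1_maxent(
    Xp: np.ndarray,
    Xb: np.ndarray,
    lam: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> np.ndarray:
    """FISTA with backtracking for the L1-penalized presence-background loss."""
    n_feat = Xp.shape[1]
    beta = np.zeros(n_feat)
    y = beta.copy()
    t = 1.0
    step = 1.0
    f_y, g_y = _pb_loss_grad(y, Xp, Xb)
    prev_obj = f_y + np.abs(beta) @ lam
    for _ in range(max_iter):
        # backtracking line search on the smooth part
        for _bt in range(50):
            cand = _soft_threshold(y - step * g_y, step * lam)
            d = cand - y
            f_cand, _ = _pb_loss_grad(cand, Xp, Xb)
            if f_cand <= f_y + g_y @ d + (d @ d) / (2.0 * step) + 1e-12:
                break
            step *= 0.5
        beta_new = cand
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = beta_new + ((t - 1.0) / t_new) * (beta_new - beta)
        beta, t = beta_new, t_new
        f_y, g_y = _pb_loss_grad(y, Xp, Xb)
        obj = f_y + np.abs(beta) @ lam
        if abs(prev_obj - obj) <= tol * (1.0 + abs(prev_obj)):
            break
        prev_obj = obj
        step *= 2.0  # allow the step to grow back
    return beta


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Feature classes, regularization multiplier, CV folds, and seed."""

    fc: str = "lh"
    reg: float = 1.0
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fc or any(c not in "lqph" for c in self.fc):
            raise ValueError(f"invalid feature classes {self.fc!r}")
        if self.reg <= 0:
            raise ValueError("reg must be positive")


def default_config_grid(
    fcs: tuple[str, ...] = ("l", "lq", "lh", "lqh", "lqph"),
    regs: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0),
    k_folds: int = 5,
    seed: int = 0,
) -> list[ModelConfig]:
    """Grid of feature-class sets x regularization multipliers (1-3, step 0.5)."""
    return [ModelConfig(fc=f, reg=r, k_folds=k_folds, seed=seed)
            for f in fcs for r in regs]


@dataclass
class NicheModel:
    """Fitted maxnet-style model, sufficient to reproduce projections exactly."""

    variables: list[str]
    expansion: FeatureExpansion
    coef: np.ndarray
    log_z_bg: float  # log mean_background exp(eta)
    entropy: float   # entropy of the fitted distribution over background
    n_background: int
    p10: float
    config: ModelConfig

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.expansion.transform(X) @ self.coef

    def cloglog(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1]: 1 - exp(-exp(H) * raw(x))."""
        eta = self.linear_predictor(X)
        log_raw = eta - self.log_z_bg - np.log(self.n_background)
        return 1.0 - np.exp(-np.exp(self.entropy + log_raw))

    def to_json(self) -> str:
        doc = {
            "variables": self.variables,
            "fc": self.expansion.fc,
            "n_knots": self.expansion.n_knots,
            "mins": self.expansion.mins.tolist(),
            "maxs": self.expansion.maxs.tolist(),
            "knots": None if self.expansion.knots is None
                     else self.expansion.knots.tolist(),
            "coef": self.coef.tolist(),
            "log_z_bg": self.log_z_bg,
            "entropy": self.entropy,
            "n_background": self.n_background,
            "p10": self.p10,
            "config": {"fc": self.config.fc, "reg": self.config.reg,
                       "k_folds": self.config.k_folds, "seed": self.config.seed},
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NicheModel":
        doc = json.loads(text)
        exp = FeatureExpansion(doc["variables"], doc["fc"], doc["n_knots"])
        exp.mins = np.asarray(doc["mins"])
        exp.maxs = np.asarray(doc["maxs"])
        exp.knots = None if doc["knots"] is None else np.asarray(doc["knots"])
        exp._index_features()
        cfg = ModelConfig(**doc["config"])
        return cls(
            variables=doc["variables"], expansion=exp,
            coef=np.asarray(doc["coef"]), log_z_bg=doc["log_z_bg"],
            entropy=doc["entropy"], n_background=doc["n_background"],
            p10=doc["p10"], config=cfg,
        )


MIN_PRESENCES = 8


def _p10_threshold(scores: np.ndarray) -> float:
    # 10th percentile with linear interpolation between order statistics
    return float(np.percentile(scores, 10.0, method="linear"))


def fit_model(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    stack: xr.Dataset,
    config: ModelConfig,
    variables: list[str] | None = None,
) -> NicheModel:
    """Fit the penalized presence-background model on extracted predictor values."""
    variables = variables or list(stack.data_vars)
    if len(presences) < MIN_PRESENCES:
        raise ValueError(
            f"need at least {MIN_PRESENCES} presences, got {len(presences)}"
        )
    Xp_raw = extract_values(stack, presences, variables)
    Xb_raw = extract_values(stack, background, variables)
    ok_p = np.isfinite(Xp_raw).all(axis=1)
    ok_b = np.isfinite(Xb_raw).all(axis=1)
    Xp_raw, Xb_raw = Xp_raw[ok_p], Xb_raw[ok_b]
    if len(Xp_raw) < MIN_PRESENCES:
        raise ValueError("too few presences with complete predictor values")
    expansion = FeatureExpansion(variables, config.fc).fit(Xb_raw)
    Xp = expansion.transform(Xp_raw)
    Xb = expansion.transform(Xb_raw)
    if Xp.shape[1] == 0 or np.allclose(Xb.std(axis=0), 0.0):
        raise ValueError("degenerate design: all features constant")
    lam = penalty_weights(expansion, config.reg, Xp.shape[0])
    coef = fit_l1_maxent(Xp, Xb, lam)

    eta_b = Xb @ coef
    mx = eta_b.max()
    w = np.exp(eta_b - mx)
    z = w.sum()
    log_z_bg = mx + np.log(z / Xb.shape[0])
    prob = w / z
    entropy = float(-(prob * np.log(np.clip(prob, 1e-300, None))).sum())

    model = NicheModel(
        variables=variables, expansion=expansion, coef=coef,
        log_z_bg=float(log_z_bg), entropy=entropy, n_background=Xb.shape[0],
        p10=0.0, config=config,
    )
    model.p10 = _p10_threshold(model.cloglog(Xp_raw))
    return model


# ---------------------------------------------------------------------------
# Evaluation, tuning, ensembles, projection, importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationResult:
    auc_test: float
    or_p10: float
    n_test_presences: int
    per_fold: tuple[tuple[float, float], ...] = ()


def evaluate(
    model: NicheModel,
    test_presences: pd.DataFrame,
    background: pd.DataFrame,
    stack: xr.Dataset,
) -> EvaluationResult:
    """AUC (presences vs background, ties count 1/2) and omission below P10."""
    if len(test_presences) == 0:
        raise ValueError("no test presences")
    if len(background) == 0:
        raise ValueError("no background points")
    sp = model.cloglog(extract_values(stack, test_presences, model.variables))
    sb = model.cloglog(extract_values(stack, background, model.variables))
    ok_p, ok_b = np.isfinite(sp), np.isfinite(sb)
    sp, sb = sp[ok_p], sb[ok_b]
    scores = np.concatenate([sp, sb])
    labels = np.concatenate([np.ones(sp.size), np.zeros(sb.size)])
    auc = float(roc_auc_score(labels, scores))
    omission = float(np.mean(sp < model.p10))
    return EvaluationResult(auc, omission, int(sp.size))


def _fc_complexity(fc: str) -> tuple[int, int]:
    try:
        return (0, _FC_ORDER.index(fc))
    except ValueError:
        return (1, len(fc))


def tune(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    stack: xr.Dataset,
    configs: list[ModelConfig] | None = None,
    variables: list[str] | None = None,
    seed: int | None = None,
    auc_margin: float = 0.005,
    or_margin: float = 0.01,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Grid search with k-fold CV; winner by the lexicographic selection rule.

    Candidates within ``auc_margin`` of the best mean AUC are kept; among
    them, those within ``or_margin`` of the lowest mean OR_P10; ties resolved
    by the simplest feature-class set (l < lq < lh < lqh < lqph), then the
    smallest regularization multiplier.
    """
    configs = configs or default_config_grid()
    if not configs:
        raise ValueError("empty configuration grid")
    rng = np.random.default_rng(seed)
    n = len(presences)
    k = configs[0].k_folds
    fold = rng.permutation(n) % k
    rows = []
    for cfg in configs:
        aucs, ors = [], []
        try:
            for f in range(k):
                train = presences.iloc[fold != f]
                test = presences.iloc[fold == f]
                if len(test) == 0 or len(train) < MIN_PRESENCES:
                    continue
                m = fit_model(train, background, stack, cfg, variables)
                ev = evaluate(m, test, background, stack)
                aucs.append(ev.auc_test)
                ors.append(ev.or_p10)
        except ValueError:
            continue
        if aucs:
            rows.append({"fc": cfg.fc, "reg": cfg.reg,
                         "auc": float(np.mean(aucs)), "or_p10": float(np.mean(ors))})
    if not rows:
        raise ValueError("no configuration could be fitted")
    res = pd.DataFrame(rows)
    best_auc = res["auc"].max()
    pool = res[res["auc"] >= best_auc - auc_margin]
    best_or = pool["or_p10"].min()
    pool = pool[pool["or_p10"] <= best_or + or_margin].copy()
    pool["cx"] = [_fc_complexity(f) for f in pool["fc"]]
    pool = pool.sort_values(["cx", "reg"], kind="mergesort")
    winner = pool.iloc[0]
    cfg = next(c for c in configs if c.fc == winner["fc"] and c.reg == winner["reg"])
    return cfg, res.drop(columns=[c for c in ("cx",) if c in res])


def project(model: NicheModel, stack: xr.Dataset) -> xr.DataArray:
    """Cell-wise cloglog suitability over a target stack."""
    missing = [v for v in model.variables if v not in stack.data_vars]
    if missing:
        raise KeyError(f"target stack lacks predictor(s): {', '.join(missing)}")
    cols = [stack[v].values.ravel() for v in model.variables]
    X = np.column_stack(cols)
    out = np.full(X.shape[0], np.nan)
    ok = np.isfinite(X).all(axis=1)
    out[ok] = model.cloglog(X[ok])
    shape = (stack["lat"].size, stack["lon"].size)
    return xr.DataArray(
        out.reshape(shape), dims=("lat", "lon"),
        coords={"lat": stack["lat"].values, "lon": stack["lon"].values},
        name="suitability",
    )


def bootstrap_ensemble(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    stack: xr.Dataset,
    config: ModelConfig,
    reps: int = 10,
    seed: int | None = None,
    variables: list[str] | None = None,
    target: xr.Dataset | None = None,
) -> tuple[xr.DataArray, float, list[NicheModel]]:
    """Ensemble over presence bootstrap resamples (background held constant).

    Returns the cell-wise mean suitability raster over ``target`` (training
    stack by default), the mean P10 across replicates, and the replicate
    models.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    target = target if target is not None else stack
    rasters, p10s, models = [], [], []
    for _ in range(reps):
        idx = rng.integers(0, len(presences), size=len(presences))
        resampled = presences.iloc[idx].reset_index(drop=True)
        m = fit_model(resampled, background, stack, config, variables)
        rasters.append(project(m, target))
        p10s.append(m.p10)
        models.append(m)
    mean_raster = xr.concat(rasters, dim="rep").mean("rep", skipna=False)
    mean_raster.name = "suitability"
    return mean_raster, float(np.mean(p10s)), models


def permutation_importance(
    model: NicheModel,
    presences: pd.DataFrame,
    background: pd.DataFrame,
    stack: xr.Dataset,
    seed: int | None = None,
    n_repeats: int = 2,
) -> pd.DataFrame:
    """Permutation importance per predictor, normalized to sum to 100.

    Each predictor's values are shuffled jointly across presence and
    background evaluation rows; importance is the resulting drop in AUC
    (negative drops clipped to 0), averaged over ``n_repeats`` shuffles.
    """
    rng = np.random.default_rng(seed)
    Xp = extract_values(stack, presences, model.variables)
    Xb = extract_values(stack, background, model.variables)
    X = np.vstack([Xp, Xb])
    labels = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    ok = np.isfinite(X).all(axis=1)
    X, labels = X[ok], labels[ok]
    base = roc_auc_score(labels, model.cloglog(X))
    drops = np.zeros(len(model.variables))
    for j in range(len(model.variables)):
        vals = []
        for _ in range(n_repeats):
            Xs = X.copy()
            Xs[:, j] = rng.permutation(Xs[:, j])
            vals.append(base - roc_auc_score(labels, model.cloglog(Xs)))
        drops[j] = max(0.0, float(np.mean(vals)))
    total = drops.sum()
    importance = 100.0 * drops / total if total > 0 else np.zeros_like(drops)
    out = pd.DataFrame({"variable": model.variables, "importance": importance})
    out["rank"] = out["importance"].rank(ascending=False, method="first").astype(int)
    return out.sort_values("rank").reset_index(drop=True)
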