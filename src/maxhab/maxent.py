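"""Presence-background maximum-entropy suitability modeling.

The model is the Gibbs distribution over background cells,
``p(x) = exp(lam . f(x)) / Z``, whose feature expectations match the
presence sample under an L1 budget.  Fitting minimizes the convex
objective

    J(lam) = -mean_presence[lam . f] + log mean_background[exp(lam . f)]
             + sum_j beta_j |lam_j|

with ``beta_j = beta_multiplier * s_j / sqrt(m)`` (``s_j``: feature
standard deviation over the presences, floored at 1e-3; ``m``: presence
count).  Optimization is cyclic coordinate descent with soft-threshold
Newton steps and backtracking; the per-update objective decreases form
the gain-increment trace that percent-contribution accounting consumes.

The regularized training gain is the improvement in mean presence
log-likelihood over the uniform background distribution.  Raw output is
the normalized Gibbs density; logistic and cloglog transforms map it to
[0, 1] using the entropy H of the fitted background distribution:
``logistic = e^H r / (1 + e^H r)``, ``cloglog = 1 - exp(-e^H r)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .errors import (
    ConfigError,
    ConvergenceError,
    DataError,
    InsufficientDataError,
    ValidationError,
)
from .raster_io import Raster, RasterStack, cell_center

__all__ = [
    "MaxentParams",
    "FeatureExpansion",
    "MaxentModel",
    "EvalResult",
    "sample_background",
    "build_features",
    "fit",
    "predict",
    "predict_raster",
    "crossvalidate",
    "auc",
    "classify_auc",
    "percent_contribution",
    "permutation_importance",
    "save_model",
    "load_model",
    "jackknife",
    "response_curve",
    "optimal_range",
]

_FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")


@dataclass(frozen=True)
class MaxentParams:
    """Tunable model settings; defaults follow common Maxent practice."""

    feature_classes: tuple = ("linear", "quadratic", "hinge")
    beta_multiplier: float = 1.0
    background_size: int = 10_000
    max_iter: int = 500
    tol: float = 1e-7
    transform: str = "cloglog"
    clamp: bool = True
    replicates: int = 10
    hinge_knots: int = 15
    seed: int = 0

    def __post_init__(self):
        for fc in self.feature_classes:
            if fc not in _FEATURE_CLASSES:
                raise ConfigError(f"unknown feature class {fc!r}")
        if self.transform not in ("raw", "logistic", "cloglog"):
            raise ConfigError(f"unknown output transform {self.transform!r}")
        if self.background_size < 2:
            raise ConfigError("background_size must be >= 2")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.beta_multiplier < 0:
            raise ConfigError("beta_multiplier must be >= 0")


@dataclass
class FeatureExpansion:
    """Deterministic mapping from raw variable values to model features.

    Scaling (min/max) and hinge/threshold knots come from the background
    sample only, so the expansion can be reused unchanged when projecting
    to other scenarios; with clamping on, projected values are clipped to
    the training range first.
    """

    variables: list[str]
    vmin: np.ndarray
    vmax: np.ndarray
    means: np.ndarray  # raw background means, for response curves
    descriptors: list[dict]

    @classmethod
    def from_background(cls, bg: pd.DataFrame, params: MaxentParams):
        variables = list(bg.columns)
        x = bg.to_numpy(dtype=float)
        if np.isnan(x).any():
            raise DataError("background values must be finite")
        vmin = x.min(axis=0)
        vmax = x.max(axis=0)
        means = x.mean(axis=0)
        desc: list[dict] = []
        classes = params.feature_classes
        for i, name in enumerate(variables):
            if "linear" in classes:
                desc.append({"kind": "linear", "vars": (name,), "knot": None})
            if "quadratic" in classes:
                desc.append({"kind": "quadratic", "vars": (name,), "knot": None})
        if "product" in classes:
            for i in range(len(variables)):
                for j in range(i + 1, len(variables)):
                    desc.append(
                        {
                            "kind": "product",
                            "vars": (variables[i], variables[j]),
                            "knot": None,
                        }
                    )
        for kind in ("hinge", "threshold"):
            if kind not in classes:
                continue
            k = params.hinge_knots
            qs = np.arange(1, k + 1) / (k + 1)
            for i, name in enumerate(variables):
                if vmax[i] <= vmin[i]:
                    continue  # constant variable: no informative knots
                knots = np.unique(np.quantile(x[:, i], qs))
                for t in knots:
                    if not (vmin[i] < t < vmax[i]):
                        continue
                    if kind == "hinge":
                        desc.append({"kind": "hinge_fwd", "vars": (name,), "knot": float(t)})
                        desc.append({"kind": "hinge_rev", "vars": (name,), "knot": float(t)})
                    else:
                        desc.append({"kind": "threshold", "vars": (name,), "knot": float(t)})
        return cls(variables, vmin, vmax, means, desc)

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def feature_vars(self) -> list[tuple]:
        return [d["vars"] for d in self.descriptors]

    def transform(self, values, clamp: bool = False) -> np.ndarray:
        """Build the feature matrix for a table of raw variable values."""
        if isinstance(values, pd.DataFrame):
            missing = [v for v in self.variables if v not in values.columns]
            if missing:
                raise DataError(f"values table missing variable(s): {missing}")
            x = values[self.variables].to_numpy(dtype=float)
        else:
            x = np.asarray(values, dtype=float)
            if x.ndim == 1:
                x = x[None, :]
            if x.shape[1] != len(self.variables):
                raise DataError(
                    f"expected {len(self.variables)} variables, got {x.shape[1]}"
                )
        if clamp:
            x = np.clip(x, self.vmin, self.vmax)
        span = np.where(self.vmax > self.vmin, self.vmax - self.vmin, 1.0)
        scaled = (x - self.vmin) / span
        col = {name: i for i, name in enumerate(self.variables)}
        out = np.empty((x.shape[0], len(self.descriptors)))
        for jf, d in enumerate(self.descriptors):
            kind = d["kind"]
            i = col[d["vars"][0]]
            if kind == "linear":
                out[:, jf] = scaled[:, i]
            elif kind == "quadratic":
                out[:, jf] = scaled[:, i] ** 2
            elif kind == "product":
                j = col[d["vars"][1]]
                out[:, jf] = scaled[:, i] * scaled[:, j]
            elif kind == "hinge_fwd":
                t = d["knot"]
                out[:, jf] = np.maximum(0.0, (x[:, i] - t) / (self.vmax[i] - t))
            elif kind == "hinge_rev":
                t = d["knot"]
                out[:, jf] = np.maximum(0.0, (t - x[:, i]) / (t - self.vmin[i]))
            elif kind == "threshold":
                out[:, jf] = (x[:, i] > d["knot"]).astype(float)
            else:  # pragma: no cover
                raise ConfigError(f"unknown descriptor kind {kind!r}")
        return out


@dataclass
class MaxentModel:
    expansion: FeatureExpansion
    lam: np.ndarray
    log_zsum: float  # log sum_background exp(lam . f)
    entropy: float  # H of the fitted distribution over background
    gain: float  # training gain (nats): mean presence log-lik vs uniform
    penalized_gain: float  # gain net of the L1 penalty; monotone in nesting
    n_presence: int
    n_background: int
    params: MaxentParams
    gain_credits: np.ndarray  # per-feature cumulative objective decrease
    fold_id: int | None = None

    def scores(self, features: np.ndarray) -> np.ndarray:
        return features @ self.lam

    def variables(self) -> list[str]:
        return list(self.expansion.variables)


@dataclass
class EvalResult:
    train_auc: list[float]
    test_auc: list[float]

    @property
    def mean_train_auc(self) -> float:
        return float(np.mean(self.train_auc))

    @property
    def mean_test_auc(self) -> float:
        vals = [v for v in self.test_auc if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd_test_auc(self) -> float:
        vals = [v for v in self.test_auc if not np.isnan(v)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": np.arange(len(self.train_auc)),
                "train_auc": self.train_auc,
                "test_auc": self.test_auc,
            }
        )


def sample_background(stack: RasterStack, size: int, seed: int):
    """Uniform seeded sample of distinct non-nodata (masked) cells.

    Returns a DataFrame ``point_id, lon, lat, <layers...>``.  If fewer
    than ``size`` cells are available, all of them are returned with a
    warning.
    """
    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    n = rows.size
    if n == 0:
        raise DataError("no valid background cells (empty mask)")
    rng = np.random.default_rng(seed)
    if size >= n:
        if size > n:
            warnings.warn(
                f"requested {size} background cells but only {n} available; using all",
                stacklevel=2,
            )
        idx = np.arange(n)
    else:
        idx = rng.choice(n, size=size, replace=False)
        idx.sort()
    r, c = rows[idx], cols[idx]
    spec = stack.spec
    lon = spec.xllcorner + (c + 0.5) * spec.cellsize
    lat = spec.yllcorner + (spec.nrows - r - 0.5) * spec.cellsize
    data = {"point_id": np.arange(len(idx)), "lon": lon, "lat": lat}
    for lyr in stack.layers:
        data[lyr.name] = lyr.values[r, c]
    return pd.DataFrame(data)


def build_features(pres: pd.DataFrame, bg: pd.DataFrame, params: MaxentParams):
    """Build presence and background feature matrices from raw value
    tables (same variable columns), plus the expansion used."""
    cols = [c for c in bg.columns if c not in ("point_id", "lon", "lat", "has_nodata")]
    expansion = FeatureExpansion.from_background(bg[cols], params)
    Fp = expansion.transform(pres, clamp=params.clamp)
    Fb = expansion.transform(bg[cols], clamp=False)
    return Fp, Fb, expansion


def fit(
    Fp: np.ndarray,
    Fb: np.ndarray,
    expansion: FeatureExpansion,
    params: MaxentParams,
    fold_id: int | None = None,
    lam0: np.ndarray | None = None,
) -> MaxentModel:
    """Minimize the L1-regularized objective by coordinate descent.

    ``lam0`` warm-starts the solver (e.g. across CV folds).  Raises
    :class:`ConvergenceError` if the per-cycle objective decrease has not
    reached ``params.tol`` within ``params.max_iter`` full cycles.
    """
    Fp = np.asarray(Fp, dtype=float)
    Fb = np.asarray(Fb, dtype=float)
    m, nf = Fp.shape
    B = Fb.shape[0]
    if m < 2:
        raise InsufficientDataError(f"need >= 2 presences, got {m}")
    if B < 2:
        raise InsufficientDataError(f"need >= 2 background cells, got {B}")
    if Fb.shape[1] != nf:
        raise DataError("presence/background feature dimension mismatch")

    pbar = Fp.mean(axis=0)
    s = np.maximum(Fp.std(axis=0), 1e-3)
    beta = params.beta_multiplier * s / np.sqrt(m)
    Fb2 = Fb * Fb

    lam = np.zeros(nf) if lam0 is None else np.array(lam0, dtype=float)
    u = Fb @ lam
    shift = float(u.max())
    w = np.exp(u - shift)
    S = float(w.sum())
    credits = np.zeros(nf)

    def sweep(indices):
        """One pass over the given coordinates; returns objective decrease."""
        nonlocal S
        dec = 0.0
        for j in indices:
            fj = Fb[:, j]
            qj = (w @ fj) / S
            q2 = (w @ Fb2[:, j]) / S
            g = qj - pbar[j]
            h = max(q2 - qj * qj, 1e-12)
            z = lam[j] - g / h
            bj = beta[j]
            if abs(z) * h <= bj:
                target = 0.0
            else:
                target = z - np.sign(z) * bj / h
            delta = target - lam[j]
            if abs(delta) < 1e-14:
                continue
            delta = float(np.clip(delta, -20.0, 20.0))
            accepted = False
            for _ in range(40):
                e = np.exp(delta * fj)
                S_new = float(w @ e)
                d_obj = (
                    -delta * pbar[j]
                    + np.log(S_new / S)
                    + bj * (abs(lam[j] + delta) - abs(lam[j]))
                )
                if d_obj <= 1e-15:
                    accepted = True
                    break
                delta *= 0.5
                if abs(delta) < 1e-14:
                    break
            if not accepted:
                continue
            lam[j] += delta
            u[:] += delta * fj
            w[:] *= e
            S = S_new
            credits[j] += -d_obj
            dec += -d_obj
        return dec

    def renormalize():
        nonlocal shift, w, S
        shift = float(u.max())
        w = np.exp(u - shift)
        S = float(w.sum())

    converged = False
    final_dec = np.inf
    all_idx = np.arange(nf)
    for _cycle in range(params.max_iter):
        renormalize()
        dec = sweep(all_idx)
        final_dec = dec
        if dec < params.tol:
            converged = True
            break
        # refine the active set cheaply between full passes
        for _ in range(20):
            active = np.nonzero(lam)[0]
            if active.size == 0:
                break
            d = sweep(active)
            if d < params.tol:
                break
    if not converged:
        raise ConvergenceError(
            f"coordinate descent did not converge in {params.max_iter} cycles "
            f"(last full-cycle decrease {final_dec:.3e})",
            final_delta=final_dec,
        )

    renormalize()
    log_zsum = float(logsumexp(u))
    p = w / S
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = float(-plogp.sum())
    gain = float(Fp.mean(axis=0) @ lam - log_zsum + np.log(B))
    return MaxentModel(
        expansion=expansion,
        lam=lam,
        log_zsum=log_zsum,
        entropy=entropy,
        gain=gain,
        penalized_gain=gain - float(beta @ np.abs(lam)),
        n_presence=m,
        n_background=B,
        params=params,
        gain_credits=credits,
        fold_id=fold_id,
    )


def _transform_raw(raw: np.ndarray, entropy: float, transform: str) -> np.ndarray:
    if transform == "raw":
        return raw
    eh = np.exp(entropy)
    if transform == "logistic":
        return eh * raw / (1.0 + eh * raw)
    if transform == "cloglog":
        return 1.0 - np.exp(-eh * raw)
    raise ConfigError(f"unknown output transform {transform!r}")


def predict(model: MaxentModel, values, transform: str | None = None) -> np.ndarray:
    """Suitability for a table of raw variable values.

    ``raw`` is the normalized Gibbs density relative to the training
    background (it sums to 1 over that background); logistic and cloglog
    are monotone maps of raw into [0, 1].
    """
    transform = transform or model.params.transform
    F = model.expansion.transform(values, clamp=model.params.clamp)
    raw = np.exp(model.scores(F) - model.log_zsum)
    return _transform_raw(raw, model.entropy, transform)


def predict_raster(
    model: MaxentModel, stack: RasterStack, transform: str | None = None
) -> Raster:
    """Project the model over a stack; nodata propagates."""
    missing = [v for v in model.expansion.variables if v not in stack.names]
    if missing:
        raise DataError(f"projection stack missing variable(s): {missing}")
    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    table = pd.DataFrame(
        {v: stack.get(v).values[rows, cols] for v in model.expansion.variables}
    )
    pred = predict(model, table, transform=transform)
    out = np.full((stack.spec.nrows, stack.spec.ncols), np.nan)
    out[rows, cols] = pred
    return Raster(stack.spec, out, name="suitability")


def crossvalidate(
    pres_values: pd.DataFrame,
    bg_values: pd.DataFrame,
    params: MaxentParams,
    stack: RasterStack | None = None,
):
    """k-fold cross-validation with a shared background sample.

    Presences are partitioned into ``params.replicates`` seeded folds;
    each model trains on the remaining folds and is scored (AUC) on the
    held-out fold against the background.  The summary suitability raster
    is the arithmetic mean of the per-fold rasters.  Returns
    ``(models, EvalResult, mean_raster_or_None)``.
    """
    k = params.replicates
    var_cols = [
        c for c in pres_values.columns if c not in ("point_id", "lon", "lat", "has_nodata")
    ]
    pres = pres_values[var_cols]
    m = len(pres)
    if m < k:
        raise InsufficientDataError(
            f"{m} presences cannot fill {k} folds; use fewer replicates"
        )
    Fp, Fb, expansion = build_features(pres, bg_values, params)
    rng = np.random.default_rng(params.seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k)
    for f in folds:
        if f.size == 0:
            raise InsufficientDataError("empty cross-validation fold; reduce k")

    models: list[MaxentModel] = []
    train_aucs: list[float] = []
    test_aucs: list[float] = []
    warm = None
    for i, test_idx in enumerate(folds):
        if k == 1:
            train_idx = test_idx
            test_idx = np.array([], dtype=int)
        else:
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        model = fit(Fp[train_idx], Fb, expansion, params, fold_id=i, lam0=warm)
        warm = model.lam
        bg_scores = model.scores(Fb)
        train_aucs.append(auc(model.scores(Fp[train_idx]), bg_scores))
        if test_idx.size:
            test_aucs.append(auc(model.scores(Fp[test_idx]), bg_scores))
        else:
            test_aucs.append(float("nan"))
        models.append(model)

    mean_raster = None
    if stack is not None:
        acc = None
        for model in models:
            r = predict_raster(model, stack)
            acc = r.values if acc is None else acc + r.values
        mean_raster = Raster(stack.spec, acc / len(models), name="suitability_mean")
    return models, EvalResult(train_aucs, test_aucs), mean_raster


def auc(pos_scores, neg_scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("AUC needs nonempty score sets")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def classify_auc(value: float) -> str:
    """Discriminative-accuracy band for an AUC value."""
    if not 0 <= value <= 1:
        raise ValidationError(f"AUC must lie in [0, 1], got {value}")
    if value > 0.9:
        return "very-high"
    if value > 0.8:
        return "good"
    if value > 0.7:
        return "average"
    if value > 0.6:
        return "poor"
    if value >= 0.5:
        return "failure"
    return "worse-than-random"


def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Heuristic credit of training-gain increments to source variables.

    Product features split their credit evenly between the two sources;
    negative credits are floored at zero; the result is normalized to sum
    to 100.  A zero-gain model yields equal shares.
    """
    credit = {v: 0.0 for v in model.expansion.variables}
    for c, vars_ in zip(model.gain_credits, model.expansion.feature_vars()):
        c = max(0.0, float(c))
        share = c / len(vars_)
        for v in vars_:
            credit[v] += share
    total = sum(credit.values())
    if total <= 0:
        n = len(credit)
        return {v: 100.0 / n for v in credit}
    return {v: 100.0 * c / total for v, c in credit.items()}


def permutation_importance(
    model: MaxentModel,
    pres_values: pd.DataFrame,
    bg_values: pd.DataFrame,
    seed: int = 0,
) -> dict[str, float]:
    """Training-AUC drop when one variable is permuted jointly across
    presences and background, floored at 0 and normalized to sum 100."""
    variables = model.expansion.variables
    var_cols = list(variables)
    pres = pres_values[var_cols].reset_index(drop=True)
    bg = bg_values[var_cols].reset_index(drop=True)
    both = pd.concat([pres, bg], ignore_index=True)
    n_pres = len(pres)

    def scores_of(table):
        F = model.expansion.transform(table, clamp=model.params.clamp)
        return model.scores(F)

    base = scores_of(both)
    auc0 = auc(base[:n_pres], base[n_pres:])
    rng = np.random.default_rng(seed)
    drops = {}
    for v in variables:
        shuffled = both.copy()
        shuffled[v] = rng.permutation(shuffled[v].to_numpy())
        sc = scores_of(shuffled)
        drops[v] = max(0.0, auc0 - auc(sc[:n_pres], sc[n_pres:]))
    total = sum(drops.values())
    if total <= 0:
        n = len(drops)
        return {v: 100.0 / n for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


def jackknife(
    pres_values: pd.DataFrame, bg_values: pd.DataFrame, params: MaxentParams
) -> dict:
    """Per-variable with-only / without training gains plus the full-model
    gain, all with the same seed and settings."""
    var_cols = [
        c for c in pres_values.columns if c not in ("point_id", "lon", "lat", "has_nodata")
    ]
    if len(var_cols) < 2:
        raise InsufficientDataError("jackknife needs >= 2 variables")

    def gains_of(cols):
        Fp, Fb, expansion = build_features(pres_values[cols], bg_values[cols], params)
        m = fit(Fp, Fb, expansion, params)
        return m.gain, m.penalized_gain

    full, full_pen = gains_of(var_cols)
    out = {"full_gain": full, "full_penalized_gain": full_pen, "variables": {}}
    for v in var_cols:
        only, only_pen = gains_of([v])
        without, without_pen = gains_of([c for c in var_cols if c != v])
        out["variables"][v] = {
            "gain_with_only": only,
            "gain_without": without,
            "penalized_gain_with_only": only_pen,
            "penalized_gain_without": without_pen,
        }
    return out


def save_model(model: MaxentModel, path) -> str:
    """Dump a fitted model as structured text (YAML): feature descriptors,
    weights, scaling, and the output-transform constants."""
    import yaml

    doc = {
        "variables": list(model.expansion.variables),
        "vmin": [float(v) for v in model.expansion.vmin],
        "vmax": [float(v) for v in model.expansion.vmax],
        "means": [float(v) for v in model.expansion.means],
        "descriptors": [
            {"kind": d["kind"], "vars": list(d["vars"]), "knot": d["knot"]}
            for d in model.expansion.descriptors
        ],
        "lam": [float(v) for v in model.lam],
        "log_zsum": model.log_zsum,
        "entropy": model.entropy,
        "gain": model.gain,
        "penalized_gain": model.penalized_gain,
        "n_presence": model.n_presence,
        "n_background": model.n_background,
        "transform": model.params.transform,
        "clamp": model.params.clamp,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return str(path)


def load_model(path) -> MaxentModel:
    """Reconstruct a model saved with :func:`save_model` (for projection)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    expansion = FeatureExpansion(
        variables=list(doc["variables"]),
        vmin=np.array(doc["vmin"], dtype=float),
        vmax=np.array(doc["vmax"], dtype=float),
        means=np.array(doc["means"], dtype=float),
        descriptors=[
            {"kind": d["kind"], "vars": tuple(d["vars"]), "knot": d["knot"]}
            for d in doc["descriptors"]
        ],
    )
    params = MaxentParams(transform=doc["transform"], clamp=doc["clamp"])
    lam = np.array(doc["lam"], dtype=float)
    return MaxentModel(
        expansion=expansion,
        lam=lam,
        log_zsum=float(doc["log_zsum"]),
        entropy=float(doc["entropy"]),
        gain=float(doc["gain"]),
        penalized_gain=float(doc.get("penalized_gain", doc["gain"])),
        n_presence=int(doc["n_presence"]),
        n_background=int(doc["n_background"]),
        params=params,
        gain_credits=np.zeros(len(lam)),
    )


@dataclass
class ResponseCurve:
    variable: str
    grid: np.ndarray
    prediction: np.ndarray


def response_curve(model: MaxentModel, variable: str, n: int = 100) -> ResponseCurve:
    """Marginal response: sweep one variable over its background range
    with every other variable held at its background mean."""
    if variable not in model.expansion.variables:
        raise ConfigError(f"variable {variable!r} not in model")
    i = model.expansion.variables.index(variable)
    grid = np.linspace(model.expansion.vmin[i], model.expansion.vmax[i], n)
    table = pd.DataFrame(
        {
            v: (grid if v == variable else np.full(n, model.expansion.means[j]))
            for j, v in enumerate(model.expansion.variables)
        }
    )
    pred = predict(model, table)
    return ResponseCurve(variable, grid, pred)


def optimal_range(curve: ResponseCurve, level: float = 0.5) -> list[tuple[float, float]]:
    """Maximal contiguous intervals of the sweep where predicted
    suitability >= level, with linear interpolation at the crossings."""
    x, y = curve.grid, curve.prediction
    above = y >= level
    intervals: list[tuple[float, float]] = []
    start = None
    for i in range(len(x)):
        if above[i] and start is None:
            if i == 0:
                start = x[0]
            else:
                t = (level - y[i - 1]) / (y[i] - y[i - 1])
                start = x[i - 1] + t * (x[i] - x[i - 1])
        elif not above[i] and start is not None:
            t = (level - y[i - 1]) / (y[i] - y[i - 1])
            intervals.append((start, x[i - 1] + t * (x[i] - x[i - 1])))
            start = None
    if start is not None:
        intervals.append((start, x[-1]))
    return intervals
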