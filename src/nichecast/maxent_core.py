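"""Presence-only maximum-entropy (Gibbs) density estimation over grid cells.

The model is the distribution q(x) ∝ exp(λ·f(x)) over background cells that
is closest to uniform subject to matching the presence-sample feature means,
found by minimising the L1-regularised convex objective

    F(λ) = −(1/m) Σ_i λ·f(x_i) + ln Σ_{x∈B} exp(λ·f(x)) + Σ_j β_j |λ_j|

over feature weights λ (m presences, background B).  Features are built
from covariates scaled to [0, 1] by their training bounds: linear,
quadratic, pairwise product, forward hinge and step (threshold) classes,
with the active classes chosen from the presence count the way the
reference MaxEnt tool's defaults do.  The nonsmooth L1 term is handled by
splitting λ = λ⁺ − λ⁻ with λ± ≥ 0, which turns F into a smooth objective
on the non-negative orthant solved by bound-constrained quasi-Newton
iteration.

Prediction applies the fitted weights to features computed on a (possibly
future) covariate stack; with clamping on, scaled covariates are truncated
to the training [0, 1] range first, so projections never use conditions
outside those encountered in training.  The raw output is normalised over
the *training* background; the logistic output is the entropy-calibrated
transform logistic(x) = τ e^η / (1 − τ + τ e^η) with η(x) = ln raw(x) + H
and prevalence τ (default 0.5), interpretable as habitat suitability in
(0, 1) and equal to τ at a cell of typical (entropy-level) suitability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, xlogy

from .geo_io import ClimateStack, Grid

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "PredictionGrid",
    "auto_feature_classes",
    "compute_bounds",
    "build_features",
    "fit_lambdas",
    "fit_maxent",
    "predict",
]

FEATURE_CLASS_ORDER = ("linear", "quadratic", "product", "hinge", "threshold")

#: Default per-class L1 penalty multipliers (flat values; the reference tool
#: interpolates tables keyed by sample size — behaviour, not bits).
DEFAULT_BETA_CLASS = {
    "linear": 1.0, "quadratic": 1.0, "product": 1.0, "hinge": 0.5, "threshold": 1.0,
}

DEFAULT_N_KNOTS = 30
DEFAULT_MAX_BACKGROUND = 10_000
BETA_FLOOR = 1e-4  # keeps the optimum finite when a feature is constant on presences


def auto_feature_classes(m: int) -> set[str]:
    """Feature classes enabled by presence count, following the reference
    tool's defaults: <10 linear; <15 +quadratic; <80 +hinge; ≥80 all five."""
    if m < 1:
        raise ValueError("need at least one presence")
    if m < 10:
        return {"linear"}
    if m < 15:
        return {"linear", "quadratic"}
    if m < 80:
        return {"linear", "quadratic", "hinge"}
    return set(FEATURE_CLASS_ORDER)


@dataclass
class FeatureSpec:
    """Feature recipe: active classes, per-covariate scaling bounds computed
    on the training data, and evenly spaced hinge/threshold knots."""

    classes: set[str]
    covariates: list[str]          # retained, in fixed (sorted) order
    bounds: dict[str, tuple[float, float]]
    n_knots: int = DEFAULT_N_KNOTS
    dropped: list[str] = field(default_factory=list)  # constant covariates

    def __post_init__(self) -> None:
        bad = self.classes - set(FEATURE_CLASS_ORDER)
        if bad:
            raise ValueError(f"unknown feature classes {sorted(bad)}")
        for name in self.covariates:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bounds for {name!r}: ({lo}, {hi})")

    @property
    def knots(self) -> np.ndarray:
        return np.arange(self.n_knots) / self.n_knots

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for cls in FEATURE_CLASS_ORDER:
            if cls not in self.classes:
                continue
            if cls == "linear":
                names += [f"linear:{c}" for c in self.covariates]
            elif cls == "quadratic":
                names += [f"quadratic:{c}" for c in self.covariates]
            elif cls == "product":
                names += [f"product:{a}*{b}"
                          for i, a in enumerate(self.covariates)
                          for b in self.covariates[i + 1:]]
            else:
                names += [f"{cls}:{c}@{k}" for c in self.covariates
                          for k in range(self.n_knots)]
        return names


def compute_bounds(design: np.ndarray, names: list[str]) -> tuple[dict[str, tuple[float, float]], list[str]]:
    """Min/max per covariate column; constant columns are reported separately."""
    bounds: dict[str, tuple[float, float]] = {}
    dropped: list[str] = []
    for j, name in enumerate(names):
        lo, hi = float(np.min(design[:, j])), float(np.max(design[:, j]))
        if hi - lo <= 0:
            dropped.append(name)
        else:
            bounds[name] = (lo, hi)
    return bounds, dropped


def scale_design(design: np.ndarray, names: list[str], spec: FeatureSpec,
                 clamp: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Scale covariate columns to [0, 1] by training bounds.

    Returns (scaled matrix over ``spec.covariates`` order, per-row flag that
    at least one covariate fell outside the training range).  With ``clamp``
    the scaled values are truncated to [0, 1].
    """
    col = {n: j for j, n in enumerate(names)}
    missing = [c for c in spec.covariates if c not in col]
    if missing:
        raise KeyError(f"covariates missing from stack: {missing}")
    out = np.empty((design.shape[0], len(spec.covariates)))
    for j, c in enumerate(spec.covariates):
        lo, hi = spec.bounds[c]
        out[:, j] = (design[:, col[c]] - lo) / (hi - lo)
    outside = np.any((out < 0) | (out > 1), axis=1)
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return out, outside


def build_features(scaled: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Feature matrix from a scaled design, columns in the fixed
    (class, covariate, knot) order of ``spec.feature_names()``."""
    blocks: list[np.ndarray] = []
    knots = spec.knots
    for cls in FEATURE_CLASS_ORDER:
        if cls not in spec.classes:
            continue
        if cls == "linear":
            blocks.append(scaled)
        elif cls == "quadratic":
            blocks.append(scaled**2)
        elif cls == "product":
            n = scaled.shape[1]
            if n >= 2:
                cols = [scaled[:, i] * scaled[:, j]
                        for i in range(n) for j in range(i + 1, n)]
                blocks.append(np.column_stack(cols))
        elif cls == "hinge":
            # forward hinge: 0 below the knot, rising linearly to 1 at the max
            h = (scaled[:, :, None] - knots) / (1.0 - knots)
            blocks.append(np.maximum(h, 0.0).reshape(scaled.shape[0], -1))
        elif cls == "threshold":
            t = (scaled[:, :, None] > knots).astype(float)
            blocks.append(t.reshape(scaled.shape[0], -1))
    return np.hstack([b for b in blocks if b.size]) if blocks else np.empty((scaled.shape[0], 0))


def default_betas(presence_features: np.ndarray, spec: FeatureSpec,
                  beta_class: dict[str, float] | None = None) -> np.ndarray:
    """β_j = β_class(j) · s_j / √m with s_j the presence-sample standard
    deviation of feature j, floored to keep the optimum finite."""
    beta_class = dict(DEFAULT_BETA_CLASS, **(beta_class or {}))
    m = presence_features.shape[0]
    s = presence_features.std(axis=0, ddof=1) if m > 1 else np.zeros(presence_features.shape[1])
    names = spec.feature_names()
    mult = np.array([beta_class[n.split(":", 1)[0]] for n in names])
    return np.maximum(mult * s / np.sqrt(m), BETA_FLOOR)


def fit_lambdas(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    betas: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> tuple[np.ndarray, list[float], dict]:
    """Minimise the L1-penalised objective; returns (λ, objective trajectory,
    info).  Deterministic: cold start at λ = 0, no randomness."""
    m, d = presence_features.shape
    if m < 1 or background_features.shape[0] < 2:
        raise ValueError("need ≥1 presence and ≥2 background cells")
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (d,) or np.any(betas < 0):
        raise ValueError("betas must be non-negative, one per feature")
    p_mean = presence_features.mean(axis=0)
    B = background_features

    def smooth_val_grad(lam: np.ndarray) -> tuple[float, np.ndarray]:
        eta = B @ lam
        lse = logsumexp(eta)
        w = np.exp(eta - lse)
        val = -p_mean @ lam + lse
        grad = -p_mean + B.T @ w
        if not np.isfinite(val):
            raise FloatingPointError("non-finite maxent objective")
        return float(val), grad

    def split_obj(z: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = z[:d], z[d:]
        val, grad = smooth_val_grad(u - v)
        val += betas @ (u + v)
        return val, np.concatenate([grad + betas, -grad + betas])

    trajectory: list[float] = []

    def record(z: np.ndarray) -> None:
        u, v = z[:d], z[d:]
        val, _ = smooth_val_grad(u - v)
        trajectory.append(val + float(betas @ (u + v)))

    z0 = np.zeros(2 * d)
    record(z0)
    res = minimize(split_obj, z0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * d), callback=record,
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9})
    if not res.success and res.status == 1:  # hit the iteration cap
        raise RuntimeError(
            f"maxent fit did not converge in {max_iter} iterations; "
            f"final projected-gradient norm {np.max(np.abs(res.jac)):.3e}")
    lam = res.x[:d] - res.x[d:]
    info = {"n_iter": int(res.nit), "objective": float(res.fun),
            "grad_norm": float(np.max(np.abs(res.jac)))}
    return lam, trajectory, info


@dataclass
class MaxentModel:
    """A fitted maxent niche model, sufficient to reproduce its predictions."""

    spec: FeatureSpec
    lambdas: np.ndarray
    betas: np.ndarray
    entropy_H: float
    tau: float
    log_z_train: float
    background_cells: np.ndarray       # flat indices into the training grid
    background_checksum: str
    objective_trajectory: list[float] = field(default_factory=list)
    fit_info: dict = field(default_factory=dict)

    def linear_score(self, stack: ClimateStack, clamp: bool = True
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(λ·f per unmasked cell, flat indices, clamped flags)."""
        design, idx = stack_design(stack)
        scaled, outside = scale_design(design, stack.names, self.spec, clamp=clamp)
        feats = build_features(scaled, self.spec)
        return feats @ self.lambdas, idx, outside

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "classes": sorted(self.spec.classes),
            "covariates": self.spec.covariates,
            "bounds": {k: list(v) for k, v in self.spec.bounds.items()},
            "n_knots": self.spec.n_knots,
            "dropped": self.spec.dropped,
            "feature_names": self.spec.feature_names(),
            "lambdas": self.lambdas.tolist(),
            "betas": self.betas.tolist(),
            "entropy_H": self.entropy_H,
            "tau": self.tau,
            "log_z_train": self.log_z_train,
            "background_checksum": self.background_checksum,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "MaxentModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        doc = json.loads(text)
        spec = FeatureSpec(set(doc["classes"]), list(doc["covariates"]),
                           {k: tuple(v) for k, v in doc["bounds"].items()},
                           int(doc["n_knots"]), list(doc["dropped"]))
        return cls(spec, np.array(doc["lambdas"]), np.array(doc["betas"]),
                   float(doc["entropy_H"]), float(doc["tau"]),
                   float(doc["log_z_train"]), np.array([], dtype=int),
                   doc["background_checksum"])


@dataclass
class PredictionGrid:
    """Raw (relative density), logistic (suitability) and clamp-flag layers."""

    raw: Grid
    logistic: Grid
    clamped_flags: Grid


def stack_design(stack: ClimateStack) -> tuple[np.ndarray, np.ndarray]:
    """Covariate matrix over unmasked cells + their flat indices."""
    mask = stack.combined_mask()
    idx = np.flatnonzero(~mask.ravel())
    cols = [stack[name].values.ravel()[idx] for name in stack.names]
    return np.column_stack(cols), idx


def select_background(stack: ClimateStack, max_background: int = DEFAULT_MAX_BACKGROUND,
                      seed: int = 0) -> np.ndarray:
    """Flat indices of the training background: every unmasked cell, or a
    seeded uniform sample of ``max_background`` of them."""
    mask = stack.combined_mask()
    idx = np.flatnonzero(~mask.ravel())
    if idx.size > max_background:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_background, replace=False))
    return idx


def _cells_to_flat(cells, n_cols: int) -> np.ndarray:
    arr = np.asarray(cells)
    if arr.ndim == 1:
        return arr.astype(int)
    return (arr[:, 0] * n_cols + arr[:, 1]).astype(int)


def fit_maxent(
    stack: ClimateStack,
    presence_cells,
    background: np.ndarray | None = None,
    classes: set[str] | None = None,
    beta_class: dict[str, float] | None = None,
    betas: np.ndarray | None = None,
    tau: float = 0.5,
    n_knots: int = DEFAULT_N_KNOTS,
    max_background: int = DEFAULT_MAX_BACKGROUND,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int = 0,
) -> MaxentModel:
    """Fit a maxent model to presence cells over a covariate stack.

    ``presence_cells`` may be (row, col) pairs or flat indices; duplicates
    should already be collapsed (distinct cells are what the model sees).
    Scaling bounds are computed over background ∪ presences so training
    features always lie in [0, 1].
    """
    tmpl = stack.template
    pres_idx = _cells_to_flat(presence_cells, tmpl.n_cols)
    if pres_idx.size < 1:
        raise ValueError("need at least one presence cell")
    mask_flat = stack.combined_mask().ravel()
    if np.any(mask_flat[pres_idx]):
        bad = pres_idx[mask_flat[pres_idx]][:5]
        raise ValueError(f"presence cells on nodata: flat indices {bad.tolist()}")
    if background is None:
        background = select_background(stack, max_background, seed)
    background = np.asarray(background, dtype=int)
    if background.size < 2:
        raise ValueError("background must have at least 2 cells")

    names = stack.names
    all_idx = np.concatenate([background, pres_idx])
    design_all = np.column_stack([stack[n].values.ravel()[all_idx] for n in names])
    bounds, dropped = compute_bounds(design_all, names)
    covariates = sorted(bounds)
    if not covariates:
        raise ValueError("all covariates are constant over the training data")
    m = pres_idx.size
    spec = FeatureSpec(classes if classes is not None else auto_feature_classes(m),
                       covariates, bounds, n_knots, dropped)

    scaled_all, _ = scale_design(design_all, names, spec, clamp=False)
    feats_all = build_features(scaled_all, spec)
    B = feats_all[: background.size]
    P = feats_all[background.size:]
    if betas is None:
        betas = default_betas(P, spec, beta_class)
    lam, trajectory, info = fit_lambdas(P, B, betas, tol, max_iter)

    eta_b = B @ lam
    log_z = float(logsumexp(eta_b))
    q = np.exp(eta_b - log_z)
    entropy_H = float(-np.sum(xlogy(q, q)))
    checksum = hashlib.sha256(background.tobytes()).hexdigest()[:16]
    return MaxentModel(spec, lam, np.asarray(betas), entropy_H, tau, log_z,
                       background, checksum, trajectory, info)


def predict(model: MaxentModel, stack: ClimateStack, clamp: bool = True) -> PredictionGrid:
    """Apply a fitted model to a covariate stack.

    raw(x) = exp(λ·f(x)) / Z_train (training-background normaliser);
    logistic(x) = τ e^η / (1 + τ e^η) with η = ln raw + H.  With ``clamp``
    (the default) scaled features are truncated to the training range and
    cells needing truncation are flagged.
    """
    score, idx, outside = model.linear_score(stack, clamp=clamp)
    tmpl = stack.template
    shape = tmpl.values.shape
    mask = stack.combined_mask()

    log_raw = score - model.log_z_train
    eta = log_raw + model.entropy_H
    # logistic = tau*e^eta / (1 - tau + tau*e^eta) = sigmoid(logit(tau) + eta):
    # 0.5 exactly where eta = 0 at the default prevalence.  Clip away float
    # under/overflow so the output stays strictly inside (0, 1).
    logistic = expit(np.log(model.tau / (1.0 - model.tau)) + eta)
    logistic = np.clip(logistic, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))

    def as_grid(flat_vals: np.ndarray) -> Grid:
        full = np.full(shape[0] * shape[1], np.nan)
        full[idx] = flat_vals
        return tmpl.copy_with(full.reshape(shape), mask)

    return PredictionGrid(
        raw=as_grid(np.exp(log_raw)),
        logistic=as_grid(logistic),
        clamped_flags=as_grid(outside.astype(float)),
    )
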