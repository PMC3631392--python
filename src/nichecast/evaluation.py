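"""Cross-validated model evaluation and the pseudo-presence protocol.

Presence-only evaluation: each rotation of a k-fold plan (default k = 4,
i.e. 75% training / 25% testing) refits the model on the training
presences and scores the held-out presences against a shared seeded
background sample; AUC is the Mann–Whitney rank probability that a test
presence outscores a background cell.  The same fold plan is reused when
comparing covariate sets (with vs without forest) so both conditions see
identical partitions, and the paired t-test over species' mean AUCs
quantifies the difference.

The pseudo-presence protocol trains instead on random draws from a refined
extent-of-occurrence mask (polygon ∩ forest threshold ∩ altitude band),
split into k quarters, and tests each quarter's model against a quarter of
the *real* presences — the design used to ask whether range polygons can
substitute for occurrence records when records are scarce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from shapely import contains_xy

from .geo_io import ClimateStack, Grid, OccurrenceSet, PolygonSet, check_coregistered
from .maxent_core import fit_maxent, predict, select_background
from .stats import TestResult, paired_t

__all__ = [
    "FoldPlan",
    "EvalResult",
    "make_folds",
    "auc",
    "crossval",
    "compare_covariate_sets",
    "refine_eoo",
    "draw_pseudo_presences",
    "pseudo_protocol",
    "recovery_spearman",
]


@dataclass
class FoldPlan:
    """Seeded partition of presence cells into k folds (sizes differ ≤ 1)."""

    k: int
    assignments: np.ndarray  # fold id per presence cell
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


@dataclass
class EvalResult:
    """Per-fold AUCs with their mean and (non-negative) standard deviation."""

    fold_aucs: list[float]
    condition: str = ""

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1)) if len(self.fold_aucs) > 1 else 0.0


def make_folds(occ: OccurrenceSet, k: int = 4, seed: int = 0) -> FoldPlan:
    """Seeded uniform partition of the distinct presence cells into k folds."""
    n = occ.n_cells
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if n < k:
        raise ValueError(f"{occ.species}: {n} presence cells < {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    assignments[order] = np.arange(n) % k
    return FoldPlan(k, assignments, seed)


def auc(pos_scores, neg_scores) -> float:
    """Mann–Whitney AUC: P(pos > neg) + ½ P(pos = neg), midrank ties."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def recovery_spearman(pred_logistic: Grid, true_suit: Grid,
                      envelope_frac: float = 1e-3) -> float:
    """Spearman rank correlation between fitted suitability and a known true
    suitability, over the species' plausible envelope (cells where the truth
    exceeds ``envelope_frac`` of its maximum).  Outside that envelope the
    true values are vanishingly small floats whose ordering carries no
    ecological information, so they are excluded from the rank comparison."""
    from scipy.stats import spearmanr

    ok = ~(pred_logistic.mask | true_suit.mask)
    L, S = pred_logistic.values[ok], true_suit.values[ok]
    keep = S > envelope_frac * np.nanmax(S)
    if keep.sum() < 3:
        raise ValueError("true-suitability envelope has fewer than 3 cells")
    return float(spearmanr(L[keep], S[keep]).statistic)


def _background_sample(stack: ClimateStack, seed: int) -> np.ndarray:
    # one shared seeded sample per evaluation: AUC negatives and the fit
    # background coincide, removing a variance source between rotations
    return select_background(stack, seed=seed)


def _score_at(pred_logistic: Grid, flat_idx: np.ndarray) -> np.ndarray:
    return pred_logistic.values.ravel()[flat_idx]


def crossval(
    occ: OccurrenceSet,
    stack: ClimateStack,
    plan: FoldPlan,
    model_config: dict | None = None,
    seed: int = 0,
    condition: str = "",
) -> EvalResult:
    """k-fold cross-validated AUC for one species on one covariate stack."""
    if plan.assignments.size != occ.n_cells:
        raise ValueError("fold plan was not built from this occurrence set")
    cfg = dict(model_config or {})
    cfg.setdefault("seed", seed)
    background = _background_sample(stack, seed)
    cells = np.array([r * stack.template.n_cols + c for r, c in occ.presence_cells])
    aucs: list[float] = []
    for fold in range(plan.k):
        train, test = plan.train_test(fold)
        try:
            model = fit_maxent(stack, cells[train], background=background, **cfg)
            pred = predict(model, stack, clamp=True)
        except Exception as exc:
            raise RuntimeError(f"{occ.species}: fold {fold} failed: {exc}") from exc
        aucs.append(auc(_score_at(pred.logistic, cells[test]),
                        _score_at(pred.logistic, background)))
    return EvalResult(aucs, condition)


def compare_covariate_sets(
    occ_by_species: dict[str, OccurrenceSet],
    stack_without: ClimateStack,
    stack_with: ClimateStack,
    plans: dict[str, FoldPlan],
    model_config: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TestResult]:
    """Paired per-species mean AUCs for two covariate sets + paired t-test.

    The same fold plan per species is used for both sets, so the two
    conditions see identical training/testing partitions.
    """
    rows = []
    for species, occ in occ_by_species.items():
        plan = plans[species]
        without = crossval(occ, stack_without, plan, model_config, seed, "without_forest")
        with_f = crossval(occ, stack_with, plan, model_config, seed, "with_forest")
        rows.append({
            "species": species,
            "mean_auc_without": without.mean_auc, "sd_auc_without": without.sd_auc,
            "mean_auc_with": with_f.mean_auc, "sd_auc_with": with_f.sd_auc,
            "fold_aucs_without": without.fold_aucs, "fold_aucs_with": with_f.fold_aucs,
        })
    table = pd.DataFrame(rows)
    diffs = table["mean_auc_with"] - table["mean_auc_without"]
    if np.allclose(diffs, 0.0):
        ttest = TestResult(0.0, len(diffs) - 1, 1.0, "paired t-test")
    else:
        ttest = paired_t(table["mean_auc_with"].to_numpy(),
                         table["mean_auc_without"].to_numpy())
    return table, ttest


def refine_eoo(
    poly: PolygonSet,
    forest_pct: Grid | None,
    min_forest: float,
    alt_range: tuple[float, float],
    dem: Grid,
) -> Grid:
    """Refined extent-of-occurrence mask: cells whose centre lies inside the
    polygon, with forest cover ≥ ``min_forest`` % and altitude within
    ``alt_range``.  Returns a 0/1 grid; raises if no cell qualifies."""
    grids = [dem] + ([forest_pct] if forest_pct is not None else [])
    check_coregistered(grids)
    lon, lat = dem.center_coords()
    inside = contains_xy(poly.union(), lon.ravel(), lat.ravel()).reshape(lon.shape)
    ok = inside & ~dem.mask
    lo, hi = alt_range
    ok &= (dem.values >= lo) & (dem.values <= hi)
    if forest_pct is not None:
        ok &= ~forest_pct.mask & (forest_pct.values >= min_forest)
    if not ok.any():
        raise ValueError(f"{poly.species}: refined EOO mask is empty")
    return dem.copy_with(ok.astype(float), np.zeros_like(ok))


def draw_pseudo_presences(mask: Grid, n: int, seed: int,
                          species: str = "pseudo") -> OccurrenceSet:
    """Seeded uniform draw of n distinct cells from a 0/1 mask grid."""
    candidates = np.flatnonzero((mask.values.ravel() == 1) & ~mask.mask.ravel())
    if candidates.size == 0:
        raise ValueError("mask has no cells to sample")
    if n > candidates.size:
        raise ValueError(f"cannot draw {n} distinct cells from a mask of {candidates.size}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=False)
    cells = [(int(i // mask.n_cols), int(i % mask.n_cols)) for i in chosen]
    coords = [mask.cell_center(r, c) for r, c in cells]
    return OccurrenceSet(species, coords, cells, cells)


def pseudo_protocol(
    real_occ: OccurrenceSet,
    pseudo_occ: OccurrenceSet,
    stack: ClimateStack,
    k: int = 4,
    seed: int = 0,
    model_config: dict | None = None,
) -> EvalResult:
    """Train on quarters of the pseudo-presences, test on quarters of the
    real presences (k rotations); AUC against the shared background."""
    cfg = dict(model_config or {})
    cfg.setdefault("seed", seed)
    pseudo_plan = make_folds(pseudo_occ, k, seed)
    real_plan = make_folds(real_occ, k, seed + 1)
    background = _background_sample(stack, seed)
    n_cols = stack.template.n_cols
    pseudo_cells = np.array([r * n_cols + c for r, c in pseudo_occ.presence_cells])
    real_cells = np.array([r * n_cols + c for r, c in real_occ.presence_cells])
    aucs: list[float] = []
    for fold in range(k):
        train = pseudo_cells[pseudo_plan.assignments == fold]  # each 25% set alone
        _, test = real_plan.train_test(fold)
        try:
            model = fit_maxent(stack, train, background=background, **cfg)
            pred = predict(model, stack, clamp=True)
        except Exception as exc:
            raise RuntimeError(f"{real_occ.species}: pseudo fold {fold} failed: {exc}") from exc
        aucs.append(auc(_score_at(pred.logistic, real_cells[test]),
                        _score_at(pred.logistic, background)))
    return EvalResult(aucs, "pseudo_presence")
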