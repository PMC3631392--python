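"""End-to-end climate-change vulnerability analysis.

For every species passing the record-count cutoff (default: some design row
with ≥ 6 records), the pipeline fits a maxent model on all of its presence
cells over the current covariate stack (climate + forest), projects it to
the current and the future climate with clamping, thresholds both
projections at the species' minimum-training-presence value, intersects
the binary ranges with the DEM, computes area / maximum-probability /
altitude change metrics, and assigns a vulnerability tier.  A statistics
block compares current vs future distributions across species (Shapiro–Wilk
to choose paired t vs Mann–Whitney) and correlates the reduction metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate_derive import MonthlyClimate, derive_covariates, forest_percent
from .geo_io import (ClimateStack, Grid, OccurrenceSet, read_occurrences,
                     read_polygons, read_raster, resolve_occurrences)
from .maxent_core import fit_maxent, predict
from .stats import mann_whitney, paired_t, pearson, shapiro_wilk
from .threshold_change import (ChangeSummary, ClassificationRules, TIER_LABELS,
                               binarize, change_metrics, classify, mtp_threshold,
                               summarize)

log = logging.getLogger("nichecast")

__all__ = ["PipelineConfig", "SpeciesResult", "ReportBundle",
           "run_full_analysis", "load_fixture_dir", "change_table_metrics"]


@dataclass
class PipelineConfig:
    min_records: int = 6
    k_folds: int = 4
    seed: int = 0
    clamp: bool = True
    max_background: int = 10_000
    beta_class: dict | None = None
    rules: ClassificationRules = field(default_factory=ClassificationRules)

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be ≥ 2")
        if self.min_records < 1:
            raise ValueError("min_records must be ≥ 1")


@dataclass
class SpeciesResult:
    species: str
    threshold: float
    current: "object"
    future: "object"
    change: ChangeSummary
    tier: str


@dataclass
class ReportBundle:
    results: list[SpeciesResult]
    excluded: list[str]
    failed: dict[str, str]
    statistics: dict
    table: pd.DataFrame

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "change_report.csv", index=False)
        (out / "statistics.json").write_text(json.dumps(self.statistics, indent=1))
        (out / "excluded_species.json").write_text(json.dumps(
            {"excluded": self.excluded, "failed": self.failed}, indent=1))
        return out


def _species_rows(design: pd.DataFrame) -> dict[str, list[int]]:
    rows: dict[str, list[int]] = {}
    for _, r in design.iterrows():
        rows.setdefault(str(r["species"]), []).append(int(r["records"]))
    return rows


def run_full_analysis(
    stack_current: ClimateStack,
    stack_future: ClimateStack,
    dem: Grid,
    occurrences: dict[str, OccurrenceSet],
    design: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> ReportBundle:
    """Fit, project, threshold and classify every species above the cutoff.

    ``design`` (columns ``species``, ``records``) controls the cutoff: a
    species is modeled iff one of its rows has ≥ ``cfg.min_records``
    records.  A stage failure skips that species (logged) and the run
    continues; the bundle records the reason.
    """
    cfg = cfg or PipelineConfig()
    rows = _species_rows(design)
    modeled = [s for s, rr in rows.items() if any(r >= cfg.min_records for r in rr)]
    excluded = [s for s in rows if s not in modeled]
    log.info("modeling %d species, excluding %d (min_records=%d)",
             len(modeled), len(excluded), cfg.min_records)

    results: list[SpeciesResult] = []
    failed: dict[str, str] = {}
    for species in modeled:
        try:
            occ = occurrences[species]
            model = fit_maxent(stack_current, occ.presence_cells,
                               beta_class=cfg.beta_class,
                               max_background=cfg.max_background, seed=cfg.seed)
            pred_now = predict(model, stack_current, clamp=cfg.clamp)
            pred_fut = predict(model, stack_future, clamp=cfg.clamp)
            tau = mtp_threshold(pred_now, occ)
            s_now = summarize(binarize(pred_now, tau), pred_now, dem)
            s_fut = summarize(binarize(pred_fut, tau), pred_fut, dem)
            change = change_metrics(species, s_now, s_fut)
            tier = classify(change, cfg.rules)
            results.append(SpeciesResult(species, tau, s_now, s_fut, change, tier))
            log.info("%s: tau=%.4f area %d -> %d, tier=%s",
                     species, tau, s_now.area_cells, s_fut.area_cells, tier)
        except Exception as exc:
            failed[species] = str(exc)
            log.warning("%s: skipped (%s)", species, exc)

    table = pd.DataFrame([{
        "species": r.species,
        "threshold": r.threshold,
        "area_current": r.current.area_cells,
        "area_future": r.future.area_cells,
        "maxprob_current": r.current.max_logistic,
        "maxprob_future": r.future.max_logistic,
        "alt_min_current": r.current.alt_min,
        "alt_max_current": r.current.alt_max,
        "alt_min_future": r.future.alt_min,
        "alt_max_future": r.future.alt_max,
        "area_reduction_pct": r.change.area_reduction_pct,
        "maxprob_reduction_pct": r.change.maxprob_reduction_pct,
        "tier": r.tier,
        "tier_label": TIER_LABELS[r.tier],
    } for r in results])

    statistics = _statistics_block(table) if len(table) >= 3 else {}
    return ReportBundle(results, excluded, failed, statistics, table)


def _paired_or_ranksum(current: np.ndarray, future: np.ndarray, label: str) -> dict:
    """Shapiro–Wilk on the differences decides paired t vs Mann–Whitney."""
    out: dict = {"comparison": label}
    try:
        sw = shapiro_wilk(current - future)
        out["shapiro"] = sw.as_dict()
        normal = sw.p_value > 0.05
    except ValueError as exc:
        out["shapiro"] = {"error": str(exc)}
        normal = False
    try:
        test = paired_t(current, future) if normal else mann_whitney(current, future)
    except ValueError as exc:
        out["test"] = {"error": str(exc)}
        return out
    out["test"] = test.as_dict()
    return out


def _statistics_block(table: pd.DataFrame) -> dict:
    area_now = table["area_current"].to_numpy(dtype=float)
    area_fut = table["area_future"].to_numpy(dtype=float)
    prob_now = table["maxprob_current"].to_numpy(dtype=float)
    prob_fut = table["maxprob_future"].to_numpy(dtype=float)
    block = {
        "area": _paired_or_ranksum(area_now, area_fut, "thresholded area 2000 vs 2050"),
        "maxprob": _paired_or_ranksum(prob_now, prob_fut, "max probability 2000 vs 2050"),
    }
    try:
        block["correlation_area_vs_prob"] = pearson(
            table["area_reduction_pct"], table["maxprob_reduction_pct"])
    except ValueError as exc:
        block["correlation_area_vs_prob"] = {"error": str(exc)}
    return block


def change_table_metrics(table: pd.DataFrame,
                         rules: ClassificationRules | None = None) -> pd.DataFrame:
    """Change metrics + tiers from a range-summary table (columns
    ``species, area_2000, area_2050, maxprob_2000, maxprob_2050`` and
    optional altitude limits) — the same arithmetic the pipeline applies,
    usable directly on a published summary table."""
    from .threshold_change import RangeSummary

    out_rows = []
    for _, r in table.iterrows():
        cur = RangeSummary(int(r["area_2000"]), float(r["maxprob_2000"]),
                           float(r.get("alt_min_2000", 0.0)), float(r.get("alt_max_2000", 0.0)))
        a_fut = int(r["area_2050"])
        fut = RangeSummary(
            a_fut, float(r["maxprob_2050"]),
            float(r.get("alt_min_2050", 0.0)) if a_fut > 0 else None,
            float(r.get("alt_max_2050", 0.0)) if a_fut > 0 else None)
        ch = change_metrics(str(r["species"]), cur, fut)
        out_rows.append({
            "species": ch.species,
            "area_reduction_pct": ch.area_reduction_pct,
            "maxprob_reduction_pct": ch.maxprob_reduction_pct,
            "alt_min_shift": ch.alt_min_shift,
            "alt_max_shift": ch.alt_max_shift,
            "tier": classify(ch, rules),
        })
    return pd.DataFrame(out_rows)


def load_fixture_dir(path: str | Path) -> dict:
    """Load a serialized study directory (the ``StudyFixture.save`` layout)
    back into co-registered in-memory structures."""
    p = Path(path)
    dem = read_raster(p / "dem.asc")
    forest_fine = read_raster(p / "forest_fine.asc")
    temps = [read_raster(p / f"temp_{m + 1:02d}.asc") for m in range(12)]
    precips = [read_raster(p / f"precip_{m + 1:02d}.asc") for m in range(12)]
    temps_f = [read_raster(p / f"temp_future_{m + 1:02d}.asc") for m in range(12)]
    precips_f = [read_raster(p / f"precip_future_{m + 1:02d}.asc") for m in range(12)]
    mc_now = MonthlyClimate(temps, precips)
    mc_fut = MonthlyClimate(temps_f, precips_f)
    forest_pct = forest_percent(forest_fine, dem)
    stack_now = derive_covariates(mc_now, forest_pct)
    stack_fut = derive_covariates(mc_fut, forest_pct)
    raw_occ = read_occurrences(p / "occurrences.csv")
    occurrences = {sp: resolve_occurrences(sp, coords, dem)
                   for sp, coords in raw_occ.items()}
    manifest = json.loads((p / "manifest.json").read_text())
    design = pd.DataFrame(manifest["design"])
    polygons = read_polygons(p / "eoo.geojson") if (p / "eoo.geojson").exists() else {}
    return {"dem": dem, "stack_current": stack_now, "stack_future": stack_fut,
            "occurrences": occurrences, "design": design, "polygons": polygons,
            "manifest": manifest}
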