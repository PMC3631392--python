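"""Binary range maps, current-vs-future change metrics, vulnerability tiers.

Continuous suitability becomes a presence/absence map via the
minimum-training-presence (MTP) rule: the threshold is the smallest
predicted value at any training presence, and binarisation is inclusive
(cell = 1 iff logistic ≥ τ), so every training presence ends up inside the
current binary range — zero training omission by construction.

A range is summarised by its thresholded cell count, the maximum logistic
value over the whole prediction grid, and the altitude extremes of the
thresholded cells on a DEM.  Change metrics compare a current and a future
summary (positive reductions = loss), and a rule classifies each species:
most vulnerable when the thresholded area shrinks by more than 75% and the
maximum presence probability by more than 50%; lowest concern when the area
expands and the maximum probability rises by more than 25%; otherwise
intermediate.  Tier labels map onto the field-report wording as
most_vulnerable = "Most vulnerable", intermediate = "Less vulnerable",
lowest_concern = "More adapted".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo_io import Grid, OccurrenceSet, check_coregistered
from .maxent_core import PredictionGrid

__all__ = [
    "RangeSummary",
    "ChangeSummary",
    "ClassificationRules",
    "TIER_LABELS",
    "mtp_threshold",
    "binarize",
    "summarize",
    "change_metrics",
    "classify",
]

TIER_LABELS = {
    "most_vulnerable": "Most vulnerable",
    "intermediate": "Less vulnerable",
    "lowest_concern": "More adapted",
}


@dataclass
class RangeSummary:
    """Thresholded range of one species in one period."""

    area_cells: int
    max_logistic: float
    alt_min: float | None   # None when the thresholded range is empty
    alt_max: float | None

    def __post_init__(self) -> None:
        if self.area_cells < 0:
            raise ValueError("negative area")
        if self.area_cells > 0 and (self.alt_min is None or self.alt_max is None):
            raise ValueError("non-empty range must carry altitude limits")
        if self.alt_min is not None and self.alt_max is not None and self.alt_min > self.alt_max:
            raise ValueError("alt_min > alt_max")

    @property
    def alt_range(self) -> float | None:
        if self.alt_min is None or self.alt_max is None:
            return None
        return self.alt_max - self.alt_min


@dataclass
class ChangeSummary:
    """Current→future deltas; positive reductions denote loss."""

    species: str
    area_reduction_pct: float
    maxprob_reduction_pct: float
    alt_range_current: float | None
    alt_range_future: float | None
    alt_min_shift: float | None   # future − current (positive = uphill)
    alt_max_shift: float | None


@dataclass
class ClassificationRules:
    """Configurable tier thresholds (percent reductions)."""

    most_vulnerable_area: float = 75.0
    most_vulnerable_prob: float = 50.0
    lowest_concern_prob_raise: float = 25.0


def mtp_threshold(pred: PredictionGrid, occ: OccurrenceSet) -> float:
    """Minimum logistic value across the species' training presence cells."""
    vals = []
    for (r, c), (lon, lat) in zip(occ.cell_ids, occ.records):
        v = pred.logistic.values[r, c]
        if pred.logistic.mask[r, c] or not np.isfinite(v):
            raise ValueError(
                f"{occ.species}: record ({lon}, {lat}) falls on a masked prediction cell")
        vals.append(v)
    if not vals:
        raise ValueError(f"{occ.species}: no occurrence cells to threshold on")
    return float(min(vals))


def binarize(pred: PredictionGrid, tau: float) -> Grid:
    """Presence/absence map: 1 iff logistic ≥ τ (inclusive)."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {tau}")
    g = pred.logistic
    binary = np.where(g.mask, np.nan, (g.values >= tau).astype(float))
    return g.copy_with(binary, g.mask)


def summarize(binary: Grid, pred: PredictionGrid, dem: Grid) -> RangeSummary:
    """Cell count, grid-wide maximum logistic, and DEM extremes over 1-cells.

    An empty binary map is a legitimate outcome (a range can vanish under a
    future climate): area 0 with undefined altitude limits.
    """
    check_coregistered([binary, pred.logistic, dem])
    ones = (~binary.mask) & (binary.values == 1)
    area = int(ones.sum())
    max_logistic = float(np.nanmax(np.where(pred.logistic.mask, np.nan,
                                            pred.logistic.values)))
    if area == 0:
        return RangeSummary(0, max_logistic, None, None)
    alt = dem.values[ones & ~dem.mask]
    if alt.size == 0:
        raise ValueError("thresholded range lies entirely on DEM nodata")
    return RangeSummary(area, max_logistic, float(alt.min()), float(alt.max()))


def change_metrics(species: str, current: RangeSummary, future: RangeSummary) -> ChangeSummary:
    """Percent area / max-probability reductions and altitude-limit shifts."""
    if current.area_cells == 0:
        raise ValueError(f"{species}: current area is 0, reduction undefined")
    area_red = 100.0 * (current.area_cells - future.area_cells) / current.area_cells
    prob_red = 100.0 * (current.max_logistic - future.max_logistic) / current.max_logistic
    if future.area_cells > 0:
        alt_min_shift = future.alt_min - current.alt_min
        alt_max_shift = future.alt_max - current.alt_max
        alt_range_future = future.alt_range
    else:
        alt_min_shift = alt_max_shift = alt_range_future = None
    return ChangeSummary(species, area_red, prob_red,
                         current.alt_range, alt_range_future,
                         alt_min_shift, alt_max_shift)


def classify(ch: ChangeSummary, rules: ClassificationRules | None = None) -> str:
    """Vulnerability tier from the area / maximum-probability reductions."""
    r = rules or ClassificationRules()
    if (ch.area_reduction_pct > r.most_vulnerable_area
            and ch.maxprob_reduction_pct > r.most_vulnerable_prob):
        return "most_vulnerable"
    if (ch.area_reduction_pct < 0
            and ch.maxprob_reduction_pct < -r.lowest_concern_prob_raise):
        return "lowest_concern"
    return "intermediate"
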