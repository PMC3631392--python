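"""Bioclimatic covariates from monthly climate plus a fine forest map.

Ten covariates drive the niche models: six direct monthly summaries
(coldest/hottest month temperature, annual mean temperature, wettest/driest
month precipitation, annual precipitation), three hydrological derivations
(annual potential evapotranspiration, annual water balance, number of months
with a strictly positive water balance), and percent forest cover aggregated
from a finer binary forest map onto the climate lattice.

PET follows the Thornthwaite (1948) monthly method — it needs exactly the
inputs available here (monthly mean temperature and latitude for day
length).  The day-length correction uses the mid-month solar declination
and is undefined poleward of the polar circles.  The hook
``pet_model="thornthwaite"`` in :func:`derive_covariates` is the seam where
an alternative PET formulation could be slotted in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo_io import ClimateStack, Grid, check_coregistered

__all__ = [
    "MonthlyClimate",
    "COVARIATE_NAMES",
    "summarize_monthly",
    "thornthwaite_pet",
    "water_balance",
    "forest_percent",
    "derive_covariates",
]

#: Canonical covariate layer names, in the fixed order used for features.
COVARIATE_NAMES = [
    "t_cold", "t_hot", "t_mean", "p_wet", "p_dry", "p_ann",
    "pet_ann", "wb_ann", "wb_pos_months",
]

_MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)


@dataclass
class MonthlyClimate:
    """Twelve co-registered monthly mean-temperature (°C) and precipitation
    (mm/month) layers."""

    temp: list[Grid]
    precip: list[Grid]

    def __post_init__(self) -> None:
        if len(self.temp) != 12 or len(self.precip) != 12:
            raise ValueError("need exactly 12 temperature and 12 precipitation layers")
        check_coregistered(self.temp + self.precip)

    @property
    def template(self) -> Grid:
        return self.temp[0]

    def combined_mask(self) -> np.ndarray:
        out = np.zeros(self.template.values.shape, dtype=bool)
        for g in self.temp + self.precip:
            out |= g.mask
        return out


def _stack_values(grids: list[Grid]) -> np.ndarray:
    return np.stack([g.values for g in grids])


def summarize_monthly(mc: MonthlyClimate) -> dict[str, Grid]:
    """Six direct summaries; a cell masked in any month is masked in all."""
    mask = mc.combined_mask()
    t = _stack_values(mc.temp)
    p = _stack_values(mc.precip)
    with np.errstate(invalid="ignore"):
        out = {
            "t_cold": np.nanmin(t, axis=0),
            "t_hot": np.nanmax(t, axis=0),
            "t_mean": np.nanmean(t, axis=0),
            "p_wet": np.nanmax(p, axis=0),
            "p_dry": np.nanmin(p, axis=0),
            "p_ann": np.nansum(p, axis=0),
        }
    tmpl = mc.template
    return {k: tmpl.copy_with(np.where(mask, np.nan, v), mask) for k, v in out.items()}


def _day_length_hours(lat_deg: np.ndarray, doy: int) -> np.ndarray:
    """Astronomical day length (h) from latitude and day of year."""
    if np.any(np.abs(lat_deg) > 66.5):
        raise ValueError("latitude beyond ±66.5°: day-length formula undefined")
    phi = np.deg2rad(lat_deg)
    decl = 0.409 * np.sin(2 * np.pi * doy / 365.0 - 1.39)
    cos_ws = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_ws)


def thornthwaite_pet(mc: MonthlyClimate, latitude_per_row: np.ndarray | None = None) -> list[Grid]:
    """Monthly potential evapotranspiration (mm/month), Thornthwaite method.

    Heat index I = sum over months of (T/5)^1.514 for T > 0; exponent
    a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239.  Unadjusted
    PET = 16 (10 T / I)^a for 0 < T < 26.5 °C, and the high-temperature
    polynomial -415.85 + 32.24 T - 0.43 T^2 above 26.5 °C; months at or
    below 0 °C evaporate nothing.  Each month is scaled by day length / 12
    and days-in-month / 30.
    """
    tmpl = mc.template
    if latitude_per_row is None:
        latitude_per_row = tmpl.row_latitudes()
    latitude_per_row = np.asarray(latitude_per_row, dtype=float)
    if latitude_per_row.shape != (tmpl.n_rows,):
        raise ValueError("latitude_per_row must have one entry per grid row")
    if np.any(np.abs(latitude_per_row) > 66.5):
        raise ValueError("latitude beyond ±66.5°: day-length formula undefined")

    mask = mc.combined_mask()
    t = _stack_values(mc.temp)  # (12, rows, cols)
    t_pos = np.where(t > 0, t, 0.0)
    with np.errstate(invalid="ignore"):
        heat_index = np.nansum((t_pos / 5.0) ** 1.514, axis=0)
    a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
         + 1.792e-2 * heat_index + 0.49239)

    out: list[Grid] = []
    for m in range(12):
        tm = t[m]
        pet = np.zeros_like(tm)
        warm = (tm > 0) & (tm < 26.5) & (heat_index > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pet = np.where(warm, 16.0 * (10.0 * t_pos[m] / np.where(heat_index > 0, heat_index, 1.0)) ** a, pet)
        hot = tm >= 26.5
        pet = np.where(hot, -415.85 + 32.24 * tm - 0.43 * tm**2, pet)
        day_len = _day_length_hours(latitude_per_row, int(_MID_MONTH_DOY[m]))
        corr = (day_len / 12.0)[:, None] * (_DAYS_IN_MONTH[m] / 30.0)
        pet = np.maximum(pet * corr, 0.0)
        out.append(tmpl.copy_with(np.where(mask, np.nan, pet), mask))
    return out


def water_balance(mc: MonthlyClimate, pet: list[Grid]) -> dict[str, Grid]:
    """Annual PET, annual water balance and count of months with P - PET > 0.

    The conservation identity wb_ann = p_ann - pet_ann holds cell-wise.
    "Positive" is strict: a month with P exactly equal to PET does not count.
    """
    if len(pet) != 12:
        raise ValueError("need 12 PET layers")
    check_coregistered(mc.temp + pet)
    mask = mc.combined_mask()
    for g in pet:
        mask = mask | g.mask
    p = _stack_values(mc.precip)
    e = _stack_values(pet)
    with np.errstate(invalid="ignore"):
        pet_ann = np.nansum(e, axis=0)
        wb_ann = np.nansum(p - e, axis=0)
        wb_pos = np.sum((p - e) > 0, axis=0).astype(float)
    tmpl = mc.template
    return {
        "pet_ann": tmpl.copy_with(np.where(mask, np.nan, pet_ann), mask),
        "wb_ann": tmpl.copy_with(np.where(mask, np.nan, wb_ann), mask),
        "wb_pos_months": tmpl.copy_with(np.where(mask, np.nan, wb_pos), mask),
    }


def forest_percent(fine: Grid, coarse_template: Grid) -> Grid:
    """Aggregate a fine binary forest map to percent cover on a coarse lattice.

    The fine lattice must nest exactly in the coarse one (shared origin,
    integer cell-size ratio).  Percent cover is taken over *unmasked* fine
    cells only; a coarse cell whose fine cells are all masked is masked.
    """
    ratio_f = coarse_template.cell_size / fine.cell_size
    ratio = int(round(ratio_f))
    if abs(ratio_f - ratio) > 1e-6 or ratio < 1:
        raise ValueError(
            f"fine cell size {fine.cell_size} does not nest in coarse "
            f"cell size {coarse_template.cell_size}")
    if (abs(fine.x_origin - coarse_template.x_origin) > 1e-9
            or abs(fine.y_origin - coarse_template.y_origin) > 1e-9):
        raise ValueError("fine and coarse grids must share an origin")
    if (fine.n_rows != coarse_template.n_rows * ratio
            or fine.n_cols != coarse_template.n_cols * ratio):
        raise ValueError("fine grid shape is not ratio x coarse shape")
    vals = np.where(fine.mask, np.nan, fine.values)
    if not np.all(np.isin(vals[~fine.mask], (0.0, 1.0))):
        raise ValueError("fine forest map must be binary 0/1")
    blocks = vals.reshape(coarse_template.n_rows, ratio, coarse_template.n_cols, ratio)
    forest = np.nansum(blocks, axis=(1, 3))
    valid = np.sum(~np.isnan(blocks), axis=(1, 3))
    out_mask = valid == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(out_mask, np.nan, 100.0 * forest / np.where(valid > 0, valid, 1))
    return coarse_template.copy_with(pct, out_mask)


def derive_covariates(
    mc: MonthlyClimate,
    forest_pct: Grid | None = None,
    pet_model: str = "thornthwaite",
) -> ClimateStack:
    """Full covariate stack (nine climate layers, plus forest when given)."""
    if pet_model != "thornthwaite":
        raise ValueError(f"unknown PET model {pet_model!r}")
    layers = summarize_monthly(mc)
    pet = thornthwaite_pet(mc)
    layers.update(water_balance(mc, pet))
    if forest_pct is not None:
        check_coregistered([mc.template, forest_pct])
        layers["forest_pct"] = forest_pct
    return ClimateStack(layers)
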